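import numpy as np
import pandas as pd
import pytest

from autonomics.indices import ALL_CHANNELS, IndexSeries
from autonomics.synthetic import (RegimeParams, SessionAnnotations,
                                  SyntheticSessionSpec)


def small_spec(n_subjects=3, seed=5, effect_scale=1.0):
    """A 50-minute scaled-down study (10 stages of 5 min) for fast tests."""
    return SyntheticSessionSpec(
        n_subjects=n_subjects,
        stage_minutes=5.0,
        loc_time=800.0,
        roc_time=2600.0,
        autonomic_lag_range=(-60.0, 60.0),
        transition_halfwidth=60.0,
        effect_scale=effect_scale,
        seed=seed,
    )


SMALL_PIPE_CFG = {
    "seed": 5,
    "delta": 1.0,
    "rr": {"p": 1, "W_fit": 60.0},
    "eda": {"p": 1, "W_fit": 240.0, "q": 1},
}


@pytest.fixture(scope="session")
def stationary_rr():
    return RegimeParams(mu_base=1.0, lambda_shape=1000.0)


@pytest.fixture(scope="session")
def annotations_9000s():
    return SessionAnnotations(
        loc_s=2400.0, roc_s=7800.0,
        baseline_pre=(0.0, 900.0), baseline_post=(8100.0, 9000.0),
        stage_starts=tuple(900.0 * k for k in range(10)),
        stage_targets=(0, 1, 2, 3, 4, 5, 3.75, 2.5, 1.25, 0),
        duration=9000.0)


@pytest.fixture(scope="session")
def noise_index_series():
    """A 15-channel index series of white noise on a 1 s grid (2.5 h),
    invalid during the first 60 s (mimicking the initial fitting window)."""
    rng = np.random.default_rng(0)
    grid = np.arange(0.0, 9000.0, 1.0)
    vals = pd.DataFrame({ch: rng.standard_normal(len(grid))
                         for ch in ALL_CHANNELS})
    valid = pd.DataFrame({ch: grid >= 60.0 for ch in ALL_CHANNELS})
    return IndexSeries(grid=grid, values=vals[list(ALL_CHANNELS)],
                       valid=valid[list(ALL_CHANNELS)])


@pytest.fixture(scope="session")
def fitted_small_study():
    """Three fitted 50-min sessions: (index_by_subject, ann_by_subject)."""
    from autonomics.pipeline import fit_session_indices, merge_config
    from autonomics.synthetic import simulate_study
    cfg = merge_config(SMALL_PIPE_CFG)
    idx_by, ann_by = {}, {}
    for s in simulate_study(small_spec()):
        idx, *_ = fit_session_indices(
            s.r_peaks, s.eda_pulse_times, s.eda_pulse_amps,
            s.tonic_times, s.tonic_values, cfg)
        idx_by[s.subject_id] = idx
        ann_by[s.subject_id] = s.annotations
    return idx_by, ann_by
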