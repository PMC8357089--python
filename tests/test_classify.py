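"""Labeling, features, z-scoring, AUC, LOSO LASSO, bootstrap CIs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autonomics.classify import (auc, auc_diff_ci, build_features,
                                 build_question_features, feature_columns,
                                 label_windows, loso_lasso_logistic,
                                 select_modality, zscore_by_subject)


class TestLabelWindows:
    def test_q1_midpoint_rule(self, annotations_9000s):
        lw = label_windows(annotations_9000s, 1, 20.0)
        s = dict(zip(lw.starts, lw.labels))
        assert s[2400.0] == 1      # midpoint 2410 inside [loc, roc)
        assert s[2380.0] == 0      # midpoint 2390 before loc
        assert s[7780.0] == 1 and s[7800.0] == 0

    @pytest.mark.parametrize("w", [10.0, 20.0, 30.0])
    def test_q2_window_count(self, annotations_9000s, w):
        lw = label_windows(annotations_9000s, 2, w, t_min=20)
        assert len(lw.starts) == int(2 * 20 * 60 / w)
        assert lw.labels.sum() == len(lw.starts) // 2

    def test_q3_consciousness_is_one(self, annotations_9000s):
        lw = label_windows(annotations_9000s, 3, 20.0, t_min=10)
        after = lw.starts >= annotations_9000s.roc_s
        assert np.all(lw.labels[after] == 1)
        assert np.all(lw.labels[~after] == 0)

    def test_q4_avoids_anesthesia_period(self, annotations_9000s):
        lw = label_windows(annotations_9000s, 4, 20.0)
        loc, roc = annotations_9000s.loc_s, annotations_9000s.roc_s
        assert not np.any((lw.starts >= loc) & (lw.starts < roc))

    def test_invalid_inputs(self, annotations_9000s):
        with pytest.raises(ValueError):
            label_windows(annotations_9000s, 5, 20.0)
        with pytest.raises(ValueError):
            label_windows(annotations_9000s, 2, 20.0)   # t missing


class TestBuildFeatures:
    @pytest.mark.parametrize("w,h,per_index", [(30.0, 120.0, 5),
                                               (15.0, 30.0, 3),
                                               (20.0, 0.0, 1)])
    def test_lagged_feature_count(self, noise_index_series,
                                  annotations_9000s, w, h, per_index):
        lw = label_windows(annotations_9000s, 1, w)
        ft = build_features(noise_index_series, lw, "S1", h=h)
        assert len(feature_columns(ft)) == per_index * 15

    def test_rows_before_onset_dropped(self, noise_index_series,
                                       annotations_9000s):
        # indices invalid before 60 s; with h = 120 the first usable
        # window starts at >= onset + h
        lw = label_windows(annotations_9000s, 1, 30.0)
        ft = build_features(noise_index_series, lw, "S1", h=120.0)
        assert ft["window_start_s"].min() >= 60.0 + 120.0

    def test_indivisible_history_raises(self, noise_index_series,
                                        annotations_9000s):
        lw = label_windows(annotations_9000s, 1, 20.0)
        with pytest.raises(ValueError):
            build_features(noise_index_series, lw, "S1", h=30.0)

    def test_modality_subsets(self, noise_index_series, annotations_9000s):
        lw = label_windows(annotations_9000s, 1, 30.0)
        ft = build_features(noise_index_series, lw, "S1", h=120.0)
        assert len(feature_columns(select_modality(ft, "hrv"))) == 10 * 5
        assert len(feature_columns(select_modality(ft, "eda"))) == 5 * 5
        no_amp = feature_columns(select_modality(ft, "eda_no_amp"))
        assert len(no_amp) == 3 * 5
        assert not any(c.startswith(("mu_amp", "sigma_amp"))
                       for c in no_amp)


class TestZScore:
    def _table(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "subject_id": np.repeat(["A", "B"], 50),
            "window_start_s": np.tile(np.arange(50.0), 2),
            "label": np.tile([0, 1], 50),
            "f1": rng.standard_normal(100) * 3 + 2,
            "f2": np.ones(100),
        })

    def test_per_subject_moments(self):
        z = zscore_by_subject(self._table())
        for _, g in z.groupby("subject_id"):
            assert g["f1"].mean() == pytest.approx(0.0, abs=1e-12)
            assert g["f1"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_feature_zeroed(self):
        z = zscore_by_subject(self._table())
        assert (z["f2"] == 0).all()

    def test_idempotent(self):
        once = zscore_by_subject(self._table())
        twice = zscore_by_subject(once)
        pd.testing.assert_frame_equal(once, twice)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]) == 1.0

    def test_interleaved(self):
        assert auc([0.9, 0.6, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_all_ties(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(20)
        for _ in range(100):
            n = rng.integers(4, 13)
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            num, den = 0.0, 0
            for i, j in itertools.product(np.flatnonzero(labels == 1),
                                          np.flatnonzero(labels == 0)):
                den += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
            assert auc(scores, labels) == pytest.approx(num / den,
                                                        abs=1e-12)


class TestAucDiffCi:
    def _paired(self, seed=0, gap=0.15, n_subj=9, n_win=40):
        rng = np.random.default_rng(seed)
        labels, sa, sb, sid = [], [], [], []
        for s in range(n_subj):
            shift = rng.normal(0, 0.3)
            for i in range(n_win):
                y = i % 2
                labels.append(y)
                sa.append(1.2 * y + shift + rng.normal(0, 1))
                sb.append(0.55 * y + shift + rng.normal(0, 1))
                sid.append(f"S{s}")
        return (np.array(sa), np.array(sb), np.array(labels),
                np.array(sid))

    def test_identical_models(self):
        sa, sb, labels, sid = self._paired()
        pt, lo, hi, sig = auc_diff_ci(sa, sa, labels, sid, n_boot=200,
                                      seed=1)
        assert pt == 0.0
        assert lo <= 0.0 <= hi
        assert not sig

    def test_significance_flag_definition(self):
        sa, sb, labels, sid = self._paired()
        pt, lo, hi, sig = auc_diff_ci(sa, sb, labels, sid, n_boot=400,
                                      seed=2)
        assert sig == (lo > 0 or hi < 0)
        assert pt > 0

    def test_coverage_of_known_gap(self):
        # empirical true gap from a very large single draw
        sa, sb, labels, sid = self._paired(seed=123, n_subj=200, n_win=200)
        true_gap = auc(sa, labels) - auc(sb, labels)
        cover = 0
        n_rep = 100
        for rep in range(n_rep):
            sa, sb, labels, sid = self._paired(seed=rep)
            _, lo, hi, _ = auc_diff_ci(sa, sb, labels, sid, n_boot=300,
                                       seed=rep)
            cover += lo <= true_gap <= hi
        assert cover / n_rep >= 0.85   # ~95% nominal, small-sample slack

    def test_single_subject_raises(self):
        with pytest.raises(ValueError):
            auc_diff_ci([0.1, 0.9], [0.2, 0.8], [0, 1], ["A", "A"])


class TestLoso:
    def test_single_subject_rejected(self):
        ft = pd.DataFrame({"subject_id": ["A"] * 10,
                           "window_start_s": np.arange(10.0),
                           "label": [0, 1] * 5,
                           "f": np.arange(10.0)})
        with pytest.raises(ValueError):
            loso_lasso_logistic(ft)

    def test_single_class_training_fold_rejected(self):
        ft = pd.DataFrame({"subject_id": ["A"] * 10 + ["B"] * 10,
                           "window_start_s": np.arange(20.0),
                           "label": [0] * 10 + [1] * 10,
                           "f": np.arange(20.0)})
        with pytest.raises(ValueError):
            loso_lasso_logistic(ft)

    def test_separable_study_high_auc(self, fitted_small_study):
        idx_by, ann_by = fitted_small_study
        ft = build_question_features(idx_by, ann_by, 1, w=20.0,
                                     metric="median", h=120.0)
        rep = loso_lasso_logistic(ft, seed=0)
        assert rep.pooled_auc >= 0.90
        assert set(rep.predictions["subject_id"]) == set(idx_by)
        assert np.all((rep.predictions["probability"] >= 0)
                      & (rep.predictions["probability"] <= 1))

    def test_no_leakage_from_held_out_subject(self, fitted_small_study):
        # duplicating a held-out subject's rows with shuffled labels must
        # not change that subject's predictions
        idx_by, ann_by = fitted_small_study
        ft = build_question_features(idx_by, ann_by, 1, w=20.0,
                                     metric="median", h=0.0)
        target = ft["subject_id"].iloc[0]
        rep0 = loso_lasso_logistic(ft, seed=0)
        p0 = rep0.predictions.query("subject_id == @target")
        dup = ft[ft.subject_id == target].copy()
        rng = np.random.default_rng(1)
        dup["label"] = rng.permutation(dup["label"].to_numpy())
        rep1 = loso_lasso_logistic(pd.concat([ft, dup], ignore_index=True),
                                   seed=0)
        p1 = rep1.predictions.query("subject_id == @target") \
            .iloc[:len(p0)]
        np.testing.assert_allclose(p0["probability"].to_numpy(),
                                   p1["probability"].to_numpy(),
                                   atol=1e-12)

    def test_duplicated_features_leave_auc_unchanged(self,
                                                     fitted_small_study):
        idx_by, ann_by = fitted_small_study
        ft = build_question_features(idx_by, ann_by, 1, w=20.0,
                                     metric="median", h=0.0)
        rep0 = loso_lasso_logistic(ft, seed=0)
        dup = ft.copy()
        for c in feature_columns(ft):
            dup[c + "_copy"] = dup[c]
        rep1 = loso_lasso_logistic(dup, seed=0)
        assert abs(rep0.pooled_auc - rep1.pooled_auc) <= 0.01

    def test_permuted_labels_near_chance(self, fitted_small_study):
        idx_by, ann_by = fitted_small_study
        ft = build_question_features(idx_by, ann_by, 1, w=20.0,
                                     metric="median", h=0.0)
        aucs = []
        for seed in range(3):
            ftp = ft.copy()
            rng = np.random.default_rng(seed)
            for _, rows in ftp.groupby("subject_id").groups.items():
                ftp.loc[rows, "label"] = rng.permutation(
                    ftp.loc[rows, "label"].to_numpy())
            aucs.append(loso_lasso_logistic(ftp, seed=0).pooled_auc)
        assert 0.40 <= np.mean(aucs) <= 0.60
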