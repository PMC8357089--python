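"""Behavioral-vs-autonomic classification framework.

Logistic regression is used as a statistical tool: behavioral state
(from LOC/ROC annotations) is the ground-truth left side, and the 15
autonomic indices — aggregated in w-second windows, optionally with M =
h/w lagged history windows per index — are the features.  Four questions
share the machinery and differ only in the stretch of session used and
the labeling:

1. consciousness vs unconsciousness over the full session
   (before LOC / after ROC = 0; between = 1);
2. t minutes before vs after LOC (before = 0, after = 1);
3. t minutes before vs after ROC (unconsciousness = 0, consciousness = 1);
4. pre- vs post-anesthesia baselines (pre = 0, post = 1).

Features are z-scored within subject, models are L1-penalized logistic
regressions with the penalty chosen by inner stratified CV (one-SE
rule), evaluated by leave-one-subject-out cross-validation and pooled
AUC.  Modality ablations (HRV-only, EDA-only, EDA without amplitude) and
paired subject-level bootstrap CIs on AUC differences quantify what each
modality contributes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .indices import ALL_CHANNELS, EDA_CHANNELS, HRV_CHANNELS, IndexSeries
from .synthetic import SessionAnnotations

EDA_NO_AMP_CHANNELS = ("tonic_EDA", "muPR", "sigmaPR")

W_GRID = (2, 5, 10, 15, 20, 30)
H_GRID = (0, 30, 60, 120, 240)
T_GRID_MIN = (10, 15, 20)


# ---------------------------------------------------------------------------
# windows and labels


@dataclass(frozen=True)
class LabeledWindows:
    """Window start times (s) and binary labels for one subject."""

    starts: np.ndarray
    labels: np.ndarray
    w: float


def label_windows(ann: SessionAnnotations, question: int, w: float,
                  t_min: float | None = None) -> LabeledWindows:
    """Tile the relevant session stretch with w-second windows and label.

    A window's label follows its midpoint (so windows straddling LOC/ROC
    get a deterministic label).  Questions 2 and 3 require ``t_min``
    (minutes before/after the transition).
    """
    if question not in (1, 2, 3, 4):
        raise ValueError("question must be 1, 2, 3, or 4")
    if w <= 0:
        raise ValueError("window length must be positive")
    loc, roc = ann.loc_s, ann.roc_s

    def tile(lo, hi):
        n = int(np.floor((hi - lo) / w))
        return lo + w * np.arange(n)

    if question == 1:
        starts = tile(0.0, ann.duration)
        mid = starts + w / 2.0
        labels = ((mid >= loc) & (mid < roc)).astype(int)
    elif question in (2, 3):
        if t_min is None:
            raise ValueError("questions 2 and 3 require t (minutes)")
        t = t_min * 60.0
        center = loc if question == 2 else roc
        starts = tile(center - t, center + t)
        mid = starts + w / 2.0
        labels = (mid >= center).astype(int)
    else:
        s_pre = tile(*ann.baseline_pre)
        s_post = tile(*ann.baseline_post)
        starts = np.concatenate([s_pre, s_post])
        labels = np.concatenate([np.zeros(len(s_pre), int),
                                 np.ones(len(s_post), int)])
    return LabeledWindows(starts=starts, labels=labels, w=float(w))


# ---------------------------------------------------------------------------
# features


def build_features(idx: IndexSeries, windows: LabeledWindows,
                   subject_id: str, metric: str = "median",
                   h: float = 0.0) -> pd.DataFrame:
    """Window-aggregated feature rows for one subject.

    Each row holds, for every index, the ``metric`` (mean or median) of
    that index over the window plus over the M = h/w immediately
    preceding lagged windows — (M+1) features per index.  Rows whose
    earliest lag window reaches before the data onset (the initial
    fitting period, where no indices exist) are dropped.
    """
    if metric not in ("mean", "median"):
        raise ValueError("metric must be 'mean' or 'median'")
    w = windows.w
    M_f = h / w
    if abs(M_f - round(M_f)) > 1e-9:
        raise ValueError("h must be an integer multiple of w")
    M = int(round(M_f))

    grid = idx.grid
    delta = idx.delta
    nw = max(1, int(round(w / delta)))
    vals = idx.values.to_numpy(dtype=float).copy()
    vals[~idx.valid.to_numpy(dtype=bool)] = np.nan

    # data onset: first grid time at which any channel is valid
    any_valid = idx.valid.to_numpy(dtype=bool).any(axis=1)
    if not any_valid.any():
        raise ValueError("index series has no valid samples")
    onset = grid[int(np.argmax(any_valid))]

    reducer = np.nanmean if metric == "mean" else np.nanmedian
    rows = []
    starts_kept = []
    labels_kept = []
    for s, lab in zip(windows.starts, windows.labels):
        if s - M * w < onset - 1e-9:
            continue
        feats = np.empty((M + 1) * len(ALL_CHANNELS))
        ok = True
        for k in range(M + 1):
            lo = s - k * w
            i0 = int(np.round((lo - grid[0]) / delta))
            i1 = i0 + nw
            if i0 < 0 or i1 > len(grid):
                ok = False
                break
            block = vals[i0:i1]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                feats[k * len(ALL_CHANNELS):(k + 1) * len(ALL_CHANNELS)] = \
                    reducer(block, axis=0)
        if not ok:
            continue
        rows.append(feats)
        starts_kept.append(s)
        labels_kept.append(lab)
    cols = [f"{ch}_lag{k}" for k in range(M + 1) for ch in ALL_CHANNELS]
    ft = pd.DataFrame(rows, columns=cols)
    ft.insert(0, "subject_id", subject_id)
    ft.insert(1, "window_start_s", starts_kept)
    ft.insert(2, "label", labels_kept)
    return ft


def feature_columns(ft: pd.DataFrame) -> list[str]:
    return [c for c in ft.columns
            if c not in ("subject_id", "window_start_s", "label")]


def select_modality(ft: pd.DataFrame, modality: str) -> pd.DataFrame:
    """Restrict the feature table to a modality subset of indices."""
    keep = {
        "multimodal": ALL_CHANNELS,
        "hrv": HRV_CHANNELS,
        "eda": EDA_CHANNELS,
        "eda_no_amp": EDA_NO_AMP_CHANNELS,
    }[modality]
    cols = [c for c in feature_columns(ft)
            if c.rsplit("_lag", 1)[0] in keep]
    return ft[["subject_id", "window_start_s", "label"] + cols]


def zscore_by_subject(ft: pd.DataFrame) -> pd.DataFrame:
    """Z-score every feature within each subject (idempotent).

    Constant features become all zeros; residual NaNs (windows where an
    index was fully masked) are set to 0 after standardization.
    """
    out = ft.copy()
    cols = feature_columns(ft)
    for _, idx in ft.groupby("subject_id").groups.items():
        block = out.loc[idx, cols]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        sd = sd.replace(0.0, np.nan)
        z = (block - mu) / sd
        out.loc[idx, cols] = z.fillna(0.0)
    return out


# ---------------------------------------------------------------------------
# AUC


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative),
    ties counted 1/2.  Requires both classes present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    npos = int(np.sum(labels == 1))
    nneg = int(np.sum(labels == 0))
    if npos == 0 or nneg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((np.sum(ranks[labels == 1]) - npos * (npos + 1) / 2.0)
                 / (npos * nneg))


def auc_diff_ci(scores_a, scores_b, labels, subject_ids,
                level: float = 0.95, n_boot: int = 1000,
                seed: int = 0):
    """Paired subject-level bootstrap CI for AUC_a - AUC_b.

    Subjects are resampled with replacement; both models' pooled AUCs are
    recomputed on the resampled pool and the percentile interval of the
    difference is returned as (point_estimate, lo, hi, significant).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if len(subjects) < 2:
        raise ValueError("bootstrap CI requires >= 2 subjects")
    groups = {s: np.flatnonzero(subject_ids == s) for s in subjects}
    point = auc(scores_a, labels) - auc(scores_b, labels)
    rng = np.random.default_rng(seed)
    diffs = []
    attempts = 0
    while len(diffs) < n_boot and attempts < 20 * n_boot:
        attempts += 1
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        sel = np.concatenate([groups[s] for s in pick])
        lab = labels[sel]
        if lab.min() == lab.max():
            continue
        diffs.append(auc(scores_a[sel], lab) - auc(scores_b[sel], lab))
    diffs = np.asarray(diffs)
    alpha = 1.0 - level
    lo, hi = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0])
    significant = bool(lo > 0 or hi < 0)
    return point, float(lo), float(hi), significant


# ---------------------------------------------------------------------------
# LASSO-logistic LOSO


@dataclass
class ClassifierReport:
    """Held-out predictions and summary for one model configuration."""

    predictions: pd.DataFrame      # subject_id, window_start_s, label, prob
    pooled_auc: float
    per_subject_auc: dict
    surviving_features: dict       # held-out subject -> list of (name, coef)
    config: dict = field(default_factory=dict)

    @property
    def n_surviving(self) -> float:
        counts = [len(v) for v in self.surviving_features.values()]
        return float(np.mean(counts)) if counts else 0.0


def _one_se_c(mean_dev: np.ndarray, se_dev: np.ndarray,
              c_grid: np.ndarray) -> float:
    """One-SE rule: strongest penalty whose deviance is within one SE of
    the best.  c_grid ascends (small C = strong penalty)."""
    best = int(np.argmin(mean_dev))
    limit = mean_dev[best] + se_dev[best]
    for i in range(len(c_grid)):
        if mean_dev[i] <= limit:
            return float(c_grid[i])
    return float(c_grid[best])


def _log_loss(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def loso_lasso_logistic(ft: pd.DataFrame,
                        c_grid: np.ndarray | None = None,
                        inner_folds: int = 5,
                        seed: int = 0) -> ClassifierReport:
    """Leave-one-subject-out L1-logistic regression with pooled AUC.

    For each held-out subject the model is fitted on the remaining
    subjects' windows; the L1 penalty is chosen on the training windows
    by stratified ``inner_folds``-fold CV minimizing deviance with the
    one-SE rule.  Held-out predicted probabilities are pooled across
    subjects for a single AUC; per-fold surviving (nonzero-coefficient)
    features are recorded.
    """
    if c_grid is None:
        c_grid = np.logspace(-2.5, -0.5, 8)
    c_grid = np.sort(np.asarray(c_grid, dtype=float))
    subjects = ft["subject_id"].unique()
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    cols = feature_columns(ft)
    X_all = ft[cols].to_numpy(dtype=float)
    y_all = ft["label"].to_numpy(dtype=int)
    sid = ft["subject_id"].to_numpy()

    preds = np.full(len(ft), np.nan)
    surviving: dict = {}
    for held in subjects:
        test = sid == held
        train = ~test
        X, y = X_all[train], y_all[train]
        if y.min() == y.max():
            raise ValueError(f"training fold for {held} has a single class")
        k = min(inner_folds, int(np.bincount(y).min()))
        mean_dev = np.empty(len(c_grid))
        se_dev = np.empty(len(c_grid))
        if k >= 2:
            skf = StratifiedKFold(n_splits=k, shuffle=True,
                                  random_state=seed)
            splits = list(skf.split(X, y))
            dev = np.empty((len(c_grid), k))
            for ic, C in enumerate(c_grid):
                for j, (tr, va) in enumerate(splits):
                    clf = LogisticRegression(
                        l1_ratio=1.0, C=C, solver="liblinear",
                        max_iter=500, tol=1e-4, random_state=0)
                    clf.fit(X[tr], y[tr])
                    dev[ic, j] = _log_loss(y[va],
                                           clf.predict_proba(X[va])[:, 1])
            mean_dev = dev.mean(axis=1)
            se_dev = dev.std(axis=1, ddof=1) / np.sqrt(k)
        else:
            for ic, C in enumerate(c_grid):
                clf = LogisticRegression(l1_ratio=1.0, C=C,
                                         solver="liblinear", max_iter=500, random_state=0)
                clf.fit(X, y)
                mean_dev[ic] = _log_loss(y, clf.predict_proba(X)[:, 1])
            se_dev = np.zeros(len(c_grid))
        C_star = _one_se_c(mean_dev, se_dev, c_grid)
        clf = LogisticRegression(l1_ratio=1.0, C=C_star, solver="liblinear",
                                 max_iter=500, tol=1e-4, random_state=0)
        clf.fit(X, y)
        preds[test] = clf.predict_proba(X_all[test])[:, 1]
        coef = clf.coef_.ravel()
        surviving[held] = [(cols[i], float(coef[i]))
                           for i in np.flatnonzero(np.abs(coef) > 1e-10)]

    pred_df = ft[["subject_id", "window_start_s", "label"]].copy()
    pred_df["probability"] = preds
    pooled = auc(preds, y_all)
    per_subject = {}
    for s in subjects:
        sel = sid == s
        ys = y_all[sel]
        per_subject[s] = auc(preds[sel], ys) \
            if ys.min() != ys.max() else np.nan
    return ClassifierReport(
        predictions=pred_df, pooled_auc=pooled,
        per_subject_auc=per_subject, surviving_features=surviving,
    )


# ---------------------------------------------------------------------------
# question runner


def build_question_features(index_by_subject: dict,
                            ann_by_subject: dict,
                            question: int, w: float, metric: str,
                            h: float, t_min: float | None = None,
                            zscore: bool = True) -> pd.DataFrame:
    """Labeled, z-scored feature table across subjects for one question."""
    parts = []
    for sid, idx in index_by_subject.items():
        lw = label_windows(ann_by_subject[sid], question, w, t_min)
        parts.append(build_features(idx, lw, sid, metric=metric, h=h))
    ft = pd.concat(parts, ignore_index=True)
    return zscore_by_subject(ft) if zscore else ft


@dataclass
class QuestionResult:
    question: int
    best_config: dict
    grid_table: pd.DataFrame
    reports: dict                   # modality -> ClassifierReport
    auc_diff_cis: dict              # modality -> (point, lo, hi, significant)


def run_question(index_by_subject: dict, ann_by_subject: dict,
                 question: int,
                 w_grid=W_GRID, h_grid=H_GRID, metrics=("mean", "median"),
                 t_grid=T_GRID_MIN, seed: int = 0,
                 n_boot: int = 1000) -> QuestionResult:
    """Sweep (w, metric, h[, t]), pick the best pooled AUC, run ablations.

    Ties in pooled AUC break toward the model with fewer surviving
    features.  For the best configuration, HRV-only, EDA-only and
    EDA-without-amplitude models are also fitted, with paired bootstrap
    CIs on the AUC difference vs the multimodal model.
    """
    if question not in (1, 2, 3, 4):
        raise ValueError("question must be 1, 2, 3, or 4")
    t_values = list(t_grid) if question in (2, 3) else [None]
    combos = [
        (w, metric, h, t)
        for w, metric, h, t in itertools.product(w_grid, metrics, h_grid,
                                                 t_values)
        if h % w == 0
    ]
    if not combos:
        raise ValueError("empty hyperparameter grid")

    rows = []
    best = None
    for w, metric, h, t in combos:
        ft = build_question_features(index_by_subject, ann_by_subject,
                                     question, w, metric, h, t)
        rep = loso_lasso_logistic(ft, seed=seed)
        rep.config = {"w": w, "metric": metric, "h": h, "t": t}
        rows.append({"w": w, "metric": metric, "h": h, "t": t,
                     "pooled_auc": rep.pooled_auc,
                     "mean_surviving": rep.n_surviving})
        key = (rep.pooled_auc, -rep.n_surviving)
        if best is None or key > best[0]:
            best = (key, rep, ft)
    _, best_rep, best_ft = best

    reports = {"multimodal": best_rep}
    cis = {}
    labels = best_ft["label"].to_numpy(int)
    sids = best_ft["subject_id"].to_numpy()
    for modality in ("hrv", "eda", "eda_no_amp"):
        sub = select_modality(best_ft, modality)
        rep = loso_lasso_logistic(sub, seed=seed)
        rep.config = dict(best_rep.config, modality=modality)
        reports[modality] = rep
        cis[modality] = auc_diff_ci(
            best_rep.predictions["probability"].to_numpy(),
            rep.predictions["probability"].to_numpy(),
            labels, sids, n_boot=n_boot, seed=seed)
    return QuestionResult(
        question=question, best_config=best_rep.config,
        grid_table=pd.DataFrame(rows), reports=reports, auc_diff_cis=cis,
    )
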