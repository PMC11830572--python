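"""Validation metrics and descriptive analyses: ROC/AUC, confusion
matrices, per-marker AUC, PCA, correlation, and survival stratification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class SurvivalFit:
    curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)
    logrank_chi2: float
    pvalue: float


def roc(scores, labels) -> RocResult:
    """ROC curve over all distinct score thresholds with trapezoidal AUC.

    Tied scores are grouped (producing diagonal segments), which makes the
    trapezoidal area identical to the rank-sum statistic U/(n+ * n-).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # group tied scores
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    group_idx = np.cumsum(distinct) - 1
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    last_of_group = np.r_[distinct[1:], True]
    tpr = np.r_[0.0, tp_cum[last_of_group] / n_pos]
    fpr = np.r_[0.0, fp_cum[last_of_group] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[last_of_group]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds, fpr, tpr, auc)


def confusion_at(scores, labels, threshold: float = 0.5) -> dict:
    """Confusion counts plus sensitivity/specificity at a score threshold
    (predict positive iff score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn,
            "sensitivity": sens, "specificity": spec}


def per_feature_auc(X: pd.DataFrame, y) -> pd.DataFrame:
    """Per-column AUC with explicit orientation.

    ``auc`` is the class-1-high orientation max(raw, 1 - raw); the
    ``orientation`` column records '+' when the raw AUC was >= 0.5, '-'
    when the feature scores anti-correlate with the label, and 'flat' for
    constant features (reported as 0.5).
    """
    y = np.asarray(y).astype(int)
    rows = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.all(v == v[0]):
            rows.append((col, 0.5, 0.5, "flat"))
            continue
        raw = roc(v, y).auc
        rows.append((col, raw, max(raw, 1 - raw), "+" if raw >= 0.5 else "-"))
    return pd.DataFrame(rows, columns=["feature", "auc_raw", "auc", "orientation"]
                        ).set_index("feature")


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


def top_variance(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k rows with largest sample variance (ddof=1); ties lexicographic."""
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds {len(matrix)} rows")
    var = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda r: (-var[r], r))
    return matrix.loc[order[:k]]


def pca(matrix: pd.DataFrame, n_components: int):
    """Column-centered SVD PCA of a samples x features matrix.

    Returns (scores, loadings, explained variance fractions); with all
    components the reconstruction scores @ loadings.T + mean is exact.
    """
    X = matrix.to_numpy(dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((S**2).sum())
    evr = (S**2 / total_var)[:n_components] if total_var > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].T
    return scores, loadings, evr


def dichotomize(values, rule="median") -> np.ndarray:
    """High/low split: high iff value > cutoff (strict; ties go low).

    ``rule`` is "median" or a quantile level in (0, 1); the cutoff is
    ``np.quantile(values, q)`` with linear interpolation.
    """
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 2:
        raise ValueError("all values identical; cannot dichotomize")
    q = 0.5 if rule == "median" else float(rule)
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    cut = np.quantile(v, q)
    return v > cut


def km_logrank(times, events, group) -> SurvivalFit:
    """Per-group Kaplan-Meier curves and the two-sample log-rank test.

    ``group`` is binary (False = low, True = high). Requires at least one
    event overall.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    group = np.asarray(group).astype(bool)
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if group.all() or not group.any():
        raise ValueError("both groups must be non-empty")
    if events.sum() == 0:
        raise ValueError("no events observed")
    curves = {}
    for lab, mask in (("low", ~group), ("high", group)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = logrank_test(times[~group], times[group], events[~group], events[group])
    return SurvivalFit(curves, float(res.test_statistic), float(res.p_value))
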