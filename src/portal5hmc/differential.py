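"""Differential hydroxymethylation calling between two groups.

The test is a negative-binomial Wald test on a log-link GLM with design
intercept + group indicator and log size-factor offsets, the model DESeq2
popularized for count data. Normalization uses median-of-ratios size
factors; per-region dispersions come from a method-of-moments estimate on
normalized counts with group means removed (no empirical-Bayes shrinkage,
no fold-change shrinkage — a stated approximation validated by simulation).
Auxiliary two-sample tests used in the downstream FPKM comparisons (Welch t,
Wilcoxon rank-sum) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LN2 = float(np.log(2.0))
ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0

#: presets for |log2FC| thresholds used in the two published contrasts
LFC_PRESETS = {"relaxed": 0.35, "strict": 0.5}


def size_factors(counts, fallback: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-region geometric mean over samples, computed on
    regions with nonzero counts in *all* samples; each sample's factor is
    the median of its count/reference ratios. With ``fallback=True`` the
    reference uses only a sample's nonzero entries per region (pseudo-
    reference for sparse matrices).
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any() and not fallback:
        raise ValueError(
            "no region has nonzero counts in every sample; re-run with "
            "fallback=True to use a pseudo-reference over nonzero entries"
        )
    if all_pos.any() and not fallback:
        sub = mat[all_pos]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        sf = np.median(sub / ref[:, None], axis=0)
    else:
        usable = (mat > 0).any(axis=1)
        if not usable.any():
            raise ValueError("count matrix is entirely zero")
        with np.errstate(divide="ignore"):
            logs = np.where(mat > 0, np.log(mat), np.nan)
        log_ref = np.full(mat.shape[0], -np.inf)
        log_ref[usable] = np.nanmean(logs[usable], axis=1)
        with np.errstate(invalid="ignore"):
            ratios = np.where(mat[usable] > 0,
                              mat[usable] / np.exp(log_ref[usable])[:, None], np.nan)
        sf = np.nanmedian(ratios, axis=0)
    if not np.all(np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("degenerate size factors; check for all-zero samples")
    return pd.Series(sf, index=counts.counts.columns, name="size_factor")


def estimate_dispersion(counts, sf: pd.Series, groups: pd.Series) -> pd.Series:
    """Per-region method-of-moments dispersion on normalized counts.

    Group means are removed before pooling:
    alpha = clip((pooled variance - pooled mean) / pooled mean^2,
    1e-8, 10).
    """
    mat = counts.counts.to_numpy(dtype=float)
    s = sf.reindex(counts.counts.columns).to_numpy()
    y = mat / s[None, :]
    groups = groups.reindex(counts.counts.columns)
    labels = groups.unique()
    n = y.shape[1]
    ss = np.zeros(y.shape[0])
    for lab in labels:
        cols = (groups == lab).to_numpy()
        if cols.sum() < 2:
            raise ValueError(f"group {lab!r} has < 2 samples")
        sub = y[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / (n - len(labels))
    pooled_mean = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, ALPHA_MIN)
    alpha = np.clip(alpha, ALPHA_MIN, ALPHA_MAX)
    return pd.Series(alpha, index=counts.counts.index, name="dispersion")


def _nb_irls(y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
             tol: float = 1e-8, max_iter: int = 100, beta_cap: float = 20.0):
    """Vectorized IRLS for R independent NB GLMs: log mu = offset + b0 + b1*x.

    y: (R, N) counts, x: (N,) 0/1 indicator, offset: (N,) log size factors,
    alpha: (R,) dispersions. Returns (b0, b1, se1, converged) with se from
    the expected Fisher information (weights mu/(1+alpha*mu)).
    """
    R, N = y.shape
    g0 = x == 0
    g1 = x == 1
    m0 = (y[:, g0] / np.exp(offset[g0])[None, :]).mean(axis=1)
    m1 = (y[:, g1] / np.exp(offset[g1])[None, :]).mean(axis=1)
    b0 = np.log(np.maximum(m0, 1e-3))
    b1 = np.log(np.maximum(m1, 1e-3)) - b0
    active = np.ones(R, dtype=bool)
    converged = np.zeros(R, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        eta = b0[idx, None] + b1[idx, None] * x[None, :] + offset[None, :]
        mu = np.exp(np.clip(eta, -50.0, 50.0))
        denom = 1.0 + alpha[idx, None] * mu
        w = mu / denom
        r = (y[idx] - mu) / denom
        U0 = r.sum(axis=1)
        U1 = r[:, g1].sum(axis=1)
        I00 = w.sum(axis=1)
        I01 = w[:, g1].sum(axis=1)
        I11 = I01
        det = I00 * I11 - I01 * I01
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        d0 = (I11 * U0 - I01 * U1) / det
        d1 = (I00 * U1 - I01 * U0) / det
        d0 = np.nan_to_num(np.clip(d0, -5.0, 5.0))
        d1 = np.nan_to_num(np.clip(d1, -5.0, 5.0))
        b0[idx] += d0
        b1[idx] += d1
        b1[idx] = np.clip(b1[idx], -beta_cap, beta_cap)
        done = (np.abs(d0) < tol) & (np.abs(d1) < tol)
        converged[idx[done]] = True
        active[idx[done]] = False
    # Fisher information at the final estimate
    eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
    mu = np.exp(np.clip(eta, -50.0, 50.0))
    w = mu / (1.0 + alpha[:, None] * mu)
    I00 = w.sum(axis=1)
    I11 = w[:, g1].sum(axis=1)
    I01 = I11
    det = I00 * I11 - I01 * I01
    with np.errstate(divide="ignore", invalid="ignore"):
        var1 = I00 / det
    se1 = np.sqrt(np.where((det > 0) & (var1 > 0), var1, np.inf))
    boundary = np.abs(b1) >= beta_cap - 1e-9
    converged &= ~boundary
    return b0, b1, se1, converged


def nb_wald_test(counts, sf: pd.Series, groups: pd.Series,
                 dispersions: pd.Series,
                 contrast: tuple[str, str] | None = None) -> pd.DataFrame:
    """Per-region NB Wald test of the group effect.

    ``groups`` must take exactly two values; ``contrast`` is
    (reference, alternative) — the reported effect is the log2 fold change
    of the alternative over the reference (sorted order when omitted).
    Returns a frame with baseMean, log2fc, lfcSE, wald_z, pvalue, padj
    (BH), the dispersion used, and flags. All-zero regions are flagged
    with p = 1 and log2fc = 0.
    """
    groups = groups.reindex(counts.counts.columns)
    labels = sorted(groups.unique()) if contrast is None else list(contrast)
    if len(labels) != 2 or set(labels) != set(groups.unique()):
        raise ValueError(f"need exactly the two groups present, got {labels}")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has < 2 samples")
    x = (groups == labels[1]).to_numpy().astype(float)
    s = sf.reindex(counts.counts.columns).to_numpy(dtype=float)
    y = counts.counts.to_numpy(dtype=float)
    alpha = dispersions.reindex(counts.counts.index).to_numpy(dtype=float)

    base_mean = (y / s[None, :]).mean(axis=1)
    allzero = y.sum(axis=1) == 0

    b0, b1, se1, converged = _nb_irls(y, x, np.log(s), alpha)

    log2fc = b1 / LN2
    lfc_se = se1 / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se1
    z = np.where(np.isfinite(z), z, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))

    log2fc[allzero] = 0.0
    z[allzero] = 0.0
    pval[allzero] = 1.0
    lfc_se[allzero] = np.inf
    converged = converged & ~allzero

    order = np.argsort(pval, kind="stable")
    padj = np.empty_like(pval)
    n = len(pval)
    ranked = pval[order] * n / (np.arange(n) + 1)
    padj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    padj = np.clip(padj, 0.0, 1.0)

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "lfcSE": lfc_se,
            "wald_z": z,
            "pvalue": pval,
            "padj": padj,
            "dispersion": alpha,
            "converged": converged,
            "allzero": allzero,
        },
        index=counts.counts.index,
    )


def call_dhmrs(results: pd.DataFrame, lfc_min: float = 0.5,
               p_max: float = 0.01) -> tuple[list[str], list[str]]:
    """Split significant regions into up- and down-regulated sets.

    Thresholds follow the published rule: |log2FC| >= lfc_min (inclusive)
    and p < p_max (strict). Presets 0.35 and 0.5 are in ``LFC_PRESETS``.
    """
    sig = results["pvalue"] < p_max
    up = results.index[sig & (results["log2fc"] >= lfc_min)].tolist()
    down = results.index[sig & (results["log2fc"] <= -lfc_min)].tolist()
    return up, down


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per sample")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for x over y, ties counted half) and two-sided p.

    Exact enumeration when n_x * n_y <= 1e4 and there are no ties;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) * len(y) <= 10_000 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
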