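"""Marker selection and model training.

The procedure mirrors the published machine-learning workflow: the
two-group cohort is split 2:1 into training and validation; differential
regions called on the training cohort enter recursive feature elimination
(RFE) under an L2-penalized, class-balanced logistic estimator with
internal 2-fold accuracy cross-validation; five rounds of stratified 4/5
subsampling, each with 100 re-seeded RFE repeats, yield per-round
selection frequencies, and markers observed in at least three of the five
rounds form the consensus panel used to train the final model.

Features entering selection are log2(normalized count + 1), z-scored with
training-cohort statistics only.

The logistic fits are performed by an in-house damped Newton solver (the
problem is strictly convex for lambda > 0); millions of small fits occur
inside the stability loop, so the solver is deliberately allocation-lean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

DEFAULT_LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, grad_norm: float, n_iter: int):
        super().__init__(f"{message} (|grad|_inf={grad_norm:.3g} after {n_iter} iters)")
        self.grad_norm = grad_norm
        self.n_iter = n_iter


@dataclass
class SplitSpec:
    train_fraction: float = 2.0 / 3.0
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ClassifierModel:
    """Penalized logistic model with frozen standardization parameters."""

    marker_ids: list[str]
    weights: np.ndarray
    intercept: float
    lam: float
    feature_center: np.ndarray
    feature_scale: np.ndarray
    class_weighting: str = "balanced"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.feature_center = np.asarray(self.feature_center, dtype=float)
        self.feature_scale = np.asarray(self.feature_scale, dtype=float)
        if len(self.weights) != len(self.marker_ids):
            raise ValueError("one weight per marker required")
        if np.any(self.feature_scale <= 0):
            raise ValueError("feature_scale must be positive")

    def decision(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.marker_ids].to_numpy(dtype=float) - self.feature_center) / self.feature_scale
        return self.intercept + Z @ self.weights

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.decision(X))

    def to_json(self) -> str:
        return json.dumps(
            {
                "marker_ids": self.marker_ids,
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "lambda": self.lam,
                "feature_center": self.feature_center.tolist(),
                "feature_scale": self.feature_scale.tolist(),
                "class_weighting": self.class_weighting,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            marker_ids=d["marker_ids"],
            weights=np.array(d["weights"]),
            intercept=d["intercept"],
            lam=d["lambda"],
            feature_center=np.array(d["feature_center"]),
            feature_scale=np.array(d["feature_scale"]),
            class_weighting=d.get("class_weighting", "balanced"),
        )


@dataclass
class MarkerPanel:
    """Consensus-selected markers with per-round observation bookkeeping."""

    marker_ids: list[str]  # retained (>= min_rounds), sorted
    rounds_observed: pd.Series  # per candidate feature
    frequencies: pd.DataFrame  # feature x round selection frequency
    min_rounds: int


# ---------------------------------------------------------------------------
# cohort split


def split_cohort(samples: pd.DataFrame, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Stratified random 2:1 split of a two-group sample table.

    Per-class training size is round(train_fraction * n_class)
    (round-half-even). Deterministic given ``spec.seed``.
    """
    groups = samples["group"]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 10]))
    train, valid = [], []
    if spec.stratified:
        strata = [(lab, sorted(samples.index[groups == lab])) for lab in labels]
    else:
        strata = [("all", sorted(samples.index))]
    for lab, ids in strata:
        if len(ids) < 3:
            raise ValueError(f"group {lab!r} has < 3 samples")
        n_train = int(round(spec.train_fraction * len(ids)))
        if n_train == 0 or n_train == len(ids):
            raise ValueError(f"group {lab!r}: split leaves an empty cohort")
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        valid.extend(ids[i] for i in perm[n_train:])
    return sorted(train), sorted(valid)


# ---------------------------------------------------------------------------
# penalized logistic core


def _class_weights(y: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "none":
        return np.ones(len(y))
    if scheme != "balanced":
        raise ValueError(f"unknown class_weighting {scheme!r}")
    n = len(y)
    n1 = y.sum()
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("constant label vector")
    return np.where(y == 1, n / (2.0 * n1), n / (2.0 * n0))


try:  # numba accelerates the million-fit stability loop; numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=False)
def _newton_jit(X, y, w, lam, b, max_iter, tol):  # pragma: no cover - mirrored below
    n, p = X.shape
    g = np.empty(p + 1)
    H = np.empty((p + 1, p + 1))
    f_cur = np.inf
    for _ in range(max_iter):
        eta = b[0] + X @ b[1:]
        phat = 1.0 / (1.0 + np.exp(-eta))
        r = w * (phat - y)
        g[0] = r.sum()
        g[1:] = X.T @ r + lam * b[1:]
        gnorm = np.abs(g).max()
        if gnorm < tol:
            return b, True
        W = w * phat * (1.0 - phat) + 1e-12
        WX = X * W.reshape(-1, 1)
        H[0, 0] = W.sum()
        for j in range(p):
            H[0, j + 1] = WX[:, j].sum()
            H[j + 1, 0] = H[0, j + 1]
        H[1:, 1:] = X.T @ WX
        for j in range(p):
            H[j + 1, j + 1] += lam
        step = np.linalg.solve(H, g)
        # objective at current point
        ll = 0.0
        for i in range(n):
            e = eta[i]
            if e > 0:
                ll += w[i] * (e + np.log1p(np.exp(-e)) - y[i] * e)
            else:
                ll += w[i] * (np.log1p(np.exp(e)) - y[i] * e)
        f_cur = ll + 0.5 * lam * (b[1:] @ b[1:])
        t = 1.0
        for _ls in range(30):
            bn = b - t * step
            etan = bn[0] + X @ bn[1:]
            lln = 0.0
            for i in range(n):
                e = etan[i]
                if e > 0:
                    lln += w[i] * (e + np.log1p(np.exp(-e)) - y[i] * e)
                else:
                    lln += w[i] * (np.log1p(np.exp(e)) - y[i] * e)
            fn = lln + 0.5 * lam * (bn[1:] @ bn[1:])
            if fn <= f_cur + 1e-12:
                break
            t *= 0.5
        b = bn
    eta = b[0] + X @ b[1:]
    phat = 1.0 / (1.0 + np.exp(-eta))
    r = w * (phat - y)
    g[0] = r.sum()
    g[1:] = X.T @ r + lam * b[1:]
    return b, np.abs(g).max() < tol * 100.0


def _fit_logistic_core(X: np.ndarray, y: np.ndarray, lam: float, w: np.ndarray,
                       tol: float = 1e-8, max_iter: int = 100, warm=None):
    """Damped Newton for weighted L2-logistic (intercept unpenalized).

    Minimizes sum_i w_i * log(1 + exp(-(2y_i-1) eta_i)) + lam/2 ||beta||^2.
    Returns (intercept, beta). ``warm`` optionally provides a starting
    (intercept, beta). Raises ConvergenceError if the gradient norm stays
    above tol*max(1, n) after max_iter damped steps.
    """
    n, p = X.shape
    if warm is not None:
        b0, beta = float(warm[0]), np.array(warm[1], dtype=float)
    else:
        b0, beta = 0.0, np.zeros(p)
    if _HAVE_NUMBA:
        b = np.empty(p + 1)
        b[0] = b0
        b[1:] = beta
        b, ok = _newton_jit(np.ascontiguousarray(X, dtype=np.float64),
                            np.ascontiguousarray(y, dtype=np.float64),
                            np.ascontiguousarray(w, dtype=np.float64),
                            float(lam), b, max_iter, tol * max(1.0, n))
        if not ok:
            raise ConvergenceError("logistic fit did not converge", np.nan, max_iter)
        return float(b[0]), b[1:]

    def objective(b0, beta):
        eta = b0 + X @ beta
        # log(1+e^eta) - y*eta, numerically stable
        ll = np.logaddexp(0.0, eta) - y * eta
        return float(w @ ll + 0.5 * lam * beta @ beta)

    f = objective(b0, beta)
    grad_norm = np.inf
    for it in range(max_iter):
        eta = b0 + X @ beta
        p_hat = expit(eta)
        r = w * (p_hat - y)
        g0 = r.sum()
        g = X.T @ r + lam * beta
        grad_norm = max(abs(g0), np.abs(g).max(initial=0.0))
        if grad_norm < 1e-8 * max(1.0, n):
            break
        W = w * p_hat * (1.0 - p_hat) + 1e-12
        WX = X * W[:, None]
        H = np.empty((p + 1, p + 1))
        H[0, 0] = W.sum()
        H[0, 1:] = WX.sum(axis=0)
        H[1:, 0] = H[0, 1:]
        H[1:, 1:] = X.T @ WX
        H[1:, 1:].flat[:: p + 1] += lam
        try:
            step = np.linalg.solve(H, np.concatenate([[g0], g]))
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, np.concatenate([[g0], g]), rcond=None)[0]
        t = 1.0
        for _ in range(30):
            nb0 = b0 - t * step[0]
            nbeta = beta - t * step[1:]
            nf = objective(nb0, nbeta)
            if nf <= f + 1e-12:
                break
            t *= 0.5
        b0, beta, f = nb0, nbeta, nf
    else:
        if grad_norm >= 1e-6 * max(1.0, n):
            raise ConvergenceError("logistic fit did not converge", grad_norm, max_iter)
    return b0, beta


def fit_penalized_logistic(X: pd.DataFrame, y: np.ndarray, lam: float,
                           class_weighting: str = "balanced") -> ClassifierModel:
    """Fit an L2-penalized weighted logistic model on pre-standardized
    features (identity standardization is recorded)."""
    y = np.asarray(y, dtype=float)
    w = _class_weights(y, class_weighting)
    b0, beta = _fit_logistic_core(X.to_numpy(dtype=float), y, lam, w)
    p = X.shape[1]
    return ClassifierModel(
        marker_ids=list(X.columns),
        weights=beta,
        intercept=b0,
        lam=lam,
        feature_center=np.zeros(p),
        feature_scale=np.ones(p),
        class_weighting=class_weighting,
    )


# ---------------------------------------------------------------------------
# cross-validated accuracy


def _stratified_folds(y: np.ndarray, folds: int, seed: int):
    """Deterministic shuffled stratified K-fold: per class, shuffle then
    deal round-robin into folds. Returns [(train_idx, test_idx), ...]."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    out = []
    for f in range(folds):
        test = np.where(fold_of == f)[0]
        train = np.where(fold_of != f)[0]
        out.append((train, test))
    return out


def cv_score(X: np.ndarray, y: np.ndarray, lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
             folds: int = 2, seed: int = 0,
             class_weighting: str = "balanced") -> tuple[float, dict[float, float]]:
    """Mean held-out accuracy per lambda over stratified folds.

    Returns (best lambda, {lambda: accuracy}); ties prefer the larger
    lambda (more regularization).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < folds:
        raise ValueError("each fold must contain both classes")
    splits = _stratified_folds(y, folds, seed)
    fold_w = [_class_weights(y[tr], class_weighting) for tr, _ in splits]
    scores = {}
    warm = [None] * folds
    for lam in sorted(lambda_grid, reverse=True):  # strong -> weak, warm-started
        acc = 0.0
        for k, (tr, te) in enumerate(splits):
            b0, beta = _fit_logistic_core(X[tr], y[tr], lam, fold_w[k], warm=warm[k])
            warm[k] = (b0, beta)
            pred = (b0 + X[te] @ beta) >= 0.0
            acc += float(np.mean(pred == (y[te] == 1)))
        scores[float(lam)] = acc / folds
    best = max(scores, key=lambda l: (scores[l], l))
    return best, scores


# ---------------------------------------------------------------------------
# recursive feature elimination


@dataclass
class RfeResult:
    selected_ids: list[str]
    accuracy_by_size: dict[int, float]
    ranking: dict[str, int]  # 1 = survives longest


def rfe(X: pd.DataFrame, y: np.ndarray, step_fraction: float = 0.1,
        folds: int = 2, lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
        seed: int = 0) -> RfeResult:
    """Recursive feature elimination under the penalized logistic estimator.

    At each size: pick lambda by CV accuracy, fit on all rows, drop the
    ceil(step_fraction * remaining) features with smallest |weight| (ties
    lexicographic on id). The selected set is the smallest size whose CV
    accuracy ties the maximum (tolerance 1e-12).
    """
    if X.shape[1] < 1:
        raise ValueError("need >= 1 feature")
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xfull = np.ascontiguousarray(X.to_numpy(dtype=float))
    cols = list(range(len(names)))
    w_full = _class_weights(y, "balanced")
    accuracy_by_size: dict[int, float] = {}
    sets_by_size: dict[int, list[int]] = {}
    ranking: dict[str, int] = {}
    elim_order: list[str] = []
    warm_fit = None

    while True:
        Xs = Xfull[:, cols]
        best_lam, scores = cv_score(Xs, y, lambda_grid, folds, seed)
        accuracy_by_size[len(cols)] = scores[best_lam]
        sets_by_size[len(cols)] = list(cols)
        if len(cols) == 1:
            break
        b0, beta = _fit_logistic_core(Xs, y, best_lam, w_full, warm=warm_fit)
        k = int(np.ceil(step_fraction * len(cols)))
        k = min(k, len(cols) - 1)
        order = sorted(range(len(cols)), key=lambda i: (np.abs(beta[i]), names[cols[i]]))
        dropped = sorted(order[:k], reverse=True)
        elim_order.extend(names[cols[i]] for i in order[:k])
        keep_pos = [i for i in range(len(cols)) if i not in set(order[:k])]
        warm_fit = (b0, beta[keep_pos])
        cols = [cols[i] for i in keep_pos]

    max_acc = max(accuracy_by_size.values())
    selected_size = min(s for s, a in accuracy_by_size.items() if a >= max_acc - 1e-12)
    selected = sorted(names[c] for c in sets_by_size[selected_size])

    elim_order.extend(names[c] for c in cols)  # survivors eliminated "last"
    for rank, feat in enumerate(reversed(elim_order), start=1):
        ranking[feat] = rank
    return RfeResult(selected, accuracy_by_size, ranking)


# ---------------------------------------------------------------------------
# stability consensus


def _stratified_subset(ids: list[str], y: pd.Series, fraction: float,
                       rng: np.random.Generator) -> list[str]:
    chosen = []
    for lab in sorted(y.unique()):
        lab_ids = sorted(i for i in ids if y[i] == lab)
        n_take = int(round(fraction * len(lab_ids)))
        n_take = max(2, min(n_take, len(lab_ids)))
        perm = rng.permutation(len(lab_ids))
        chosen.extend(lab_ids[i] for i in perm[:n_take])
    return sorted(chosen)


def panel_from_rounds(rounds_observed: pd.Series, min_rounds: int) -> list[str]:
    """The consensus rule: keep markers observed in >= min_rounds rounds."""
    return sorted(rounds_observed.index[rounds_observed >= min_rounds])


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Z-score columns; zero-variance columns get scale 1."""
    center = X.mean(axis=0).to_numpy()
    scale = X.std(axis=0, ddof=0).to_numpy()
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale
    return Z, center, scale


def stability_select(X_train: pd.DataFrame, y_train: pd.Series, n_rounds: int = 5,
                     round_fraction: float = 0.8, n_repeats: int = 100,
                     within_round_rule: float = 0.3, min_rounds: int = 3,
                     lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                     step_fraction: float = 0.1, folds: int = 2,
                     seed: int = 0) -> MarkerPanel:
    """Five-round stability consensus over repeated RFE.

    Each round draws a stratified ``round_fraction`` subset of the training
    cohort and runs RFE ``n_repeats`` times with distinct derived seeds; a
    marker is observed in the round iff selected in at least
    ``within_round_rule`` of the repeats (default 0.3 — "observed" denotes
    recurrent presence, not a majority; a majority rule collapses the panel
    onto the few strongest markers and discards the complementary ones the
    consensus is meant to keep). The panel keeps markers observed in >=
    ``min_rounds`` rounds. An empty panel is returned as-is (the caller
    decides any fallback).
    """
    features = list(X_train.columns)
    y_train = y_train.reindex(X_train.index)
    freq = pd.DataFrame(0.0, index=features,
                        columns=[f"round_{r + 1}" for r in range(n_rounds)])
    for r in range(n_rounds):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 20, r]))
        subset = _stratified_subset(list(X_train.index), y_train, round_fraction, rng)
        Xr = X_train.loc[subset]
        Zr, _, _ = standardize(Xr)
        yr = y_train.loc[subset].to_numpy(dtype=float)
        hits = pd.Series(0, index=features, dtype=int)
        for rep in range(n_repeats):
            rep_seed = int(
                np.random.SeedSequence([int(seed), 21, r, rep]).generate_state(1)[0]
                % (2**31)
            )
            res = rfe(Zr, yr, step_fraction=step_fraction, folds=folds,
                      lambda_grid=lambda_grid, seed=rep_seed)
            hits[res.selected_ids] += 1
        freq.iloc[:, r] = hits / n_repeats
    observed = (freq >= within_round_rule).sum(axis=1)
    panel = panel_from_rounds(observed, min_rounds)
    return MarkerPanel(panel, observed, freq, min_rounds)


# ---------------------------------------------------------------------------
# final model


def marker_features(counts, sf: pd.Series) -> pd.DataFrame:
    """Feature representation entering selection and the final model:
    log2(count / size_factor + 1), samples x regions."""
    s = sf.reindex(counts.counts.columns).to_numpy(dtype=float)
    norm = counts.counts.to_numpy(dtype=float) / s[None, :]
    return pd.DataFrame(np.log2(norm + 1.0).T,
                        index=counts.counts.columns, columns=counts.counts.index)


def train_final_model(X_train: pd.DataFrame, y_train: np.ndarray,
                      lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                      folds: int = 2, seed: int = 0,
                      class_weighting: str = "balanced") -> ClassifierModel:
    """Choose lambda by CV on the full training cohort, freeze training
    standardization, and fit the final penalized logistic model."""
    if X_train.shape[1] == 0:
        raise ValueError("empty marker panel")
    y = np.asarray(y_train, dtype=float)
    Z, center, scale = standardize(X_train)
    best_lam, _ = cv_score(Z.to_numpy(dtype=float), y, lambda_grid, folds, seed,
                           class_weighting)
    w = _class_weights(y, class_weighting)
    b0, beta = _fit_logistic_core(Z.to_numpy(dtype=float), y, best_lam, w)
    return ClassifierModel(
        marker_ids=list(X_train.columns),
        weights=beta,
        intercept=b0,
        lam=best_lam,
        feature_center=center,
        feature_scale=scale,
        class_weighting=class_weighting,
    )
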