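"""Nuisance-model learners and the discrete super learner.

Two candidate families are provided, matching the estimation toolchain of
the analysis: weighted main-effects logistic regression, and weighted
recursive partitioning (a CART-style probability tree grown on the Gini
criterion). A discrete super learner selects among candidates by v-fold
cross-validated weighted Bernoulli log-loss and refits the winner on the
full data.

All fits treat the sampling weights as relative: rescaling every weight by
a positive constant changes neither the fitted predictions nor the
cross-validation ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

logger = logging.getLogger("neopim")

#: Held-out predictions are clipped into this range before the log-loss so
#: degenerate (0/1) leaves yield a finite cross-validation risk.
RISK_CLIP = 1e-6
#: A fitted coefficient beyond this magnitude is treated as separation.
_SEPARATION_NORM = 30.0
_RIDGE_PENALTY = 1e-6


@dataclass(frozen=True)
class LearnerSpec:
    """A candidate learner: ``logistic_main_effects`` or ``recursive_partition``.

    The partitioning hyperparameters are in weight units relative to a mean-1
    weight scale, i.e. roughly row counts: a node is split only while its
    total weight is at least ``min_split``, each child keeps at least
    ``min_leaf``, depth stays below ``max_depth``, and the best split's
    relative Gini-impurity decrease exceeds ``complexity_threshold``.
    """

    kind: str = "logistic_main_effects"
    min_split: float = 20.0
    min_leaf: float = 7.0
    complexity_threshold: float = 0.01
    max_depth: int = 30

    def __post_init__(self) -> None:
        if self.kind not in ("logistic_main_effects", "recursive_partition"):
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if min(self.min_split, self.min_leaf) <= 0 or self.max_depth <= 0:
            raise ValueError("partition hyperparameters must be positive")
        if self.complexity_threshold < 0:
            raise ValueError("complexity_threshold must be >= 0")


LOGISTIC = LearnerSpec("logistic_main_effects")
PARTITION = LearnerSpec("recursive_partition")
#: Default discrete super-learner library.
DEFAULT_LIBRARY: tuple[LearnerSpec, ...] = (LOGISTIC, PARTITION)


@dataclass(frozen=True)
class CVConfig:
    v: int = 10
    seed: int = 0
    loss: str = "weighted_bernoulli_nll"

    def __post_init__(self) -> None:
        if self.v < 2:
            raise ValueError("v must be >= 2")
        if self.loss != "weighted_bernoulli_nll":
            raise ValueError(f"unknown loss {self.loss!r}")


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    return X


def _check_yw(y, w, n: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    if len(y) != n or len(w) != n:
        raise ValueError("X, y, weights must have equal length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary")
    return y, w / w.mean()


def weighted_bernoulli_nll(y, p, w=None, clip: float = RISK_CLIP) -> float:
    """Weighted Bernoulli negative log-likelihood (mean per unit weight)."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), clip, 1.0 - clip)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    return float(-np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))) / np.sum(w))


# --------------------------------------------------------------------------
# Weighted logistic regression
# --------------------------------------------------------------------------

class FittedLogistic:
    """Weighted main-effects logistic regression with a probability contract."""

    kind = "logistic_main_effects"

    def __init__(self, coef: np.ndarray, keep: np.ndarray, flags: dict):
        self._coef = coef  # intercept first
        self._keep = keep  # mask of non-constant columns used in the fit
        self.flags = flags

    @property
    def coef_(self) -> np.ndarray:
        return self._coef

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        return expit(self._coef[0] + X[:, self._keep] @ self._coef[1:])


def _ridge_logistic(Xc: np.ndarray, y: np.ndarray, w: np.ndarray,
                    lam: float = _RIDGE_PENALTY, maxiter: int = 500) -> np.ndarray:
    """Newton fit of the weighted logistic log-likelihood with a small L2
    penalty on the slopes; used when the unpenalised fit separates."""
    n, p = Xc.shape
    pen = np.full(p, lam)
    pen[0] = 0.0  # no penalty on the intercept
    beta = np.zeros(p)
    for _ in range(maxiter):
        eta = Xc @ beta
        mu = expit(eta)
        grad = Xc.T @ (w * (y - mu)) - pen * beta
        v = np.maximum(w * mu * (1 - mu), 1e-12)
        H = (Xc * v[:, None]).T @ Xc + np.diag(pen + 1e-10)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(grad)) < 1e-9 * n:
            break
    return beta


def fit_logistic(X, y, weights=None) -> FittedLogistic:
    """Maximise the weighted Bernoulli likelihood (main effects + intercept).

    A constant outcome returns the constant predictor with a degeneracy flag;
    separation or non-convergence falls back to a ridge-stabilised fit.
    """
    X = _as_matrix(X)
    y, w = _check_yw(y, weights, len(X))
    flags: dict = {"degenerate": False, "ridge_fallback": False}

    keep = X.std(axis=0) > 0
    if y.min() == y.max():
        flags["degenerate"] = True
        p = float(np.sum(w * y) / np.sum(w))
        coef = np.zeros(int(keep.sum()) + 1)
        coef[0] = np.log(max(p, 1e-12) / max(1 - p, 1e-12)) if 0 < p < 1 else (
            -500.0 if p == 0 else 500.0)
        return FittedLogistic(coef, keep, flags)

    Xk = X[:, keep]
    Xc = np.column_stack([np.ones(len(Xk)), Xk])
    coef = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xc, family=sm.families.Binomial(), freq_weights=w).fit(
                maxiter=100
            )
        if res.converged and np.max(np.abs(res.params)) < _SEPARATION_NORM:
            coef = np.asarray(res.params)
    except Exception:  # singular / separation
        coef = None
    if coef is None:
        flags["ridge_fallback"] = True
        logger.warning("logistic fit separated or failed to converge; ridge fallback used")
        coef = _ridge_logistic(Xc, y, w)
    return FittedLogistic(coef, keep, flags)


# --------------------------------------------------------------------------
# Weighted recursive partitioning
# --------------------------------------------------------------------------

class FittedPartition:
    """CART-style probability tree: weighted Gini splits, weighted-mean leaves."""

    kind = "recursive_partition"

    def __init__(self, spec: LearnerSpec):
        self.spec = spec
        self.feature: list[int] = []    # -1 for a leaf
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []
        self.flags: dict = {}

    def _add_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(np.nan)
        return len(self.feature) - 1

    @property
    def n_leaves(self) -> int:
        return sum(1 for f in self.feature if f == -1)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        out = np.empty(len(X))
        node_of = np.zeros(len(X), dtype=int)
        active = np.arange(len(X))
        while len(active):
            nodes = node_of[active]
            leaf_mask = np.array([self.feature[k] == -1 for k in nodes])
            done = active[leaf_mask]
            out[done] = [self.value[k] for k in node_of[done]]
            active = active[~leaf_mask]
            if not len(active):
                break
            nodes = node_of[active]
            feats = np.array([self.feature[k] for k in nodes])
            thrs = np.array([self.threshold[k] for k in nodes])
            go_left = X[active, feats] <= thrs
            node_of[active] = np.where(
                go_left,
                [self.left[k] for k in nodes],
                [self.right[k] for k in nodes],
            )
        return out


def _best_split(x: np.ndarray, y: np.ndarray, w: np.ndarray, min_leaf: float
                ) -> tuple[float, float] | None:
    """Best (impurity-decrease, threshold) for one column, or None.

    Thresholds are midpoints between adjacent distinct values, scanned in
    increasing order; the first threshold attaining the maximum wins.
    """
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], w[order]
    cw = np.cumsum(ws)
    cwy = np.cumsum(ws * ys)
    tot_w, tot_wy = cw[-1], cwy[-1]
    boundary = np.nonzero(np.diff(xs) > 0)[0]  # split after position i
    if not len(boundary):
        return None
    wl, wyl = cw[boundary], cwy[boundary]
    wr, wyr = tot_w - wl, tot_wy - wyl
    valid = (wl >= min_leaf) & (wr >= min_leaf)
    if not valid.any():
        return None
    wl, wyl, wr, wyr = wl[valid], wyl[valid], wr[valid], wyr[valid]
    bnd = boundary[valid]
    pl, pr = wyl / wl, wyr / wr
    p = tot_wy / tot_w
    parent = p * (1 - p)
    child = (wl * pl * (1 - pl) + wr * pr * (1 - pr)) / tot_w
    dec = parent - child
    k = int(np.argmax(dec))  # first max wins -> lower threshold on ties
    thr = 0.5 * (xs[bnd[k]] + xs[bnd[k] + 1])
    return float(dec[k]), thr


def fit_partition(X, y, weights=None, spec: LearnerSpec = PARTITION) -> FittedPartition:
    """Grow the weighted recursive partition greedily.

    Ties in the split search break toward the lower column index, then the
    lower threshold, so the fit is fully deterministic.
    """
    X = _as_matrix(X)
    y, w = _check_yw(y, weights, len(X))
    tree = FittedPartition(spec)

    def grow(rows: np.ndarray, depth: int) -> int:
        node = tree._add_node()
        wr_, yr_ = w[rows], y[rows]
        wtot = wr_.sum()
        p = float(np.sum(wr_ * yr_) / wtot)
        tree.value[node] = p
        impurity = p * (1 - p)
        if (depth >= spec.max_depth or wtot < spec.min_split or impurity <= 0.0):
            return node
        best = None  # (decrease, col, thr)
        for col in range(X.shape[1]):
            res = _best_split(X[rows, col], yr_, wr_, spec.min_leaf)
            if res is None:
                continue
            dec, thr = res
            if best is None or dec > best[0] + 1e-15:
                best = (dec, col, thr)
        if best is None or best[0] / impurity <= spec.complexity_threshold:
            return node
        _, col, thr = best
        go_left = X[rows, col] <= thr
        tree.feature[node] = col
        tree.threshold[node] = thr
        tree.left[node] = grow(rows[go_left], depth + 1)
        tree.right[node] = grow(rows[~go_left], depth + 1)
        return node

    grow(np.arange(len(X)), 0)
    return tree


# --------------------------------------------------------------------------
# Discrete super learner
# --------------------------------------------------------------------------

def fit_learner(spec: LearnerSpec, X, y, weights=None):
    if spec.kind == "logistic_main_effects":
        return fit_logistic(X, y, weights)
    return fit_partition(X, y, weights, spec)


def cv_folds(n: int, v: int, seed: int) -> list[np.ndarray]:
    """Near-equal folds from a seeded permutation; reproducible by (seed, n, v)."""
    if v > n:
        raise ValueError(f"v={v} exceeds n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, v)]


def cv_select(candidates: Sequence[LearnerSpec], X, y, weights=None,
              cv: CVConfig = CVConfig()):
    """Discrete super learner: v-fold CV risk, winner refit on all data.

    The winner is the candidate with the lowest held-out weighted Bernoulli
    negative log-likelihood (ties break toward the first candidate listed).
    A single candidate is fit directly without cross-validation. The fitted
    learner carries a ``cv_table`` attribute (kind, CV risk) for logging.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate learner")
    X = _as_matrix(X)
    y, w = _check_yw(y, weights, len(X))

    if len(candidates) == 1:
        fitted = fit_learner(candidates[0], X, y, w)
        fitted.cv_table = None
        fitted.cv_risk = None
        return fitted

    folds = cv_folds(len(y), cv.v, cv.seed)
    risks = []
    for spec in candidates:
        oof = np.empty(len(y))
        for test_idx in folds:
            train = np.setdiff1d(np.arange(len(y)), test_idx, assume_unique=False)
            fit = fit_learner(spec, X[train], y[train], w[train])
            oof[test_idx] = fit.predict(X[test_idx])
        risks.append(weighted_bernoulli_nll(y, oof, w))
    winner = int(np.argmin(risks))  # argmin returns the first minimum on ties
    table = pd.DataFrame({
        "kind": [s.kind for s in candidates],
        "cv_risk": risks,
        "selected": [i == winner for i in range(len(candidates))],
    })
    logger.info("super learner CV risks:\n%s", table.to_string(index=False))
    fitted = fit_learner(candidates[winner], X, y, w)
    fitted.cv_table = table
    fitted.cv_risk = float(risks[winner])
    return fitted
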