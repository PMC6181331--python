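"""Population-intervention attributable-risk estimators.

For each binary exposure A_j the target parameter is

    phi_j = E[Y_0^j] - E[Y],

the change in the mean outcome had everyone been unexposed to A_j (with
co-exposures left as they are). Four estimators are provided:

* ``naive``  — stratified difference using only the exposed proportion and
  the two category rates (no adjustment);
* ``gcomp``  — plug-in standardisation through the outcome model Q(A, W),
  bootstrap standard error;
* ``ipw``    — stabilised (Hajek) inverse-probability weighting through the
  propensity g_j(0 | co-exposures, W), a diagnostic estimator;
* ``tmle``   — targeted maximum likelihood: the initial Q fit is fluctuated
  along the clever covariate H = 1(A_j = 0)/g_j so the efficient
  influence-curve equation is solved exactly, giving double robustness and
  influence-curve standard errors.

Survey weights enter every stage (nuisance fits, fluctuation, empirical
means, variance) as relative weights, so all estimates are invariant to the
weight scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .learners import (
    CVConfig,
    LOGISTIC,
    LearnerSpec,
    PARTITION,
    cv_select,
    fit_learner,
)
from .records import AnalysisDataset

logger = logging.getLogger("neopim")

#: Propensities are truncated below at this bound before use (positivity).
DEFAULT_G_MIN = 0.01
#: Outcome-model predictions are clipped into [QCLIP, 1-QCLIP] before the
#: logit offset of the fluctuation (partition leaves can be exactly 0 or 1).
QCLIP = 1e-6
#: Raw propensity at or beyond these bounds marks a fully-determined stratum.
_DETERMINED_TOL = 1e-6


class EstimatorError(RuntimeError):
    pass


class PositivityError(EstimatorError):
    pass


class FluctuationError(EstimatorError):
    pass


@dataclass(frozen=True)
class LearnerConfig:
    """Candidate libraries for the nuisance fits.

    Defaults follow the analysis toolchain: logistic regression for the
    exposure (g) models and recursive partitioning for the outcome (Q)
    model. Pass several candidates to engage the discrete super learner.
    """

    g_candidates: tuple[LearnerSpec, ...] = (LOGISTIC,)
    q_candidates: tuple[LearnerSpec, ...] = (PARTITION,)


@dataclass
class PIMEstimate:
    exposure: str
    estimator: str                      # naive | gcomp | ipw | tmle
    phi: float                          # per-1 scale
    se: float = np.nan                  # per-1 scale
    mean_ic: float = np.nan
    n_truncated: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def phi_per_1000(self) -> float:
        return 1000.0 * self.phi

    @property
    def se_per_1000(self) -> float:
        return 1000.0 * self.se

    @property
    def z(self) -> float:
        return self.phi / self.se if self.se > 0 else np.nan

    @property
    def p_value(self) -> float:
        return float(2 * norm.sf(abs(self.z))) if np.isfinite(self.z) else np.nan

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        q = norm.ppf(0.5 + level / 2)
        return self.phi - q * self.se, self.phi + q * self.se


# --------------------------------------------------------------------------
# Naive stratified attributable risk
# --------------------------------------------------------------------------

def naive_par(p_exposed: float, rate_unexposed: float, rate_exposed: float) -> float:
    """Naive population attributable risk, per 1000.

    The unexposed-category rate minus the overall rate, where the overall
    rate is the prevalence-weighted average of the two category rates:
    ``1000 * (r0 - [p*r1 + (1-p)*r0]) = 1000 * p * (r0 - r1)``.
    """
    for v in (p_exposed, rate_unexposed, rate_exposed):
        if not 0.0 <= v <= 1.0:
            raise ValueError("inputs must be proportions in [0, 1]")
    # algebraically r0 - overall; this form is exactly 0 when r0 == r1
    return 1000.0 * p_exposed * (rate_unexposed - rate_exposed)


def naive_par_table(dataset: AnalysisDataset, use_weights: bool = True) -> pd.DataFrame:
    """Per-exposure naive attributable risk computed from the dataset."""
    w = dataset.weights if use_weights else np.ones(dataset.n)
    rows = []
    for j in dataset.exposure_set.members:
        a = dataset.A[j].to_numpy()
        p = float(np.sum(w * a) / np.sum(w))
        exp_m, une_m = a == 1, a == 0
        r1 = float(np.sum(w[exp_m] * dataset.y[exp_m]) / np.sum(w[exp_m])) if exp_m.any() else np.nan
        r0 = float(np.sum(w[une_m] * dataset.y[une_m]) / np.sum(w[une_m])) if une_m.any() else np.nan
        par = naive_par(p, r0, r1) if np.isfinite(r0) and np.isfinite(r1) else np.nan
        rows.append({"exposure": j, "p_exposed": p, "rate_unexposed": r0,
                     "rate_exposed": r1, "naive_par_per_1000": par})
    return pd.DataFrame(rows)


def naive_phi(dataset: AnalysisDataset, j: str, use_weights: bool = True) -> PIMEstimate:
    tab = naive_par_table(dataset, use_weights).set_index("exposure")
    return PIMEstimate(exposure=j, estimator="naive",
                       phi=float(tab.loc[j, "naive_par_per_1000"]) / 1000.0)


# --------------------------------------------------------------------------
# Nuisance fitting
# --------------------------------------------------------------------------

@dataclass
class NuisanceFits:
    """Fitted nuisance quantities for one exposure set.

    ``g0[j]`` is the truncated probability of being *unexposed* to j given
    the co-exposures and covariates; ``q_obs`` the outcome prediction at the
    observed exposures; ``q_cf[j]`` the prediction with A_j forced to 0.
    """

    g0: dict[str, np.ndarray]
    g0_raw_min: dict[str, float]
    g0_raw_max: dict[str, float]
    n_truncated: dict[str, int]
    g_learner: dict[str, str]
    q_obs: np.ndarray
    q_cf: dict[str, np.ndarray]
    q_learner: str
    g_min: float
    q_spec: LearnerSpec | None = None     # refittable spec for the bootstrap
    q_columns: list[str] | None = None
    cv_tables: dict = field(default_factory=dict)


def _design_q(dataset: AnalysisDataset) -> tuple[np.ndarray, list[str]]:
    cols = list(dataset.A.columns) + list(dataset.W.columns)
    X = np.column_stack([dataset.A.to_numpy(), dataset.W.to_numpy()]) \
        if dataset.W.shape[1] else dataset.A.to_numpy()
    return X, cols


def fit_nuisance(
    dataset: AnalysisDataset,
    learners: LearnerConfig = LearnerConfig(),
    cv: CVConfig = CVConfig(),
    g_min: float = DEFAULT_G_MIN,
    use_weights: bool = True,
    exposures: Sequence[str] | None = None,
) -> NuisanceFits:
    """Fit one propensity model per exposure and one shared outcome model.

    Each g_j regresses the indicator A_j = 0 on the *other* exposures in the
    set plus the covariates; Q regresses Y on all exposures plus covariates.
    Propensities are truncated below at ``g_min`` with the count recorded.
    ``exposures`` restricts the propensity fits to a subset of the set's
    members (the shared Q fit is unchanged).
    """
    w = dataset.weights if use_weights else np.ones(dataset.n)
    members = list(dataset.exposure_set.members)
    wanted = set(exposures) if exposures is not None else set(members)
    unknown = wanted - set(members)
    if unknown:
        raise ValueError(f"exposures {sorted(unknown)} not in the dataset's set")
    Amat = dataset.A.to_numpy()
    Wmat = dataset.W.to_numpy() if dataset.W.shape[1] else np.empty((dataset.n, 0))

    g0, rmin, rmax, ntrunc, gkind, cvtabs = {}, {}, {}, {}, {}, {}
    for k, j in enumerate(members):
        if j not in wanted:
            continue
        a = Amat[:, k]
        if a.min() == a.max():
            raise PositivityError(
                f"exposure {j!r} is constant in the data; the intervention "
                "parameter is unidentifiable (no positivity)"
            )
        co = np.delete(Amat, k, axis=1)
        Xg = np.column_stack([co, Wmat]) if (co.size or Wmat.size) else np.zeros((dataset.n, 1))
        fit = cv_select(learners.g_candidates, Xg, (a == 0).astype(float), w, cv)
        raw = fit.predict(Xg)
        rmin[j], rmax[j] = float(raw.min()), float(raw.max())
        ntrunc[j] = int(np.sum(raw < g_min))
        g0[j] = np.clip(raw, g_min, 1.0)
        gkind[j] = fit.kind
        if getattr(fit, "cv_table", None) is not None:
            cvtabs[f"g:{j}"] = fit.cv_table

    Xq, q_cols = _design_q(dataset)
    qfit = cv_select(learners.q_candidates, Xq, dataset.y, w, cv)
    q_obs = qfit.predict(Xq)
    q_cf = {}
    for k, j in enumerate(members):
        if j not in wanted:
            continue
        Xq0 = Xq.copy()
        Xq0[:, k] = 0.0
        q_cf[j] = qfit.predict(Xq0)
    if getattr(qfit, "cv_table", None) is not None:
        cvtabs["q"] = qfit.cv_table

    chosen_q_spec = next(s for s in learners.q_candidates if s.kind == qfit.kind)
    return NuisanceFits(
        g0=g0, g0_raw_min=rmin, g0_raw_max=rmax, n_truncated=ntrunc,
        g_learner=gkind, q_obs=q_obs, q_cf=q_cf, q_learner=qfit.kind,
        g_min=g_min, q_spec=chosen_q_spec, q_columns=q_cols, cv_tables=cvtabs,
    )


def positivity_report(nuisance: NuisanceFits) -> pd.DataFrame:
    """Truncation and determined-stratum diagnostics per exposure."""
    rows = []
    n = len(nuisance.q_obs)
    for j, g in nuisance.g0.items():
        rows.append({
            "exposure": j,
            "g0_raw_min": nuisance.g0_raw_min[j],
            "g0_raw_max": nuisance.g0_raw_max[j],
            "n_truncated": nuisance.n_truncated[j],
            "frac_truncated": nuisance.n_truncated[j] / n,
            "fully_determined_stratum": bool(
                nuisance.g0_raw_min[j] <= _DETERMINED_TOL
                or nuisance.g0_raw_max[j] >= 1.0 - _DETERMINED_TOL
            ),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Estimators
# --------------------------------------------------------------------------

def _norm_weights(dataset: AnalysisDataset, use_weights: bool) -> np.ndarray:
    w = dataset.weights if use_weights else np.ones(dataset.n)
    return w / w.mean()


def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def _ic_se(ic: np.ndarray, w: np.ndarray, cluster_id=None, variance: str = "iid") -> float:
    n = len(ic)
    if variance == "cluster" and cluster_id is not None:
        s = pd.Series(w * ic).groupby(pd.Series(np.asarray(cluster_id))).sum()
        return float(np.sqrt(np.sum(s.to_numpy() ** 2)) / n)
    m = _wmean(ic, w)
    var = _wmean((ic - m) ** 2, w)
    return float(np.sqrt(var / n))


def gcomp_phi(
    dataset: AnalysisDataset,
    nuisance: NuisanceFits,
    j: str,
    bootstrap: int = 500,
    seed: int = 0,
    use_weights: bool = True,
) -> PIMEstimate:
    """Plug-in (G-computation) estimate with a nonparametric bootstrap SE."""
    w = _norm_weights(dataset, use_weights)
    phi = _wmean(nuisance.q_cf[j], w) - _wmean(dataset.y, w)
    se = np.nan
    if bootstrap > 0 and nuisance.q_spec is not None:
        se = _gcomp_bootstrap(dataset, nuisance, [j], bootstrap, seed, use_weights)[j]
    return PIMEstimate(exposure=j, estimator="gcomp", phi=phi, se=se,
                       diagnostics={"q_learner": nuisance.q_learner,
                                    "bootstrap": bootstrap})


def _gcomp_bootstrap(dataset, nuisance, js: Sequence[str], B: int, seed: int,
                     use_weights: bool) -> dict[str, float]:
    """Bootstrap over rows (clusters, when present), refitting Q each draw
    with the CV-chosen learner spec."""
    rng = np.random.default_rng(seed)
    w = _norm_weights(dataset, use_weights)
    Xq, _ = _design_q(dataset)
    members = list(dataset.exposure_set.members)
    col_of = {j: members.index(j) for j in js}
    phis = {j: np.empty(B) for j in js}
    if dataset.cluster_id is not None:
        clusters = pd.Series(np.asarray(dataset.cluster_id))
        groups = [np.asarray(ix) for _, ix in
                  clusters.groupby(clusters, sort=True).groups.items()]
    else:
        groups = None
    n = dataset.n
    for b in range(B):
        if groups is not None:
            pick = rng.integers(0, len(groups), len(groups))
            idx = np.concatenate([groups[g] for g in pick])
        else:
            idx = rng.integers(0, n, n)
        fit = fit_learner(nuisance.q_spec, Xq[idx], dataset.y[idx], w[idx])
        wb = w[idx]
        for j in js:
            X0 = Xq[idx].copy()
            X0[:, col_of[j]] = 0.0
            phis[j][b] = (_wmean(fit.predict(X0), wb)
                          - _wmean(dataset.y[idx], wb))
    return {j: float(np.std(phis[j], ddof=1)) for j in js}


def ipw_phi(
    dataset: AnalysisDataset,
    nuisance: NuisanceFits,
    j: str,
    use_weights: bool = True,
) -> PIMEstimate:
    """Stabilised (Hajek) inverse-probability-weighted estimate.

    The SE treats the fitted propensity as known (diagnostic-grade)."""
    w = _norm_weights(dataset, use_weights)
    k = list(dataset.exposure_set.members).index(j)
    a = dataset.A.to_numpy()[:, k]
    g = nuisance.g0[j]
    ind = (a == 0).astype(float)
    h = ind / g
    den = _wmean(h, w)
    mu0 = _wmean(h * dataset.y, w) / den
    ybar = _wmean(dataset.y, w)
    phi = mu0 - ybar
    ic = h * (dataset.y - mu0) / den - (dataset.y - ybar)
    se = _ic_se(ic, w)
    return PIMEstimate(exposure=j, estimator="ipw", phi=phi, se=se,
                       mean_ic=_wmean(ic, w), n_truncated=nuisance.n_truncated[j],
                       diagnostics={"g_learner": nuisance.g_learner[j]})


def tmle_phi(
    dataset: AnalysisDataset,
    nuisance: NuisanceFits,
    j: str,
    use_weights: bool = True,
    variance: str = "iid",
    max_newton: int = 100,
) -> PIMEstimate:
    """Targeted maximum likelihood estimate of phi_j with IC inference.

    One fluctuation step: weighted logistic regression of Y on the clever
    covariate H = 1(A_j=0)/g_j with offset logit(Q), no intercept. The step
    solves the efficient influence-curve equation for this parameter, so no
    iteration is needed; the weighted mean IC is asserted to be ~0.
    """
    if variance not in ("iid", "cluster"):
        raise ValueError("variance must be 'iid' or 'cluster'")
    w = _norm_weights(dataset, use_weights)
    y = dataset.y
    k = list(dataset.exposure_set.members).index(j)
    a = dataset.A.to_numpy()[:, k]
    g = nuisance.g0[j]
    ind = (a == 0).astype(float)
    H = ind / g

    q_obs = np.clip(nuisance.q_obs, QCLIP, 1 - QCLIP)
    q_cf = np.clip(nuisance.q_cf[j], QCLIP, 1 - QCLIP)
    off_obs = logit(q_obs)

    # 1-D Newton for the fluctuation coefficient epsilon (concave problem).
    eps = 0.0
    n = len(y)
    converged = False
    for _ in range(max_newton):
        mu = expit(off_obs + eps * H)
        score = np.sum(w * H * (y - mu))
        if abs(score) < 1e-12 * n:
            converged = True
            break
        info = np.sum(w * H * H * mu * (1 - mu))
        if info <= 0:
            converged = abs(score) < 1e-10 * n
            break
        step = score / info
        eps += np.clip(step, -10.0, 10.0)
    if not converged:
        raise FluctuationError(
            f"fluctuation did not converge for exposure {j!r} "
            f"(score={score:.3e}, max|H|={H.max():.1f}, "
            f"n_truncated={nuisance.n_truncated[j]})"
        )

    q_star_obs = expit(off_obs + eps * H)
    q_star_cf = expit(logit(q_cf) + eps / g)   # counterfactual: a_j = 0 everywhere
    mu0 = _wmean(q_star_cf, w)
    ybar = _wmean(y, w)
    phi = mu0 - ybar

    ic = H * (y - q_star_obs) + q_star_cf - mu0 - (y - ybar)
    mean_ic = _wmean(ic, w)
    if abs(mean_ic) >= 1e-8:
        raise FluctuationError(
            f"influence-curve equation not solved for exposure {j!r}: "
            f"weighted mean IC = {mean_ic:.3e}"
        )
    se = _ic_se(ic, w, dataset.cluster_id, variance)
    return PIMEstimate(
        exposure=j, estimator="tmle", phi=phi, se=se, mean_ic=mean_ic,
        n_truncated=nuisance.n_truncated[j],
        diagnostics={"epsilon": eps, "g_learner": nuisance.g_learner[j],
                     "q_learner": nuisance.q_learner, "variance": variance},
    )


# --------------------------------------------------------------------------
# Per-set driver
# --------------------------------------------------------------------------

def estimate_exposure_set(
    dataset: AnalysisDataset,
    learners: LearnerConfig = LearnerConfig(),
    cv: CVConfig = CVConfig(),
    g_min: float = DEFAULT_G_MIN,
    estimators: Sequence[str] = ("naive", "gcomp", "ipw", "tmle"),
    gcomp_bootstrap: int = 500,
    seed: int = 0,
    use_weights: bool = True,
    nuisance_weights: bool | None = None,
    variance: str = "iid",
) -> tuple[list[PIMEstimate], NuisanceFits]:
    """All requested estimators for every exposure in the dataset's set.

    ``use_weights`` governs the estimation stage (empirical means,
    fluctuation, variances); ``nuisance_weights`` optionally overrides the
    weight use in the g/Q fits (defaults to the same setting).
    """
    if nuisance_weights is None:
        nuisance_weights = use_weights
    nuisance = fit_nuisance(dataset, learners, cv, g_min, nuisance_weights)
    members = list(dataset.exposure_set.members)
    boot_se: dict[str, float] = {}
    if "gcomp" in estimators and gcomp_bootstrap > 0:
        boot_se = _gcomp_bootstrap(dataset, nuisance, members, gcomp_bootstrap,
                                   seed, use_weights)
    out: list[PIMEstimate] = []
    for j in members:
        for tag in estimators:
            if tag == "naive":
                out.append(naive_phi(dataset, j, use_weights))
            elif tag == "gcomp":
                est = gcomp_phi(dataset, nuisance, j, bootstrap=0,
                                use_weights=use_weights)
                est.se = boot_se.get(j, np.nan)
                est.diagnostics["bootstrap"] = gcomp_bootstrap
                out.append(est)
            elif tag == "ipw":
                out.append(ipw_phi(dataset, nuisance, j, use_weights))
            elif tag == "tmle":
                out.append(tmle_phi(dataset, nuisance, j, use_weights, variance))
            else:
                raise ValueError(f"unknown estimator tag {tag!r}")
    return out, nuisance


def estimates_frame(estimates: Sequence[PIMEstimate]) -> pd.DataFrame:
    """Tabulate estimates (full precision; per-1000 columns included)."""
    rows = []
    for e in estimates:
        rows.append({
            "exposure": e.exposure,
            "estimator": e.estimator,
            "estimate_per_1000": e.phi_per_1000,
            "se_per_1000": e.se_per_1000,
            "test_statistic": abs(e.z) if np.isfinite(e.z) else np.nan,
            "p_value": e.p_value,
            "n_truncated": e.n_truncated,
        })
    return pd.DataFrame(rows)
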