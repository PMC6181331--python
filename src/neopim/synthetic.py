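"""Synthetic survey microdata with known counterfactual truth.

Generates mother-level records that mimic a national household survey of
recent live births: covariates drawn at the survey's published margins,
eight confounded binary risk exposures at their published prevalences, a
logistic neonatal-death model, and a two-stage stratified cluster design
with sampling weights.

Because the outcome model is known, the generator reports the *exact*
finite-population value of each intervention parameter
phi_j = E[Y with A_j set to 0] - E[Y], computed by averaging the outcome
probabilities over the generated rows with and without exposure j forced
to its unexposed level. Only the covariate/exposure draw is random; given
the rows, the truth has no Monte Carlo error. Co-exposures stay at their
generated values in the counterfactual, matching the one-exposure-at-a-time
definition of the parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq, root
from scipy.special import expit, logit

from .records import (
    CATEGORICAL_LEVELS,
    EXPOSURES,
    SchemaError,
)


class CalibrationError(RuntimeError):
    """A marginal target is unreachable with the given structural constraints."""


# --------------------------------------------------------------------------
# Default configuration: survey-published margins
# --------------------------------------------------------------------------

#: Covariate category probabilities (published sample margins).
DEFAULT_COVARIATE_PROBS: dict[str, dict[str, float]] = {
    "region": {"North": 0.1817, "Central": 0.3469, "South": 0.4713},
    "residence": {"urban": 0.1594, "rural": 0.8406},
    "mother_age_group": {
        "15-19": 0.1100, "20-24": 0.3153, "25-29": 0.2242,
        "30-34": 0.1798, "35-39": 0.1146, "40-49": 0.0561,
    },
    "mother_education": {"none": 0.1131, "primary": 0.6682, "secondary": 0.2007, "higher": 0.0180},
    "hh_head_sex": {"male": 0.7572, "female": 0.2428},
    "wealth_quintile": {
        "poorest": 0.2297, "poorer": 0.2188, "middle": 0.1965,
        "richer": 0.1823, "richest": 0.1727,
    },
    "child_sex": {"male": 0.5044, "female": 0.4956},
    "child_size_recall": {
        "very large": 0.0854, "larger than average": 0.2545, "average": 0.5026,
        "smaller than average": 0.1170, "very small": 0.0406,
    },
}

#: Marginal exposed proportions (published).
DEFAULT_EXPOSURE_PREVALENCE: dict[str, float] = {
    "IDELIV": 0.064,
    "SBA": 0.079,
    "ANC4": 0.496,
    "FP_UNMET": 0.166,
    "SHORT_INTERVAL": 0.079,
    "FIRST_PREG": 0.259,
    "TWO_PLUS_5Y": 0.364,
    "PREV_NNM": 0.009,
}

#: Log-odds slopes of each exposure on the confounder indicators (rural
#: residence, education, wealth): exposure risk is higher in rural, less
#: educated and poorer households. Shared across exposures by default.
DEFAULT_CONFOUNDER_SLOPES: dict[str, float] = {
    "residence_rural": 0.5,
    "mother_education_primary": -0.3,
    "mother_education_secondary": -0.7,
    "mother_education_higher": -1.1,
    "wealth_quintile_poorer": -0.15,
    "wealth_quintile_middle": -0.3,
    "wealth_quintile_richer": -0.5,
    "wealth_quintile_richest": -0.9,
}

#: Covariate effects on the neonatal-death log-odds.
DEFAULT_OUTCOME_GAMMAS: dict[str, float] = {
    "residence_rural": 0.25,
    "mother_education_primary": -0.15,
    "mother_education_secondary": -0.35,
    "mother_education_higher": -0.60,
    "wealth_quintile_poorer": -0.05,
    "wealth_quintile_middle": -0.10,
    "wealth_quintile_richer": -0.20,
    "wealth_quintile_richest": -0.30,
    "child_sex_female": -0.15,
    "child_size_recall_smaller than average": 0.35,
    "child_size_recall_very small": 0.90,
}

#: Target overall neonatal mortality (per 1) and the intervention-parameter
#: targets (per 1000) the default outcome coefficients are calibrated to.
DEFAULT_TARGET_RATE = 0.0185
DEFAULT_PHI_TARGETS_PER_1000: dict[str, float] = {
    "IDELIV": -1.3,
    "SBA": -1.6,
    "ANC4": -2.1,
    "FP_UNMET": -1.2,
    "SHORT_INTERVAL": -1.3,
    "FIRST_PREG": -3.9,
    "TWO_PLUS_5Y": -3.2,
    "PREV_NNM": -0.2,
}

# Outcome-model coefficients calibrated once (calibrate_outcome_betas, seed
# 20180, n = 400000) so the finite-population truth hits the targets above.
DEFAULT_OUTCOME_INTERCEPT = -4.817297
DEFAULT_OUTCOME_BETAS: dict[str, float] = {
    "IDELIV": 0.755273,
    "SBA": 0.758995,
    "ANC4": 0.223614,
    "FP_UNMET": 0.331231,
    "SHORT_INTERVAL": 0.790217,
    "FIRST_PREG": 0.736520,
    "TWO_PLUS_5Y": 0.439778,
    "PREV_NNM": 0.756066,
}


@dataclass(frozen=True)
class DesignConfig:
    """Two-stage stratified cluster design: strata are region x residence;
    enumeration areas (clusters) are drawn probability-proportional-to-size
    at the first stage; households within a sampled cluster are taken at a
    per-stratum fraction at the second stage.

    A record's weight is the inverse of its overall inclusion probability
    pi_cluster * pi_within, normalised to mean 1. ``within_fraction`` may be
    a single number or a mapping keyed by residence type (unequal fractions
    produce inversely proportional weights across strata).
    """

    clusters_per_stratum: int = 60          # frame clusters per stratum
    cluster_size_range: tuple[int, int] = (80, 320)
    cluster_fraction: float = 0.3           # share of frame clusters sampled
    within_fraction: float | Mapping[str, float] = 0.25

    def within(self, residence: str) -> float:
        if isinstance(self.within_fraction, Mapping):
            return float(self.within_fraction.get(str(residence), 0.25))
        return float(self.within_fraction)


@dataclass(frozen=True)
class GeneratorConfig:
    covariate_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_COVARIATE_PROBS
    )
    exposure_prevalence: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_EXPOSURE_PREVALENCE
    )
    confounder_slopes: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_CONFOUNDER_SLOPES
    )
    #: per-exposure multiplier on the confounder slopes (0 = no confounding)
    confounding_scale: Mapping[str, float] = field(default_factory=dict)
    outcome_intercept: float = DEFAULT_OUTCOME_INTERCEPT
    outcome_betas: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_BETAS)
    )
    outcome_gammas: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_OUTCOME_GAMMAS
    )
    design: DesignConfig = field(default_factory=DesignConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, probs in self.covariate_probs.items():
            p = np.array(list(probs.values()), dtype=float)
            if (p <= 0).any() or (p >= 1).any():
                raise ValueError(f"covariate_probs[{name!r}] must lie in (0,1)")
            if not np.isclose(p.sum(), 1.0, atol=5e-3):
                raise ValueError(f"covariate_probs[{name!r}] must sum to 1")
        for name, p in self.exposure_prevalence.items():
            if not 0 < p < 1:
                raise ValueError(f"exposure_prevalence[{name!r}] must lie in (0,1)")

    def slope_scale(self, exposure: str) -> float:
        return float(self.confounding_scale.get(exposure, 1.0))


@dataclass(frozen=True)
class TruthReport:
    """Generator-side truth: exact finite-population E[Y] and phi_j."""

    e_y: float
    phi: dict[str, float]            # per-1 scale
    betas: dict[str, float]
    intercept: float
    seed: int | None
    n: int

    @property
    def phi_per_1000(self) -> dict[str, float]:
        return {k: 1000.0 * v for k, v in self.phi.items()}


# --------------------------------------------------------------------------
# Internal encoding (full schema dummies, no constant-column dropping, so the
# generator and compute_truth agree on any n)
# --------------------------------------------------------------------------

def _encode_full(df: pd.DataFrame) -> pd.DataFrame:
    blocks = []
    for name, levels in CATEGORICAL_LEVELS.items():
        cat = pd.Categorical(df[name], categories=levels)
        dummies = pd.get_dummies(cat, prefix=name, dtype=float).iloc[:, 1:]
        dummies.index = df.index
        blocks.append(dummies)
    return pd.concat(blocks, axis=1)


def _linear(W: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    lp = np.zeros(len(W))
    for col, c in coefs.items():
        if col in W.columns:
            lp += c * W[col].to_numpy()
    return lp


def _solve_intercept(lp: np.ndarray, eligible: np.ndarray, forced_mass: float,
                     target: float, name: str) -> float:
    """Intercept c with forced_mass + mean(eligible * expit(c + lp)) = target."""
    elig_lp = lp[eligible]
    frac = len(elig_lp) / len(lp)

    def f(c: float) -> float:
        return forced_mass + frac * float(np.mean(expit(c + elig_lp))) - target

    lo, hi = f(-30.0), f(30.0)
    if not lo < 0 < hi:
        raise CalibrationError(
            f"exposure {name!r}: target prevalence {target} unreachable; "
            f"achievable range is ({forced_mass + lo + target - forced_mass:.4f}, "
            f"{forced_mass + frac:.4f})"
        )
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _draw_exposures(W: pd.DataFrame, config: GeneratorConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw the eight exposures, each Bernoulli in its covariate logit.

    Exposures are conditionally independent given the covariates — the
    shared confounder slopes induce the marginal correlations (e.g. between
    non-institutional delivery and unskilled attendance) without creating
    exposure-to-exposure causal paths, so the one-exposure-at-a-time
    parameter stays identifiable from any subset of co-exposures. The one
    structural exception is the schema's hard constraint: a preceding birth
    interval exists only for non-first pregnancies, so SHORT_INTERVAL is
    drawn among non-first rows (its marginal prevalence still hits the
    target).
    """
    n = len(W)
    prev = config.exposure_prevalence
    A = pd.DataFrame(index=W.index)

    def bern(p: np.ndarray) -> np.ndarray:
        return (rng.random(n) < p).astype(float)

    def draw(name: str, eligible: np.ndarray) -> np.ndarray:
        lp = config.slope_scale(name) * _linear(W, config.confounder_slopes)
        c = _solve_intercept(lp, eligible, 0.0, prev[name], name)
        a = bern(expit(c + lp))
        a[~eligible] = 0.0
        return a

    all_rows = np.ones(n, dtype=bool)
    A["FIRST_PREG"] = draw("FIRST_PREG", all_rows)
    not_first = A["FIRST_PREG"].to_numpy() == 0
    A["IDELIV"] = draw("IDELIV", all_rows)
    A["SBA"] = draw("SBA", all_rows)
    A["ANC4"] = draw("ANC4", all_rows)
    A["FP_UNMET"] = draw("FP_UNMET", all_rows)
    A["SHORT_INTERVAL"] = draw("SHORT_INTERVAL", not_first)
    A["TWO_PLUS_5Y"] = draw("TWO_PLUS_5Y", all_rows)
    A["PREV_NNM"] = draw("PREV_NNM", all_rows)
    return A[list(EXPOSURES)]


def _raw_fields(A: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Raw record fields consistent with the drawn exposures."""
    n = len(A)
    raw = pd.DataFrame(index=A.index)
    exposed_anc = A["ANC4"].to_numpy() == 1
    visits = np.where(
        exposed_anc,
        rng.choice([0, 1, 2, 3], size=n, p=[0.10, 0.20, 0.30, 0.40]),
        rng.choice([4, 5, 6, 7, 8], size=n, p=[0.45, 0.30, 0.15, 0.07, 0.03]),
    )
    raw["anc_visits"] = visits
    raw["facility_delivery"] = 1.0 - A["IDELIV"]
    raw["skilled_attendant"] = 1.0 - A["SBA"]
    raw["fp_need_unmet"] = A["FP_UNMET"]
    raw["first_pregnancy"] = A["FIRST_PREG"]

    first = A["FIRST_PREG"].to_numpy() == 1
    short = A["SHORT_INTERVAL"].to_numpy() == 1
    interval = np.where(short, rng.integers(8, 25, n), rng.integers(25, 227, n)).astype(float)
    interval[first] = np.nan
    raw["preceding_interval_months"] = interval

    two_plus = A["TWO_PLUS_5Y"].to_numpy() == 1
    extra = rng.geometric(0.7, n) - 1  # 0,1,2,... extra outcomes beyond two
    raw["outcomes_last_5y"] = np.where(two_plus, 2 + extra, 1)
    raw["prior_neonatal_death"] = A["PREV_NNM"]
    return raw


def compute_truth(records: pd.DataFrame, config: GeneratorConfig,
                  seed: int | None = None) -> TruthReport:
    """Exact finite-population truth for the given rows under the config's
    outcome model (usable to re-verify a generated dataset)."""
    from .records import derive_exposure_matrix

    A = derive_exposure_matrix(records)
    W = _encode_full(records)
    betas = dict(config.outcome_betas)
    lp = config.outcome_intercept + _linear(W, config.outcome_gammas)
    for j, b in betas.items():
        lp = lp + b * A[j].to_numpy()
    p = expit(lp)
    phi = {}
    for j, b in betas.items():
        p0 = expit(lp - b * A[j].to_numpy())
        phi[j] = float(np.mean(p0) - np.mean(p))
    return TruthReport(
        e_y=float(np.mean(p)), phi=phi, betas=betas,
        intercept=config.outcome_intercept, seed=seed, n=len(records),
    )


# --------------------------------------------------------------------------
# Main entry points
# --------------------------------------------------------------------------

def simulate_population(
    config: GeneratorConfig | None = None,
    n: int = 10_000,
    seed: int | None = None,
    with_design: bool = True,
) -> tuple[pd.DataFrame, TruthReport]:
    """Generate ``n`` records and the exact truth report.

    A single seed drives the whole call; each generation stage draws from its
    own deterministically-derived substream, so adding a stage never perturbs
    the draws of earlier stages.
    """
    config = config or GeneratorConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_cov, rng_exp, rng_raw, rng_y, rng_design = (
        np.random.default_rng(s) for s in streams
    )

    cov = pd.DataFrame(index=pd.RangeIndex(n))
    for name, probs in config.covariate_probs.items():
        levels = list(probs)
        p = np.array([probs[l] for l in levels], dtype=float)
        cov[name] = rng_cov.choice(levels, size=n, p=p / p.sum())

    W = _encode_full(cov)
    A = _draw_exposures(W, config, rng_exp)
    raw = _raw_fields(A, rng_raw)

    lp = config.outcome_intercept + _linear(W, config.outcome_gammas)
    betas = dict(config.outcome_betas)
    for j, b in betas.items():
        lp = lp + b * A[j].to_numpy()
    p_y = expit(lp)
    y = (rng_y.random(n) < p_y).astype(int)

    phi = {}
    for j, b in betas.items():
        p0 = expit(lp - b * A[j].to_numpy())
        phi[j] = float(np.mean(p0) - np.mean(p_y))
    truth = TruthReport(e_y=float(np.mean(p_y)), phi=phi, betas=betas,
                        intercept=config.outcome_intercept, seed=seed, n=n)

    records = pd.concat([raw, cov], axis=1)
    records.insert(0, "neonatal_death", y)
    if with_design:
        records = assign_design(records, config, rng=rng_design)
    else:
        records["weight"] = 1.0
        records["stratum_id"] = "all"
        records["cluster_id"] = "all:0"
    return records, truth


def pps_systematic(sizes: np.ndarray, m: int, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Systematic probability-proportional-to-size draw of ``m`` clusters.

    Returns (selected indices, inclusion probabilities min(1, m*size/total)).
    """
    sizes = np.asarray(sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    total = sizes.sum()
    step = total / m
    start = rng.uniform(0.0, step)
    points = start + step * np.arange(m)
    cum = np.cumsum(sizes)
    sel = np.unique(np.searchsorted(cum, points, side="right"))
    sel = sel[sel < len(sizes)]
    pi = np.minimum(1.0, m * sizes / total)
    return sel, pi


def assign_design(records: pd.DataFrame, config: GeneratorConfig | None = None,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Attach stratum_id, cluster_id and sampling weight.

    Strata are region x residence. Within each stratum a frame of enumeration
    areas is drawn, ``round(f * M)`` of them sampled PPS, and the stratum's
    records spread evenly over the sampled areas. The weight is the inverse
    overall inclusion probability, normalised to mean 1.
    """
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    design = config.design
    if design.clusters_per_stratum < 1:
        raise ValueError("clusters per stratum must be >= 1")
    lo, hi = design.cluster_size_range
    if lo < 1:
        raise ValueError("cluster sizes must be positive")

    out = records.copy()
    out["stratum_id"] = out["region"].astype(str) + ":" + out["residence"].astype(str)
    out["cluster_id"] = ""
    out["weight"] = np.nan

    for stratum, idx in out.groupby("stratum_id", sort=True).groups.items():
        idx = np.asarray(idx)
        residence = out.loc[idx[0], "residence"]
        f_within = design.within(residence)
        if not 0 < f_within <= 1:
            raise ValueError("within-cluster sampling fraction must lie in (0, 1]")
        M = design.clusters_per_stratum
        sizes = rng.integers(lo, hi + 1, M).astype(float)
        m = max(1, int(round(design.cluster_fraction * M)))
        sel, pi = pps_systematic(sizes, m, rng)
        # allocate the stratum's records over the sampled clusters in
        # proportion to cluster size (consistent with an equal within-cluster
        # take fraction); largest-remainder rounding
        share = sizes[sel] / sizes[sel].sum()
        counts = np.floor(share * len(idx)).astype(int)
        rem = len(idx) - counts.sum()
        if rem > 0:
            frac = share * len(idx) - counts
            counts[np.argsort(-frac)[:rem]] += 1
        order = rng.permutation(len(idx))
        start = 0
        for ci, cnt in zip(sel, counts):
            if cnt == 0:
                continue
            rows = idx[order[start:start + cnt]]
            start += cnt
            out.loc[rows, "cluster_id"] = f"{stratum}:{ci}"
            out.loc[rows, "weight"] = 1.0 / (pi[ci] * f_within)

    w = out["weight"].to_numpy(dtype=float)
    out["weight"] = w / np.nanmean(w)
    return out


#: Fields inject_missingness may blank; outcome and design fields never are.
MISSINGNESS_ELIGIBLE: tuple[str, ...] = (
    "anc_visits", "facility_delivery", "skilled_attendant", "fp_need_unmet",
    "preceding_interval_months", "first_pregnancy", "outcomes_last_5y",
    "prior_neonatal_death",
) + tuple(CATEGORICAL_LEVELS)


def inject_missingness(records: pd.DataFrame,
                       rate_per_field: float | Mapping[str, float],
                       seed: int = 0) -> pd.DataFrame:
    """Independently blank eligible fields at the stated per-field rate."""
    rng = np.random.default_rng(seed)
    if not isinstance(rate_per_field, Mapping):
        rate_per_field = {f: float(rate_per_field) for f in MISSINGNESS_ELIGIBLE}
    out = records.copy()
    for fieldname, rate in rate_per_field.items():
        if fieldname not in MISSINGNESS_ELIGIBLE:
            raise SchemaError(f"field {fieldname!r} is not eligible for missingness")
        if not 0.0 <= rate <= 1.0:
            raise ValueError("missingness rate must lie in [0, 1]")
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        if out[fieldname].dtype.kind in "iub":
            out[fieldname] = out[fieldname].astype(float)
        out.loc[mask, fieldname] = np.nan
    return out


# --------------------------------------------------------------------------
# Outcome-model calibration
# --------------------------------------------------------------------------

def calibrate_outcome_betas(
    config: GeneratorConfig | None = None,
    targets_per_1000: Mapping[str, float] | None = None,
    target_rate: float = DEFAULT_TARGET_RATE,
    n: int = 400_000,
    seed: int = 20180,
) -> tuple[float, dict[str, float]]:
    """Solve the outcome intercept and exposure log-odds coefficients so the
    finite-population truth matches the stated phi targets and overall rate.

    The covariate/exposure draw is held fixed while the root-finder moves the
    coefficients; the returned values are frozen as package defaults.
    """
    config = config or GeneratorConfig()
    targets = dict(targets_per_1000 or DEFAULT_PHI_TARGETS_PER_1000)
    names = list(targets)

    streams = np.random.SeedSequence(seed).spawn(2)
    rng_cov, rng_exp = (np.random.default_rng(s) for s in streams)
    cov = pd.DataFrame(index=pd.RangeIndex(n))
    for name, probs in config.covariate_probs.items():
        levels = list(probs)
        p = np.array([probs[l] for l in levels], dtype=float)
        cov[name] = rng_cov.choice(levels, size=n, p=p / p.sum())
    W = _encode_full(cov)
    A = _draw_exposures(W, config, rng_exp)
    Amat = A[names].to_numpy()
    gamma_lp = _linear(W, config.outcome_gammas)

    def residuals(theta: np.ndarray) -> np.ndarray:
        b0, b = theta[0], theta[1:]
        lp = b0 + gamma_lp + Amat @ b
        p = expit(lp)
        res = [np.mean(p) - target_rate]
        for k, j in enumerate(names):
            p0 = expit(lp - b[k] * Amat[:, k])
            res.append(1000.0 * (np.mean(p0) - np.mean(p)) - targets[j])
        return np.array(res)

    # crude start: intercept near logit of the target rate, harmful betas
    x0 = np.concatenate([[logit(target_rate) - 0.3], np.full(len(names), 0.5)])
    sol = root(residuals, x0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(residuals(sol.x))) > 1e-6:
        raise CalibrationError(f"outcome-model calibration failed: {sol.message}")
    return float(sol.x[0]), {j: float(v) for j, v in zip(names, sol.x[1:])}


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_truth(truth: TruthReport, path) -> None:
    payload = {
        "n": truth.n,
        "seed": truth.seed,
        "e_y": truth.e_y,
        "phi_per_1000": truth.phi_per_1000,
        "intercept": truth.intercept,
        "betas": truth.betas,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_truth(path) -> TruthReport:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    phi = {k: v / 1000.0 for k, v in payload["phi_per_1000"].items()}
    return TruthReport(
        e_y=float(payload["e_y"]), phi=phi, betas=dict(payload["betas"]),
        intercept=float(payload["intercept"]), seed=payload.get("seed"),
        n=int(payload["n"]),
    )
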