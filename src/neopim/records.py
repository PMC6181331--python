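"""Microdata schema, exposure recoding and analysis-dataset construction.

One row of input data describes a mother's most recent live birth within the
survey recall window: the binary neonatal-death outcome, the raw fields from
which eight binary risk exposures are derived, socio-demographic covariates,
and the survey design variables (sampling weight, stratum and cluster ids).

Exposures are coded 1 = exposed (high risk / lacked the service) and
0 = unexposed, so that the population-intervention parameter
phi = E[Y_0] - E[Y] is negative for a harmful exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("neopim")


class SchemaError(ValueError):
    """Input record violates the microdata schema."""


# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

#: Fixed level order for every categorical covariate; the first level is the
#: reference cell in the indicator encoding.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "region": ("North", "Central", "South"),
    "residence": ("urban", "rural"),
    "mother_age_group": ("15-19", "20-24", "25-29", "30-34", "35-39", "40-49"),
    "mother_education": ("none", "primary", "secondary", "higher"),
    "hh_head_sex": ("male", "female"),
    "wealth_quintile": ("poorest", "poorer", "middle", "richer", "richest"),
    "child_sex": ("male", "female"),
    "child_size_recall": (
        "very large",
        "larger than average",
        "average",
        "smaller than average",
        "very small",
    ),
}

#: All covariate fields usable in a covariate_spec.
COVARIATE_FIELDS: tuple[str, ...] = tuple(CATEGORICAL_LEVELS)

#: Default adjustment set: every covariate in the schema.
DEFAULT_COVARIATES: tuple[str, ...] = COVARIATE_FIELDS

#: Raw (non-covariate) fields.
BINARY_FIELDS = (
    "neonatal_death",
    "facility_delivery",
    "skilled_attendant",
    "fp_need_unmet",
    "first_pregnancy",
    "prior_neonatal_death",
)
COUNT_FIELDS = ("anc_visits", "outcomes_last_5y")
DESIGN_FIELDS = ("weight", "stratum_id", "cluster_id")

ALL_FIELDS: tuple[str, ...] = (
    BINARY_FIELDS
    + COUNT_FIELDS
    + ("preceding_interval_months",)
    + COVARIATE_FIELDS
    + DESIGN_FIELDS
)

#: Preceding birth interval bounds (months) observed in the survey categories.
INTERVAL_MIN, INTERVAL_MAX = 8, 226
#: A preceding interval of at most this many months is the short-interval
#: exposure category.
SHORT_INTERVAL_MAX = 24
#: Fewer than this many antenatal-care visits is the ANC exposure.
ANC_THRESHOLD = 4

#: Exposure names, 1 = exposed (high risk).
EXPOSURES: tuple[str, ...] = (
    "IDELIV",          # delivered outside a health facility
    "SBA",             # no skilled birth attendant
    "ANC4",            # fewer than 4 antenatal care visits
    "FP_UNMET",        # unmet family-planning need (spacing or limiting)
    "SHORT_INTERVAL",  # preceding birth interval 8-24 months
    "FIRST_PREG",      # first pregnancy
    "TWO_PLUS_5Y",     # >= 2 pregnancy outcomes in the last 5 years
    "PREV_NNM",        # a previous child died in the neonatal period
)

#: Raw fields each exposure is derived from (used for complete-case filtering).
EXPOSURE_SOURCE_FIELDS: dict[str, tuple[str, ...]] = {
    "IDELIV": ("facility_delivery",),
    "SBA": ("skilled_attendant",),
    "ANC4": ("anc_visits",),
    "FP_UNMET": ("fp_need_unmet",),
    "SHORT_INTERVAL": ("preceding_interval_months", "first_pregnancy"),
    "FIRST_PREG": ("first_pregnancy",),
    "TWO_PLUS_5Y": ("outcomes_last_5y",),
    "PREV_NNM": ("prior_neonatal_death",),
}

#: Exposure pairs that are never analysed jointly: institutional delivery and
#: skilled attendance are near-deterministically linked, and short birth
#: interval largely determines having two or more recent pregnancy outcomes.
_FORBIDDEN_PAIRS = (frozenset({"IDELIV", "SBA"}), frozenset({"SHORT_INTERVAL", "TWO_PLUS_5Y"}))


@dataclass(frozen=True)
class ExposureSet:
    """A named, ordered combination of exposures analysed together."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [m for m in self.members if m not in EXPOSURES]
        if unknown:
            raise SchemaError(f"unknown exposure name(s): {unknown}")
        if len(set(self.members)) != len(self.members):
            raise SchemaError("duplicate exposure in set")
        mem = set(self.members)
        for pair in _FORBIDDEN_PAIRS:
            if pair <= mem:
                raise SchemaError(
                    f"exposures {sorted(pair)} are completely confounded and "
                    "cannot appear in the same set"
                )

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


#: The three pre-registered exposure combinations.
EXPOSURE_SETS: dict[str, ExposureSet] = {
    "A": ExposureSet("A", ("IDELIV", "ANC4", "FP_UNMET", "SHORT_INTERVAL", "FIRST_PREG")),
    "B": ExposureSet("B", ("IDELIV", "ANC4", "FP_UNMET", "TWO_PLUS_5Y")),
    "C": ExposureSet("C", ("IDELIV", "ANC4", "FP_UNMET", "PREV_NNM")),
}


def get_exposure_set(spec: str | Sequence[str] | ExposureSet) -> ExposureSet:
    """Resolve a set name ('A'/'B'/'C'), a list of exposure names, or a set."""
    if isinstance(spec, ExposureSet):
        return spec
    if isinstance(spec, str):
        try:
            return EXPOSURE_SETS[spec]
        except KeyError:
            raise SchemaError(f"unknown exposure set {spec!r}; known: A, B, C") from None
    return ExposureSet("custom", tuple(spec))


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def validate_records(df: pd.DataFrame, require_design: bool = False) -> None:
    """Check schema invariants; missing values (NaN) are tolerated.

    Raises :class:`SchemaError` naming the offending column (and the first
    offending row label where applicable).
    """
    required = [c for c in ALL_FIELDS if c not in DESIGN_FIELDS or require_design]
    missing_cols = [c for c in required if c not in df.columns]
    if "neonatal_death" not in df.columns:
        raise SchemaError("missing required column 'neonatal_death'")
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")

    def _bad(mask: pd.Series, msg: str) -> None:
        if mask.any():
            row = mask.idxmax()
            raise SchemaError(f"{msg} (first offending row: {row})")

    for col in BINARY_FIELDS:
        vals = pd.to_numeric(df[col], errors="coerce")
        ok = vals.isna() | vals.isin([0, 1])
        _bad(~ok, f"column '{col}' must be 0/1")

    for col, levels in CATEGORICAL_LEVELS.items():
        vals = df[col]
        ok = vals.isna() | vals.isin(levels)
        _bad(~ok, f"column '{col}' has values outside its enumerated levels")

    anc = pd.to_numeric(df["anc_visits"], errors="coerce")
    _bad(anc.notna() & (anc < 0), "column 'anc_visits' must be non-negative")
    out5 = pd.to_numeric(df["outcomes_last_5y"], errors="coerce")
    _bad(out5.notna() & (out5 < 1), "column 'outcomes_last_5y' must be >= 1")

    interval = pd.to_numeric(df["preceding_interval_months"], errors="coerce")
    first = pd.to_numeric(df["first_pregnancy"], errors="coerce")
    _bad(
        interval.notna() & ((interval < INTERVAL_MIN) | (interval > INTERVAL_MAX)),
        f"column 'preceding_interval_months' outside [{INTERVAL_MIN}, {INTERVAL_MAX}]",
    )
    _bad(
        interval.notna() & (first == 1),
        "preceding_interval_months present on a first pregnancy",
    )

    if "weight" in df.columns:
        w = pd.to_numeric(df["weight"], errors="coerce")
        _bad(w.notna() & (w <= 0), "column 'weight' must be positive")


def load_records(path) -> pd.DataFrame:
    """Read the records CSV (UTF-8, header row, empty cell = missing)."""
    df = pd.read_csv(path)
    validate_records(df)
    return df


# --------------------------------------------------------------------------
# Exposure derivation
# --------------------------------------------------------------------------

def derive_exposure_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Derive all eight binary exposures, vectorised.

    Returns a float frame (0.0 / 1.0 / NaN where a source field is missing).
    A row with a preceding interval recorded on a first pregnancy is a schema
    violation and raises.
    """
    interval = pd.to_numeric(df["preceding_interval_months"], errors="coerce")
    first = pd.to_numeric(df["first_pregnancy"], errors="coerce")
    conflict = interval.notna() & (first == 1)
    if conflict.any():
        raise SchemaError(
            "preceding_interval_months present on a first pregnancy "
            f"(first offending row: {conflict.idxmax()})"
        )

    def _flip(col: str) -> pd.Series:  # exposed = service NOT received
        v = pd.to_numeric(df[col], errors="coerce")
        return 1.0 - v

    out = pd.DataFrame(index=df.index)
    out["IDELIV"] = _flip("facility_delivery")
    out["SBA"] = _flip("skilled_attendant")
    anc = pd.to_numeric(df["anc_visits"], errors="coerce")
    out["ANC4"] = (anc < ANC_THRESHOLD).astype(float).where(anc.notna())
    out["FP_UNMET"] = pd.to_numeric(df["fp_need_unmet"], errors="coerce")

    # Short interval: first pregnancies are unexposed by definition; a missing
    # interval on a non-first pregnancy is genuinely missing.
    short = (interval >= INTERVAL_MIN) & (interval <= SHORT_INTERVAL_MAX)
    si = pd.Series(np.nan, index=df.index)
    si[first == 1] = 0.0
    si[interval.notna()] = short[interval.notna()].astype(float)
    out["SHORT_INTERVAL"] = si

    out["FIRST_PREG"] = first
    n5 = pd.to_numeric(df["outcomes_last_5y"], errors="coerce")
    out["TWO_PLUS_5Y"] = (n5 >= 2).astype(float).where(n5.notna())
    out["PREV_NNM"] = pd.to_numeric(df["prior_neonatal_death"], errors="coerce")
    return out


def derive_exposures(record: Mapping) -> dict[str, float]:
    """Derive the exposure vector for a single record (dict-like)."""
    df = pd.DataFrame([dict(record)])
    for col in ALL_FIELDS:
        if col not in df.columns:
            df[col] = np.nan
    return derive_exposure_matrix(df).iloc[0].to_dict()


# --------------------------------------------------------------------------
# Covariate encoding and dataset construction
# --------------------------------------------------------------------------

def encode_covariates(df: pd.DataFrame, covariate_spec: Sequence[str]) -> pd.DataFrame:
    """Reference-cell indicator coding with the first schema level as reference.

    Columns that are constant in the data (e.g. a single observed level)
    contribute nothing and are dropped with a warning.
    """
    blocks: list[pd.DataFrame] = []
    for name in covariate_spec:
        if name not in COVARIATE_FIELDS:
            raise SchemaError(f"unknown covariate {name!r}; known: {COVARIATE_FIELDS}")
        levels = CATEGORICAL_LEVELS[name]
        cat = pd.Categorical(df[name], categories=levels)
        dummies = pd.get_dummies(cat, prefix=name, dtype=float)
        dummies.index = df.index
        dummies = dummies.iloc[:, 1:]  # drop reference level
        const = [c for c in dummies.columns if dummies[c].nunique(dropna=True) <= 1]
        if const:
            logger.warning(
                "covariate %r: dropping constant indicator column(s) %s", name, const
            )
            dummies = dummies.drop(columns=const)
        if dummies.shape[1] == 0:
            logger.warning("covariate %r has a single observed level; contributes no columns", name)
        blocks.append(dummies)
    if not blocks:
        return pd.DataFrame(index=df.index)
    W = pd.concat(blocks, axis=1)
    # NaN propagation: a missing categorical must stay missing, not all-zero.
    for name in covariate_spec:
        miss = df[name].isna()
        if miss.any():
            cols = [c for c in W.columns if c.startswith(name + "_")]
            W.loc[miss, cols] = np.nan
    return W


@dataclass
class AnalysisDataset:
    """Complete-case analysis matrices for one exposure set."""

    y: np.ndarray                      # (n,) binary outcome
    A: pd.DataFrame                    # (n, J) binary exposure matrix
    W: pd.DataFrame                    # (n, p) encoded covariates
    weights: np.ndarray                # (n,) positive sampling weights
    stratum_id: np.ndarray | None
    cluster_id: np.ndarray | None
    n_dropped_missing: int
    exposure_set: ExposureSet
    covariate_spec: tuple[str, ...] = field(default=DEFAULT_COVARIATES)

    @property
    def n(self) -> int:
        return len(self.y)

    def __post_init__(self) -> None:
        for label, arr in (("Y", self.y), ("A", self.A.to_numpy()),
                           ("W", self.W.to_numpy()), ("weights", self.weights)):
            if np.isnan(np.asarray(arr, dtype=float)).any():
                raise SchemaError(f"{label} contains missing values after complete-case filter")
        if (self.weights <= 0).any():
            raise SchemaError("weights must be positive")


def build_dataset(
    records: pd.DataFrame,
    exposure_set: str | Sequence[str] | ExposureSet = "A",
    covariate_spec: Sequence[str] = DEFAULT_COVARIATES,
    validate: bool = True,
) -> AnalysisDataset:
    """Build complete-case matrices for the given exposure set.

    A row is dropped only when it is missing a field the analysis actually
    uses: the outcome, a source field of a member exposure, a requested
    covariate, or the weight.
    """
    if len(records) == 0:
        raise SchemaError("no input records")
    if validate:
        validate_records(records)
    eset = get_exposure_set(exposure_set)
    covariate_spec = tuple(covariate_spec)

    A_full = derive_exposure_matrix(records)
    A = A_full[list(eset.members)]
    W = encode_covariates(records, covariate_spec)
    y = pd.to_numeric(records["neonatal_death"], errors="coerce")
    if "weight" in records.columns:
        w = pd.to_numeric(records["weight"], errors="coerce")
    else:
        w = pd.Series(1.0, index=records.index)

    keep = y.notna() & w.notna() & ~A.isna().any(axis=1)
    if W.shape[1]:
        keep &= ~W.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise SchemaError("no complete-case records remain after filtering")

    idx = records.index[keep]
    stratum = records.loc[idx, "stratum_id"].to_numpy() if "stratum_id" in records.columns else None
    cluster = records.loc[idx, "cluster_id"].to_numpy() if "cluster_id" in records.columns else None
    return AnalysisDataset(
        y=y.loc[idx].to_numpy(dtype=float),
        A=A.loc[idx].astype(float).reset_index(drop=True),
        W=W.loc[idx].astype(float).reset_index(drop=True) if W.shape[1] else
          pd.DataFrame(index=pd.RangeIndex(len(idx))),
        weights=w.loc[idx].to_numpy(dtype=float),
        stratum_id=stratum,
        cluster_id=cluster,
        n_dropped_missing=n_dropped,
        exposure_set=eset,
        covariate_spec=covariate_spec,
    )


# --------------------------------------------------------------------------
# Descriptive rates
# --------------------------------------------------------------------------

def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def category_rates(dataset: AnalysisDataset, use_weights: bool = True) -> pd.DataFrame:
    """Neonatal mortality rate per 1000 by exposure category.

    One row per (exposure, category) plus an overall row. An empty category
    reports NaN, never zero.
    """
    w = dataset.weights if use_weights else np.ones(dataset.n)
    rows = [{
        "exposure": "overall", "category": "all", "n": dataset.n,
        "nmr_per_1000": 1000.0 * _wmean(dataset.y, w),
    }]
    for j in dataset.exposure_set.members:
        a = dataset.A[j].to_numpy()
        for category, mask in (("unexposed", a == 0), ("exposed", a == 1)):
            n_cat = int(mask.sum())
            rate = 1000.0 * _wmean(dataset.y[mask], w[mask]) if n_cat else np.nan
            rows.append({"exposure": j, "category": category, "n": n_cat,
                         "nmr_per_1000": rate})
    return pd.DataFrame(rows)
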