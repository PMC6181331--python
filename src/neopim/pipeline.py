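"""Reproducible pipeline: simulate -> recode -> estimate -> report.

A single YAML config drives the three stages. Every number in the results
CSV is traceable through the run manifest (config echo, package version,
seeds, chosen learners, truncation counts) to a seed and a config; per-1000
estimates are rounded to one decimal only in the report table, with full
precision retained in the machine-readable outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import (
    DEFAULT_G_MIN,
    LearnerConfig,
    estimate_exposure_set,
    estimates_frame,
    naive_par_table,
    positivity_report,
    tmle_phi,
    fit_nuisance,
)
from .learners import CVConfig, LOGISTIC, PARTITION, LearnerSpec
from .records import (
    DEFAULT_COVARIATES,
    build_dataset,
    category_rates,
    get_exposure_set,
    load_records,
)
from .synthetic import (
    GeneratorConfig,
    inject_missingness,
    read_truth,
    simulate_population,
    write_records_csv,
    write_truth,
)

logger = logging.getLogger("neopim")

_LEARNER_BY_NAME = {
    "logistic": LOGISTIC,
    "logistic_main_effects": LOGISTIC,
    "partition": PARTITION,
    "recursive_partition": PARTITION,
}


def _learners(names) -> tuple[LearnerSpec, ...]:
    out = []
    for n in names:
        if isinstance(n, LearnerSpec):
            out.append(n)
        elif n in _LEARNER_BY_NAME:
            out.append(_LEARNER_BY_NAME[n])
        else:
            raise ValueError(f"unknown learner {n!r}; known: {sorted(_LEARNER_BY_NAME)}")
    return tuple(out)


@dataclass
class SimulateConfig:
    n: int = 10_000
    seed: int = 1
    out_records: str = "records.csv"
    out_truth: str = "truth.yaml"
    missingness_rate: float = 0.0


@dataclass
class EstimateConfig:
    input: str = "records.csv"
    truth: str | None = None
    exposure_sets: tuple = ("A", "B", "C")
    covariates: tuple = DEFAULT_COVARIATES
    g_candidates: tuple = ("logistic",)
    q_candidates: tuple = ("partition",)
    v: int = 10
    cv_seed: int = 0
    g_min: float = DEFAULT_G_MIN
    use_weights: bool = True
    variance: str = "iid"
    estimators: tuple = ("naive", "gcomp", "ipw", "tmle")
    gcomp_bootstrap: int = 500
    seed: int = 0
    outdir: str = "results"


@dataclass
class RecoverConfig:
    replicates: int = 20
    n: int = 5_000
    seed: int = 0
    exposure_set: str = "A"
    exposures: tuple | None = None       # default: all members of the set
    covariates: tuple = DEFAULT_COVARIATES
    g_candidates: tuple = ("logistic",)
    q_candidates: tuple = ("logistic",)
    v: int = 10
    g_min: float = DEFAULT_G_MIN
    use_weights: bool = True
    outdir: str = "results"


@dataclass
class RunConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    estimate: EstimateConfig = field(default_factory=EstimateConfig)
    recover: RecoverConfig = field(default_factory=RecoverConfig)


def load_config(path) -> RunConfig:
    """Read a YAML run config; unknown keys raise, missing keys default."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for section_name, cls in (("simulate", SimulateConfig),
                              ("estimate", EstimateConfig),
                              ("recover", RecoverConfig)):
        section = raw.pop(section_name, {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ValueError(f"unknown key(s) in config section {section_name!r}: {sorted(unknown)}")
        setattr(cfg, section_name, cls(**section))
    if raw:
        raise ValueError(f"unknown top-level config section(s): {sorted(raw)}")
    return cfg


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def run_simulate(cfg: SimulateConfig, outdir: str | Path = ".") -> dict:
    if cfg.n < 1:
        raise ValueError("simulate.n must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_population(GeneratorConfig(), n=cfg.n, seed=cfg.seed)
    if cfg.missingness_rate > 0:
        records = inject_missingness(records, cfg.missingness_rate, seed=cfg.seed + 1)
    rec_path = outdir / cfg.out_records
    truth_path = outdir / cfg.out_truth
    write_records_csv(records, rec_path)
    write_truth(truth, truth_path)
    logger.info("simulated %d records -> %s (truth sidecar %s)", cfg.n, rec_path, truth_path)
    return {"records": str(rec_path), "truth": str(truth_path), "n": cfg.n, "seed": cfg.seed}


def run_estimate(cfg: EstimateConfig) -> dict:
    t_start = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = load_records(cfg.input)
    truth = read_truth(cfg.truth) if cfg.truth else None
    learners = LearnerConfig(g_candidates=_learners(cfg.g_candidates),
                             q_candidates=_learners(cfg.q_candidates))
    cv = CVConfig(v=cfg.v, seed=cfg.cv_seed)

    results, rates, naive_tabs, diag = [], [], [], []
    manifest: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "input_records": len(records),
        "sets": {},
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    for set_name in cfg.exposure_sets:
        eset = get_exposure_set(set_name)
        ds = build_dataset(records, eset, cfg.covariates)
        logger.info("exposure set %s: n=%d (dropped %d incomplete rows)",
                    eset.name, ds.n, ds.n_dropped_missing)
        ests, nuisance = estimate_exposure_set(
            ds, learners=learners, cv=cv, g_min=cfg.g_min,
            estimators=cfg.estimators, gcomp_bootstrap=cfg.gcomp_bootstrap,
            seed=cfg.seed, use_weights=cfg.use_weights, variance=cfg.variance,
        )
        frame = estimates_frame(ests)
        frame.insert(0, "exposure_set", eset.name)
        if truth is not None:
            frame["truth_per_1000"] = frame["exposure"].map(truth.phi_per_1000)
            frame["estimate_minus_truth_per_1000"] = (
                frame["estimate_per_1000"] - frame["truth_per_1000"]
            )
        results.append(frame)

        for weighted in (True, False):
            r = category_rates(ds, use_weights=weighted)
            r.insert(0, "exposure_set", eset.name)
            r.insert(1, "weighted", weighted)
            rates.append(r)
            nt = naive_par_table(ds, use_weights=weighted)
            nt.insert(0, "exposure_set", eset.name)
            nt.insert(1, "weighted", weighted)
            naive_tabs.append(nt)

        d = positivity_report(nuisance)
        d.insert(0, "exposure_set", eset.name)
        diag.append(d)
        manifest["sets"][eset.name] = {
            "n": ds.n,
            "n_dropped_missing": ds.n_dropped_missing,
            "g_learner": nuisance.g_learner,
            "q_learner": nuisance.q_learner,
            "n_truncated": nuisance.n_truncated,
            "cv_tables": {k: v.to_dict("records") for k, v in nuisance.cv_tables.items()},
        }

    res = pd.concat(results, ignore_index=True)
    report = res.copy()
    for col in ("estimate_per_1000", "se_per_1000", "truth_per_1000",
                "estimate_minus_truth_per_1000"):
        if col in report.columns:
            report[col] = report[col].round(1)
    report["test_statistic"] = report["test_statistic"].round(3)
    report["p_value"] = report["p_value"].round(3)

    paths = {
        "results": outdir / "results.csv",
        "results_report": outdir / "results_report.csv",
        "category_rates": outdir / "category_rates.csv",
        "naive_par": outdir / "naive_par.csv",
        "positivity": outdir / "positivity.csv",
        "manifest": outdir / "manifest.json",
    }
    res.to_csv(paths["results"], index=False)
    report.to_csv(paths["results_report"], index=False)
    pd.concat(rates, ignore_index=True).to_csv(paths["category_rates"], index=False)
    pd.concat(naive_tabs, ignore_index=True).to_csv(paths["naive_par"], index=False)
    pd.concat(diag, ignore_index=True).to_csv(paths["positivity"], index=False)
    manifest["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    manifest["elapsed_seconds"] = round(time.time() - t_start, 3)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("estimation complete; outputs in %s", outdir)
    return {k: str(v) for k, v in paths.items()}


def run_recover(cfg: RecoverConfig) -> pd.DataFrame:
    """Parameter-recovery study: bias, empirical vs estimated SE, coverage."""
    if cfg.replicates < 1:
        raise ValueError("recover.replicates must be >= 1")
    eset = get_exposure_set(cfg.exposure_set)
    exposures = tuple(cfg.exposures) if cfg.exposures else eset.members
    learners = LearnerConfig(g_candidates=_learners(cfg.g_candidates),
                             q_candidates=_learners(cfg.q_candidates))
    cv = CVConfig(v=cfg.v, seed=cfg.seed)

    rows = []
    for r in range(cfg.replicates):
        rec, truth = simulate_population(GeneratorConfig(), n=cfg.n,
                                         seed=cfg.seed + 1000 * r)
        ds = build_dataset(rec, eset, cfg.covariates)
        nuisance = fit_nuisance(ds, learners, cv, cfg.g_min, cfg.use_weights)
        for j in exposures:
            est = tmle_phi(ds, nuisance, j, use_weights=cfg.use_weights)
            lo, hi = est.ci()
            rows.append({
                "replicate": r, "exposure": j,
                "estimate_per_1000": est.phi_per_1000,
                "se_per_1000": est.se_per_1000,
                "truth_per_1000": truth.phi_per_1000[j],
                "covered": lo <= truth.phi[j] <= hi,
            })
    per_rep = pd.DataFrame(rows)
    summary = per_rep.groupby("exposure").apply(
        lambda g: pd.Series({
            "replicates": len(g),
            "mean_truth_per_1000": g.truth_per_1000.mean(),
            "mean_estimate_per_1000": g.estimate_per_1000.mean(),
            "bias_per_1000": (g.estimate_per_1000 - g.truth_per_1000).mean(),
            "empirical_se_per_1000": g.estimate_per_1000.std(ddof=1) if len(g) > 1 else np.nan,
            "mean_estimated_se_per_1000": g.se_per_1000.mean(),
            "coverage_95": g.covered.mean(),
        }),
        include_groups=False,
    ).reset_index()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_rep.to_csv(outdir / "recovery_replicates.csv", index=False)
    summary.to_csv(outdir / "recovery_summary.csv", index=False)
    logger.info("recovery study complete (%d replicates, n=%d)", cfg.replicates, cfg.n)
    return summary
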