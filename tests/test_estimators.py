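"""Attributable-risk estimators: naive, G-computation, IPW, TMLE."""

import numpy as np
import pandas as pd
import pytest

from neopim import (
    AnalysisDataset,
    CVConfig,
    GeneratorConfig,
    LOGISTIC,
    LearnerConfig,
    NuisanceFits,
    PositivityError,
    build_dataset,
    category_rates,
    estimate_exposure_set,
    estimates_frame,
    fit_nuisance,
    gcomp_phi,
    get_exposure_set,
    ipw_phi,
    naive_par,
    naive_par_table,
    positivity_report,
    simulate_population,
    tmle_phi,
)

from conftest import make_records


# --------------------------------------------------------------------------
# Helpers: hand-made discrete datasets with saturated nuisances
# --------------------------------------------------------------------------

def discrete_dataset(seed, n=1500, n_cov=2, weights=True, exposure="IDELIV"):
    """Random discrete instance: binary covariates, one binary exposure."""
    rng = np.random.default_rng(seed)
    W = pd.DataFrame({f"w{i}": rng.integers(0, 2, n).astype(float)
                      for i in range(n_cov)})
    lp_a = -0.4 + sum(rng.uniform(-1, 1) * W[c] for c in W)
    a = (rng.random(n) < 1 / (1 + np.exp(-lp_a))).astype(float)
    lp_y = -1.2 + rng.uniform(0.3, 1.2) * a + sum(rng.uniform(-1, 1) * W[c] for c in W)
    y = (rng.random(n) < 1 / (1 + np.exp(-lp_y))).astype(float)
    w = rng.uniform(0.5, 2.0, n) if weights else np.ones(n)
    return AnalysisDataset(
        y=y, A=pd.DataFrame({exposure: a}), W=W, weights=w,
        stratum_id=None, cluster_id=None, n_dropped_missing=0,
        exposure_set=get_exposure_set([exposure]),
    )


def saturated_nuisance(ds, g_min=0.0):
    """Exhaustive-stratification ("saturated") nuisance fits by group means."""
    j = ds.exposure_set.members[0]
    a = ds.A[j].to_numpy()
    w = ds.weights / ds.weights.mean()
    w_cells = [tuple(row) for row in ds.W.to_numpy()] if ds.W.shape[1] else \
        [()] * ds.n

    def weighted_mean_table(keys, values):
        num, den = {}, {}
        for k, v, wi in zip(keys, values, w):
            num[k] = num.get(k, 0.0) + wi * v
            den[k] = den.get(k, 0.0) + wi
        return {k: num[k] / den[k] for k in num}

    g_tab = weighted_mean_table(w_cells, (a == 0).astype(float))
    g0 = np.array([g_tab[k] for k in w_cells])

    q_keys = [(ai,) + k for ai, k in zip(a, w_cells)]
    q_tab = weighted_mean_table(q_keys, ds.y)
    q_obs = np.array([q_tab[k] for k in q_keys])
    q_cf = np.array([q_tab[(0.0,) + k] for k in w_cells])

    gt = np.clip(g0, g_min, 1.0) if g_min > 0 else g0
    return NuisanceFits(
        g0={j: gt}, g0_raw_min={j: float(g0.min())}, g0_raw_max={j: float(g0.max())},
        n_truncated={j: int(np.sum(g0 < g_min))}, g_learner={j: "saturated"},
        q_obs=q_obs, q_cf={j: q_cf}, q_learner="saturated", g_min=g_min,
    )


def stratification_oracle(ds):
    """Hand G-computation: weighted mean of stratum-specific E[Y | A=0, W],
    standardised over the covariate distribution, minus the overall mean."""
    j = ds.exposure_set.members[0]
    a = ds.A[j].to_numpy()
    w = ds.weights / ds.weights.mean()
    df = pd.DataFrame({"a": a, "y": ds.y, "w": w})
    for c in ds.W.columns:
        df[c] = ds.W[c]
    cols = list(ds.W.columns)
    mu0 = 0.0
    for _, g in df.groupby(cols) if cols else [(None, df)]:
        unexp = g[g.a == 0]
        mu0 += g.w.sum() * np.sum(unexp.w * unexp.y) / np.sum(unexp.w)
    mu0 /= df.w.sum()
    return mu0 - np.sum(df.w * df.y) / df.w.sum()


# --------------------------------------------------------------------------
# Naive attributable risk
# --------------------------------------------------------------------------

class TestNaivePar:
    @pytest.mark.parametrize("p, r0, r1, expected", [
        (0.064, 0.0172, 0.0378, -1.3),   # institutional delivery
        (0.496, 0.0168, 0.0202, -1.7),   # <4 ANC visits
        (0.079, 0.0169, 0.0373, -1.6),   # no skilled attendant
        (0.166, 0.0173, 0.0245, -1.2),   # unmet FP need
        (0.364, 0.0158, 0.0233, -2.7),   # two+ recent outcomes
        (0.079, 0.0175, 0.0303, -1.0),   # short interval
        (0.259, 0.0165, 0.0242, -2.0),   # first pregnancy
    ])
    def test_published_survey_rows(self, p, r0, r1, expected):
        assert round(naive_par(p, r0, r1), 1) == expected

    def test_equal_rates_give_exact_zero(self):
        assert naive_par(0.3, 0.02, 0.02) == 0.0

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            naive_par(1.2, 0.1, 0.1)
        with pytest.raises(ValueError):
            naive_par(0.5, -0.1, 0.1)

    @pytest.mark.parametrize("use_weights", [True, False])
    def test_table_consistent_with_category_rates(self, sim_dataset_a, use_weights):
        ds, _ = sim_dataset_a
        tab = naive_par_table(ds, use_weights).set_index("exposure")
        rates = category_rates(ds, use_weights).set_index(["exposure", "category"])
        overall = rates.loc[("overall", "all"), "nmr_per_1000"]
        for j in ds.exposure_set.members:
            r0 = tab.loc[j, "rate_unexposed"] * 1000
            assert tab.loc[j, "naive_par_per_1000"] == pytest.approx(
                r0 - overall, abs=1e-9)


# --------------------------------------------------------------------------
# Nuisance fitting / positivity
# --------------------------------------------------------------------------

class TestNuisance:
    def test_independent_exposure_gives_flat_propensity(self):
        rng = np.random.default_rng(0)
        n = 3000
        df = make_records(n=n, seed=0, facility_delivery=rng.integers(0, 2, n))
        ds = build_dataset(df, ["IDELIV"], covariate_spec=("residence",))
        nf = fit_nuisance(ds, LearnerConfig(g_candidates=(LOGISTIC,),
                                            q_candidates=(LOGISTIC,)))
        assert np.all(np.abs(nf.g0["IDELIV"] - 0.5) < 0.06)

    def test_constant_exposure_raises_positivity_error(self):
        df = make_records(n=40, seed=1, facility_delivery=1)
        ds = build_dataset(df, ["IDELIV"])
        with pytest.raises(PositivityError, match="IDELIV"):
            fit_nuisance(ds)

    def test_truncation_counts_constructed_stratum(self):
        """A covariate stratum with true g(0|W) = 0.001 is fully truncated at
        g_min = 0.01 and the count equals the stratum size."""
        n_urban, n_rural = 1000, 1000
        df = make_records(n=n_urban + n_rural, seed=2)
        df["residence"] = ["urban"] * n_urban + ["rural"] * n_rural
        fd = np.concatenate([np.zeros(n_urban), np.ones(n_rural)])
        fd[0] = 1.0  # exactly one urban facility delivery -> g(0|urban)=0.001
        fd[n_urban:n_urban + 500] = 0.0
        df["facility_delivery"] = fd
        ds = build_dataset(df, ["IDELIV"], covariate_spec=("residence",))
        nf = fit_nuisance(ds, LearnerConfig(g_candidates=(LOGISTIC,),
                                            q_candidates=(LOGISTIC,)), g_min=0.01)
        assert nf.n_truncated["IDELIV"] == n_urban
        rep = positivity_report(nf).set_index("exposure")
        assert rep.loc["IDELIV", "n_truncated"] == n_urban
        # raising the bound weakly increases the truncated count
        nf2 = fit_nuisance(ds, LearnerConfig(g_candidates=(LOGISTIC,),
                                             q_candidates=(LOGISTIC,)), g_min=0.05)
        assert nf2.n_truncated["IDELIV"] >= nf.n_truncated["IDELIV"]

    def test_determined_stratum_flagged(self):
        df = make_records(n=400, seed=3)
        df["residence"] = ["urban"] * 200 + ["rural"] * 200
        df["facility_delivery"] = [0] * 200 + [1] * 100 + [0] * 100
        ds = build_dataset(df, ["IDELIV"], covariate_spec=("residence",))
        nf = fit_nuisance(ds, LearnerConfig(g_candidates=(LOGISTIC,),
                                            q_candidates=(LOGISTIC,)))
        rep = positivity_report(nf).set_index("exposure")
        assert rep.loc["IDELIV", "fully_determined_stratum"]

    def test_set_a_produces_five_g_fits_and_one_q_fit(self, sim_dataset_a):
        ds, _ = sim_dataset_a
        nf = fit_nuisance(ds, LearnerConfig(g_candidates=(LOGISTIC,),
                                            q_candidates=(LOGISTIC,)))
        assert set(nf.g0) == set(ds.exposure_set.members) and len(nf.g0) == 5
        assert nf.q_obs.shape == (ds.n,)


# --------------------------------------------------------------------------
# G-computation and IPW
# --------------------------------------------------------------------------

class TestGcompIpw:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gcomp_matches_stratification_oracle(self, seed):
        ds = discrete_dataset(seed)
        nf = saturated_nuisance(ds)
        est = gcomp_phi(ds, nf, ds.exposure_set.members[0], bootstrap=0)
        assert est.phi == pytest.approx(stratification_oracle(ds), abs=1e-12)

    def test_gcomp_zero_when_nobody_exposed(self):
        ds = discrete_dataset(3)
        j = ds.exposure_set.members[0]
        ds.A[j] = 0.0
        nf = saturated_nuisance(ds)
        est = gcomp_phi(ds, nf, j, bootstrap=0)
        assert est.phi == pytest.approx(0.0, abs=1e-12)

    def test_gcomp_bootstrap_se_reasonable_under_null(self):
        cfg = GeneratorConfig(outcome_betas={"IDELIV": 0.0})
        rec, _ = simulate_population(cfg, n=8000, seed=21)
        ds = build_dataset(rec, ["IDELIV"])
        lc = LearnerConfig(g_candidates=(LOGISTIC,), q_candidates=(LOGISTIC,))
        nf = fit_nuisance(ds, lc)
        est = gcomp_phi(ds, nf, "IDELIV", bootstrap=60, seed=5)
        assert est.se > 0
        assert abs(est.phi) < 3 * est.se

    def test_ipw_identity_with_constant_propensity(self):
        """With a known constant g equal to the unexposed share, the Hajek
        estimate collapses to rate_unexposed - overall rate."""
        ds = discrete_dataset(4, weights=False)
        j = ds.exposure_set.members[0]
        a = ds.A[j].to_numpy()
        nf = saturated_nuisance(ds)
        nf.g0[j] = np.full(ds.n, np.mean(a == 0))
        est = ipw_phi(ds, nf, j)
        r0 = ds.y[a == 0].mean()
        assert est.phi == pytest.approx(r0 - ds.y.mean(), abs=1e-12)

    def test_ipw_zero_when_everyone_unexposed(self):
        ds = discrete_dataset(5)
        j = ds.exposure_set.members[0]
        ds.A[j] = 0.0
        nf = saturated_nuisance(ds)
        nf.g0[j] = np.ones(ds.n)
        assert ipw_phi(ds, nf, j).phi == pytest.approx(0.0, abs=1e-15)


# --------------------------------------------------------------------------
# TMLE
# --------------------------------------------------------------------------

class TestTMLE:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_saturated_tmle_equals_oracle_with_tiny_epsilon(self, seed):
        ds = discrete_dataset(seed, n=2500)
        j = ds.exposure_set.members[0]
        nf = saturated_nuisance(ds)
        est = tmle_phi(ds, nf, j)
        assert est.phi == pytest.approx(stratification_oracle(ds), abs=1e-8)
        assert abs(est.diagnostics["epsilon"]) < 1e-6
        assert abs(est.mean_ic) < 1e-8

    def test_no_exposed_mass_gives_zero(self):
        ds = discrete_dataset(6)
        j = ds.exposure_set.members[0]
        ds.A[j] = 0.0
        nf = saturated_nuisance(ds)
        nf.g0[j] = np.ones(ds.n)
        est = tmle_phi(ds, nf, j)
        assert est.phi == pytest.approx(0.0, abs=1e-10)

    def test_weight_scale_invariance_all_estimators(self):
        rec, _ = simulate_population(n=3000, seed=31)
        ds = build_dataset(rec, "B")
        lc = LearnerConfig(g_candidates=(LOGISTIC,), q_candidates=(LOGISTIC,))
        res = {}
        for c in (1.0, 41.7):
            ds_c = AnalysisDataset(
                y=ds.y, A=ds.A, W=ds.W, weights=ds.weights * c,
                stratum_id=ds.stratum_id, cluster_id=ds.cluster_id,
                n_dropped_missing=ds.n_dropped_missing, exposure_set=ds.exposure_set)
            ests, _ = estimate_exposure_set(
                ds_c, learners=lc, estimators=("naive", "gcomp", "ipw", "tmle"),
                gcomp_bootstrap=25, seed=7)
            res[c] = {(e.exposure, e.estimator): (e.phi, e.se) for e in ests}
        for key in res[1.0]:
            p1, s1 = res[1.0][key]
            p2, s2 = res[41.7][key]
            assert p1 == pytest.approx(p2, abs=1e-10), key
            if np.isfinite(s1):
                assert s1 == pytest.approx(s2, abs=1e-10), key

    def test_cluster_variance_option_runs_and_differs(self, sim_dataset_a):
        ds, _ = sim_dataset_a
        lc = LearnerConfig(g_candidates=(LOGISTIC,), q_candidates=(LOGISTIC,))
        nf = fit_nuisance(ds, lc, exposures=["IDELIV"])
        iid = tmle_phi(ds, nf, "IDELIV", variance="iid")
        clu = tmle_phi(ds, nf, "IDELIV", variance="cluster")
        assert iid.phi == clu.phi
        assert iid.se > 0 and clu.se > 0 and iid.se != clu.se


# --------------------------------------------------------------------------
# Per-set driver
# --------------------------------------------------------------------------

class TestEstimateExposureSet:
    def test_set_a_cardinality_and_order(self, sim_dataset_a):
        ds, _ = sim_dataset_a
        lc = LearnerConfig(g_candidates=(LOGISTIC,), q_candidates=(LOGISTIC,))
        ests, _ = estimate_exposure_set(ds, learners=lc, gcomp_bootstrap=10, seed=3)
        assert len(ests) == 20  # 5 exposures x 4 estimator tags
        frame = estimates_frame(ests)
        assert list(frame.exposure.unique()) == list(ds.exposure_set.members)
        assert set(frame.estimator) == {"naive", "gcomp", "ipw", "tmle"}

    def test_harmful_exposures_report_negative_per_1000(self, sim_dataset_a):
        ds, truth = sim_dataset_a
        lc = LearnerConfig(g_candidates=(LOGISTIC,), q_candidates=(LOGISTIC,))
        ests, _ = estimate_exposure_set(ds, learners=lc, estimators=("tmle",),
                                        gcomp_bootstrap=0)
        for e in ests:
            if e.exposure in ("FIRST_PREG", "SHORT_INTERVAL"):
                assert e.phi_per_1000 < 0
                assert e.phi_per_1000 == pytest.approx(1000 * e.phi)

    def test_per_stage_weight_override(self, sim_dataset_a):
        """Weights can be switched off for the nuisance fits while kept in
        the estimation stage (and vice versa)."""
        ds, _ = sim_dataset_a
        lc = LearnerConfig(g_candidates=(LOGISTIC,), q_candidates=(LOGISTIC,))
        mixed, _ = estimate_exposure_set(
            ds, learners=lc, estimators=("tmle",), gcomp_bootstrap=0,
            use_weights=True, nuisance_weights=False)
        uniform, _ = estimate_exposure_set(
            ds, learners=lc, estimators=("tmle",), gcomp_bootstrap=0,
            use_weights=True)
        assert all(np.isfinite(e.phi) and np.isfinite(e.se) for e in mixed)
        assert any(m.phi != u.phi for m, u in zip(mixed, uniform))

    def test_sba_swap_sensitivity_runs_with_same_rows(self, sim_records):
        records, _ = sim_records
        lc = LearnerConfig(g_candidates=(LOGISTIC,), q_candidates=(LOGISTIC,))
        ds_a = build_dataset(records, "A")
        ds_sba = build_dataset(records, ["SBA", "ANC4", "FP_UNMET",
                                         "SHORT_INTERVAL", "FIRST_PREG"])
        assert ds_sba.n == ds_a.n
        ests, _ = estimate_exposure_set(ds_sba, learners=lc,
                                        estimators=("tmle",), gcomp_bootstrap=0)
        assert [e.exposure for e in ests][0] == "SBA"
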