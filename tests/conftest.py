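import numpy as np
import pandas as pd
import pytest

from neopim import GeneratorConfig, build_dataset, simulate_population


def make_records(n=12, seed=0, **overrides):
    """Small hand-controllable records frame satisfying the schema."""
    rng = np.random.default_rng(seed)
    first = rng.integers(0, 2, n).astype(float)
    interval = np.where(first == 1, np.nan, rng.integers(8, 227, n).astype(float))
    df = pd.DataFrame({
        "neonatal_death": rng.integers(0, 2, n),
        "anc_visits": rng.integers(0, 9, n),
        "facility_delivery": rng.integers(0, 2, n),
        "skilled_attendant": rng.integers(0, 2, n),
        "fp_need_unmet": rng.integers(0, 2, n),
        "preceding_interval_months": interval,
        "first_pregnancy": first,
        "outcomes_last_5y": rng.integers(1, 4, n),
        "prior_neonatal_death": rng.integers(0, 2, n),
        "region": rng.choice(["North", "Central", "South"], n),
        "residence": rng.choice(["urban", "rural"], n),
        "mother_age_group": rng.choice(["15-19", "20-24", "25-29"], n),
        "mother_education": rng.choice(["none", "primary", "secondary"], n),
        "hh_head_sex": rng.choice(["male", "female"], n),
        "wealth_quintile": rng.choice(["poorest", "poorer", "middle"], n),
        "child_sex": rng.choice(["male", "female"], n),
        "child_size_recall": rng.choice(["average", "very small"], n),
        "weight": rng.uniform(0.5, 2.0, n),
        "stratum_id": "s1",
        "cluster_id": rng.choice(["c1", "c2", "c3"], n),
    })
    for k, v in overrides.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def sim_records():
    """One medium synthetic draw shared across read-only tests."""
    records, truth = simulate_population(GeneratorConfig(), n=20_000, seed=42)
    return records, truth


@pytest.fixture(scope="session")
def sim_dataset_a(sim_records):
    records, truth = sim_records
    return build_dataset(records, "A"), truth
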