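import numpy as np
import pandas as pd
import pytest

from sagpipe import ClinicalTable, ExpressionMatrix, SimulationConfig, gen_cohort_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """3 probes x 6 samples, fixed values."""
    data = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(3, 6)),
        index=["p1", "p2", "p3"],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def clinical_toy():
    """6 patients, no tied times, all events, alternating groups."""
    df = pd.DataFrame(
        {
            "dfs_time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "dfs_event": [1, 1, 1, 1, 1, 1],
            "grade": ["G1"] * 6,
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    return ClinicalTable(df)


@pytest.fixture(scope="session")
def default_bundle():
    """One mid-sized synthetic cohort shared across read-only tests."""
    cfg = SimulationConfig(n_samples=150, pool_size=400, seed=7)
    return gen_cohort_bundle(cfg)


def make_clinical(time, event, grade=None, ids=None):
    n = len(time)
    df = pd.DataFrame(
        {
            "dfs_time": np.asarray(time, float),
            "dfs_event": np.asarray(event, int),
            "grade": grade if grade is not None else ["G1"] * n,
        },
        index=pd.Index(ids if ids is not None else [f"s{i}" for i in range(n)],
                       name="sample_id"),
    )
    return ClinicalTable(df)
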