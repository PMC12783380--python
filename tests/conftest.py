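import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ipcwjack import SurvivalData
from ipcwjack.simulation import ScenarioConfig, run_scenario

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def mixed_six_records():
    """Six records at tau=4 with exact-fraction hand-enumerated weights.

    Reverse KM: censoring jumps at 2 (risk 5) and 3.5 (risk 3), so
    G = 4/5 on [2, 3.5) and 8/15 on [3.5, 6). Raw weights are
    (1, 0, 5/4, 15/8, 15/8, 0); normalized (1/6, 0, 5/24, 5/16, 5/16, 0).
    """
    data = SurvivalData(
        x=np.arange(12, dtype=float).reshape(6, 2),
        time=np.array([1.0, 2.0, 3.0, 5.0, 6.0, 3.5]),
        status=np.array([1, 0, 1, 1, 0, 0]),
    )
    expected_raw = np.array([1.0, 0.0, 5 / 4, 15 / 8, 15 / 8, 0.0])
    return data, 4.0, expected_raw


def scenario_row(result, method, pattern):
    tab = result.table
    row = tab[(tab["method"] == method) & (tab["pattern"] == pattern)]
    assert len(row) == 1
    return row.iloc[0]


@pytest.fixture(scope="session")
def run_n1000():
    """500 replicates at n=1000, 25% expected zero weights: AFT + IPCW-GLM,
    model-based SEs only (no jackknife sweep at this size)."""
    cfg = ScenarioConfig(
        n=1000,
        lambda_cens=0.10,
        nsim=500,
        seed=914,
        methods=("aft", "ipcw_glm"),
        jackknife_methods=(),
    )
    return run_scenario(cfg)


@pytest.fixture(scope="session")
def run_n200():
    """500 replicates at n=200, 25% expected zero weights: IPCW-GLM with the
    adjusted-jackknife sweep."""
    cfg = ScenarioConfig(
        n=200, lambda_cens=0.10, nsim=500, seed=915, methods=("ipcw_glm",)
    )
    return run_scenario(cfg)
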