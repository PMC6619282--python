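import numpy as np
import pytest

from frailtysim.data import SurvData
from frailtysim.simulate import ScenarioConfig, resolve_scenario


@pytest.fixture(scope="session")
def null_cell():
    """Clustered cell, no frailty, proportional hazards (calibrated)."""
    return resolve_scenario(
        ScenarioConfig(group_size=2, total_size=300), calib_seed=101
    )


@pytest.fixture(scope="session")
def npcell():
    """Clustered cell with the strong time-dependent effect, no frailty."""
    return resolve_scenario(
        ScenarioConfig(group_size=2, total_size=300, beta1_level=2),
        calib_seed=102,
    )


@pytest.fixture(scope="session")
def gamma_frailty_cell():
    """Clustered cell generated with gamma frailty, variance 0.5, PH true."""
    return resolve_scenario(
        ScenarioConfig(
            group_size=5, total_size=500, frailty_variance=0.5,
            frailty_law="gamma",
        ),
        calib_seed=103,
    )


@pytest.fixture
def four_subjects():
    """Times 1..4, status (1,1,1,0), x (1,0,1,0): a hand-checkable dataset."""
    return SurvData(
        cluster=np.arange(4),
        subject=np.arange(4),
        start=np.zeros(4),
        stop=np.array([1.0, 2.0, 3.0, 4.0]),
        status=np.array([1, 1, 1, 0]),
        X=np.array([[1.0], [0.0], [1.0], [0.0]]),
    )


def random_survdata(rng, n=25, p=1, clusters=None, start_stop=False):
    """Small random counting-process dataset for oracle comparisons."""
    X = rng.normal(size=(n, p))
    T = rng.exponential(1.0 / np.exp(X @ (0.5 * np.ones(p))))
    C = rng.exponential(1.5, n)
    stop = np.minimum(T, C)
    status = (T <= C).astype(int)
    if status.sum() == 0:
        status[np.argmin(stop)] = 1
    start = np.zeros(n)
    if start_stop:
        start = stop * rng.random(n) * 0.5
    if clusters is None:
        cluster = np.arange(n)
    else:
        cluster = rng.integers(0, clusters, n)
    return SurvData(
        cluster=cluster,
        subject=np.arange(n),
        start=start,
        stop=stop,
        status=status,
        X=X,
        covariates=[f"x{j}" for j in range(p)],
    )
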