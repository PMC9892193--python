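import numpy as np
import pytest

from mesbalance import ReactorConfig, SimulationParams, simulate


@pytest.fixture(scope="session")
def config() -> ReactorConfig:
    return ReactorConfig()


@pytest.fixture(scope="session")
def plateau(config):
    """Noiseless biofilm-colonization run, finely sampled (0.1 d)."""
    return simulate(config, SimulationParams(seed=1, sample_interval=0.1))


@pytest.fixture(scope="session")
def plateau_05(plateau):
    """The same run observed every 0.5 d (noiseless sampling is deterministic)."""
    _, samples = plateau
    return samples.iloc[::5].reset_index(drop=True)


@pytest.fixture(scope="session")
def steady(config):
    """Long run that reaches a true product steady state (washout equilibrated)."""
    params = SimulationParams(seed=2, horizon=120.0, dt_solver=0.05, sample_interval=0.5)
    return simulate(config, params)


@pytest.fixture(scope="session")
def washout(config):
    """Pure washout: no growth, no production, planktonic inoculum only."""
    params = SimulationParams(
        mu_max=0.0,
        k_det=0.0,
        k_dec=0.0,
        q_p={"acetate": 0.0, "butyrate": 0.0, "hexanoate": 0.0},
        inoculum_biofilm_frac=0.0,
        horizon=30.0,
        seed=3,
    )
    return simulate(config, params)
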