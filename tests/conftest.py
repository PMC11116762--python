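import numpy as np
import pytest

from co2sens import vpd as vpd_mod
from co2sens.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """4x4 grid, 34 years, default magnitudes, fixed seed."""
    cfg = ScenarioConfig(n_lat=4, n_lon=4, seed=42)
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def quiet_scenario():
    """Noise-free GPP, zero sensitivity trend: exact-recovery regime."""
    cfg = ScenarioConfig(n_lat=3, n_lon=3, seed=7, noise_sd_gpp=0.0, beta_rel_trend=0.0)
    return generate_scenario(cfg)


def scenario_vpd(scenario):
    return vpd_mod.vpd(scenario.cubes["tas"], scenario.cubes["rh"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
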