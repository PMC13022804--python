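import pytest
from hypothesis import settings

from riverghg import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

ZERO_NOISE = {
    r: 0.0
    for r in [
        "water_temperature",
        "DO",
        "CO2_sat",
        "CH4_sat",
        "N2O_sat",
        "NH4",
        "NO3",
        "TN",
        "DOC",
        "DON",
    ]
}


@pytest.fixture(scope="session")
def small_scenario():
    """A modest default-condition scenario shared across read-only tests."""
    cfg = sd.ScenarioConfig(n_catchments=24, timestep_days=16, seed=101)
    return sd.generate_scenario(cfg)


@pytest.fixture(scope="session")
def noiseless_scenario():
    """All stochastic perturbations off: observed == truth, exact slopes."""
    cfg = sd.ScenarioConfig(
        n_catchments=8,
        timestep_days=16,
        seed=102,
        wt_trend_mean=0.27,
        wt_trend_sd=0.0,
        weather_sd=0.0,
        noise_sd_per_variable=dict(ZERO_NOISE),
    )
    return sd.generate_scenario(cfg)
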