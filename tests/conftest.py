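import numpy as np
import pytest

from budburst.climate import (ClimateConfig, DailyTemperatureSeries,
                              synthesize_daily_temperature)


@pytest.fixture(scope="session")
def noise_free_config():
    return ClimateConfig(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noise_free_series(noise_free_config):
    """Deterministic Belgian-climatology sinusoid, 1 Sep through 30 Jun."""
    return synthesize_daily_temperature(noise_free_config, n_days=303)


@pytest.fixture(scope="session")
def noisy_series():
    """Default stochastic climatology (AR(1) noise), fixed seed."""
    return synthesize_daily_temperature(ClimateConfig(seed=0), n_days=303)


def draw_params(spec, rng):
    """Uniform draw from a model's prior box, respecting ordering constraints."""
    for _ in range(1000):
        params = {
            n: float(rng.uniform(*spec.bounds[n])) for n in spec.parameter_names
        }
        if {"Tmin", "Topt", "Tmax"} <= set(params) and not (
            params["Tmin"] < params["Topt"] < params["Tmax"]
        ):
            continue
        return params
    raise RuntimeError("could not draw admissible parameters")


@pytest.fixture()
def constant_series():
    def make(value: float, n_days: int = 303, start: int = 1):
        return DailyTemperatureSeries(start, np.full(n_days, float(value)))

    return make
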