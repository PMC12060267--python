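import numpy as np
import pandas as pd
import pytest

from aq_accountant.synth import (
    EmissionSeriesConfig,
    RegulationStep,
    ResponseTerm,
    SourceSpec,
    TrueSourceSystem,
    generate_emissions,
    generate_meteorology,
)


@pytest.fixture(scope="session")
def met_3y():
    return generate_meteorology(n_days=1096, seed=10)


@pytest.fixture(scope="session")
def small_emissions():
    configs = [
        EmissionSeriesConfig(
            "EGU", "SO2", baseline=100.0,
            steps=[RegulationStep("2006-01-01", 0.5)], noise_sd=0.1,
        ),
        EmissionSeriesConfig("mobile", "NOx", baseline=50.0, growth_rate=0.02, noise_sd=0.05),
    ]
    return generate_emissions(configs, n_days=1096, seed=11)


@pytest.fixture(scope="session")
def simple_system():
    sources = [
        SourceSpec(
            "sulfate", baseline=1.0,
            responses=[ResponseTerm("EGU:SO2", "linear", {"slope": 0.02})],
            seasonal_amplitude=0.3, seasonal_peak_day=200, noise_sd=0.2,
        ),
        SourceSpec(
            "traffic", baseline=2.0,
            responses=[ResponseTerm("mobile:NOx", "linear", {"slope": 0.03})],
            dow_multipliers=(1.1, 1.1, 1.1, 1.1, 1.0, 0.8, 0.8), noise_sd=0.2,
        ),
    ]
    profiles = pd.DataFrame(
        [[0.7, 0.2, 0.1, 0.0], [0.1, 0.1, 0.5, 0.3]],
        index=["sulfate", "traffic"],
        columns=["SO4", "NH4", "OC", "EC"],
    )
    return TrueSourceSystem(sources=sources, profiles=profiles)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
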