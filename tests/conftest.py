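import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")

from lakewec import (
    AnnualRecord,
    LakeGeometry,
    MCMCConfig,
    NutrientSeries,
    PriorSpec,
    SimulationDesign,
    simulate_series,
)


@pytest.fixture(scope="session")
def geometry():
    return LakeGeometry(volume=44.3)


@pytest.fixture(scope="session")
def tn_prior():
    return PriorSpec(s_low=1.0, s_high=2.5)


@pytest.fixture(scope="session")
def tp_prior():
    return PriorSpec(s_low=3.0, s_high=6.0)


@pytest.fixture(scope="session")
def synthetic_series():
    """A 24-year TN-like synthetic record at Taihu magnitudes."""
    return simulate_series(SimulationDesign(seed=7))


@pytest.fixture
def tiny_series(geometry):
    """A small hand-built series for exact-arithmetic checks."""
    records = [
        AnnualRecord(year=2000, load=40000.0, outflow=120.0, observed_conc=190.0),
        AnnualRecord(year=2001, load=52000.0, outflow=140.0, observed_conc=230.0),
        AnnualRecord(year=2002, load=47000.0, outflow=130.0, observed_conc=215.0),
        AnnualRecord(year=2003, load=55000.0, outflow=150.0, observed_conc=240.0),
    ]
    return NutrientSeries("TN", records, geometry)


@pytest.fixture
def fast_mcmc():
    return MCMCConfig(n_iterations=12_000, burn_in=2_000, seed=3)
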