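import pytest

from benthme import DesignSpec, default_params, simulate_biomass


@pytest.fixture(scope="session")
def calibrated_params():
    return default_params()


@pytest.fixture(scope="session")
def survey_table(calibrated_params):
    """One simulated survey at the full printed design, shared read-only."""
    return simulate_biomass(DesignSpec(), calibrated_params, seed=20150619)


@pytest.fixture(scope="session")
def small_balanced_spec():
    """Small fully-sampled design for fast model fits (30 stations)."""
    return DesignSpec.balanced(stations_per_line=15)
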