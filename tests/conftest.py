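import numpy as np
import pytest

from protcoop import (
    ModelParameters,
    ScenarioConfig,
    run_ratio_analysis,
    solve_scenario,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def wt_ga(params):
    """Producer monoculture, glutamic-acid medium."""
    return solve_scenario(params, ScenarioConfig.for_medium("GA_GLY", 0.0))


@pytest.fixture(scope="session")
def wt_bsa(params):
    """Producer monoculture, BSA medium."""
    return solve_scenario(params, ScenarioConfig.for_medium("BSA_GLY", 0.0))


@pytest.fixture(scope="session")
def d8_bsa(params):
    """Non-producer monoculture, BSA medium."""
    return solve_scenario(params, ScenarioConfig.for_medium("BSA_GLY", 1.0))


@pytest.fixture(scope="session")
def ga_coculture(params):
    """25% non-producer coculture, glutamic-acid medium."""
    return solve_scenario(params, ScenarioConfig.for_medium("GA_GLY", 0.25))


@pytest.fixture(scope="session")
def bsa_coculture(params):
    """25% non-producer coculture, BSA medium."""
    return solve_scenario(params, ScenarioConfig.for_medium("BSA_GLY", 0.25))


@pytest.fixture(scope="session")
def ratio_frame(params):
    """Full ratio sweep over both media on the experimental mixing grid."""
    return run_ratio_analysis(params)
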