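import numpy as np
import pytest

from moosehab import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_config():
    """A fast scenario: small grid, short records, same generative model."""
    return ScenarioConfig(
        grid_height=36, grid_width=36, n_regions=16,
        n_years_fpar=3, periods_per_year=12, n_years_abundance=12,
        n_years_landcover=5, seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_scenario(small_config)


@pytest.fixture(scope="session")
def study_bundle():
    """Default study-scale scenario: 62 regions, 12 FPAR years, 30 count years."""
    return generate_scenario(ScenarioConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
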