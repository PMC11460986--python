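import warnings

import numpy as np
import pytest

import predprey as pp

# arviz emits a refactor FutureWarning on import; irrelevant to the analysis
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_mcmc():
    """Light sampler settings for tests: plenty for a 3-parameter conjugate
    model, quick enough to run many times."""
    return pp.McmcConfig(chains=2, iterations=4000, burn_in=1000, seed=11)


@pytest.fixture(scope="session")
def synthetic_biomass():
    """One seeded 15-record synthetic survey in biomass units."""
    return pp.generate_biomass(pp.SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def study_2022_biomass():
    """Biomass conversion of the printed 2022 survey records (leopard
    densities are not part of that table, so the records are flagged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pp.densities_to_biomass(pp.make_study_fixture())


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Leopard-missing/zero-record warnings are part of the tested contract;
    keep them from flooding test output."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
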