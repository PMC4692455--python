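import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from szdcm.cmc import ParameterSpace, build_prior
from szdcm.forward import default_grid
from szdcm.simulate import ideal_epoch_spectra
from szdcm.updating import run_updating


@pytest.fixture(scope="session")
def space():
    return ParameterSpace()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def prior(space):
    return build_prior((), space)


@pytest.fixture(scope="session")
def prior_params(space):
    """CMC parameters at the prior means (φ = 0)."""
    return space.to_natural(np.zeros(space.dim))


@pytest.fixture(scope="session")
def inhibitory_scenario():
    """Noiseless 7-epoch spectra along an inhibitory sigmoid drift."""
    spectra, truth = ideal_epoch_spectra("inhibitory")
    return spectra, truth


@pytest.fixture(scope="session")
def inhibitory_trajectory(inhibitory_scenario):
    """Belief-updating trajectory on the noiseless inhibitory scenario."""
    spectra, _ = inhibitory_scenario
    return run_updating(spectra, volatile_spec=("inhibitory",))
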