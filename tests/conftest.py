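import numpy as np
import pytest

from vaxperc import dynamics
from vaxperc.synthetic_survey import generate_survey_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The shipped synthetic survey (n=400, seed=11)."""
    return generate_survey_dataset()


@pytest.fixture(scope="session")
def bistable_params():
    """Published bistable parameter regime (eta=1.2, f inside the wedge)."""
    return dynamics.ModelParameters.reference(f=7.5)


@pytest.fixture(scope="session")
def graded_params():
    """Low-eta regime with a single, gradually rising coverage branch."""
    return dynamics.ModelParameters.reference(eta=0.2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240103)
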