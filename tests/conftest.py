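import numpy as np
import pytest

from motiveloop import FiniteSpace, JointTable
from motiveloop.fixtures import (
    det2,
    ensemble_model_for,
    generative_model_for,
    noisy2,
    two_state_ensemble,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def env_det2():
    return det2()


@pytest.fixture
def env_noisy2():
    return noisy2()


@pytest.fixture
def gm_dirichlet(env_noisy2):
    """Flat Dirichlet-backend model matched to the noisy two-state world."""
    return generative_model_for(env_noisy2, n=1)


@pytest.fixture
def gm_ensemble():
    """Two-point ensemble: the deterministic and the noisy two-state world."""
    return ensemble_model_for([det2(), noisy2()], n=1)


@pytest.fixture
def gm_four_models():
    return ensemble_model_for(two_state_ensemble(), n=1)


def random_joint(spaces, rng) -> JointTable:
    shape = tuple(len(s) for s in spaces)
    probs = rng.dirichlet(np.ones(int(np.prod(shape)))).reshape(shape)
    return JointTable(tuple(spaces), probs)


@pytest.fixture
def spaces_xyz():
    return (FiniteSpace("X", ("x0", "x1", "x2")),
            FiniteSpace("Y", ("y0", "y1")),
            FiniteSpace("Z", ("z0", "z1")))
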