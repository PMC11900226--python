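import numpy as np
import pytest

from tdaforce.excitonic import ExcitonState
from tdaforce.fixtures import fixture
from tdaforce.forces import BseSettings, make_context
from tdaforce.solver import solve_dense


@pytest.fixture(scope="session")
def diatomic():
    """Default two-center fixture: geometry and model parameters."""
    return fixture("diatomic", 4)


@pytest.fixture(scope="session")
def ctx_diatomic(diatomic):
    geom, params = diatomic
    return make_context(geom, params, BseSettings())


@pytest.fixture(scope="session")
def ctx_chain6():
    geom, params = fixture("chain", 6)
    return make_context(geom, params, BseSettings())


@pytest.fixture(scope="session")
def ctx_ring6():
    geom, params = fixture("ring", 6)
    return make_context(geom, params, BseSettings())


@pytest.fixture(scope="session")
def all_contexts(ctx_diatomic, ctx_chain6, ctx_ring6):
    return {"diatomic": ctx_diatomic, "chain6": ctx_chain6, "ring6": ctx_ring6}


@pytest.fixture(scope="session")
def eset_diatomic(ctx_diatomic):
    return solve_dense(ctx_diatomic, 4)


def random_exciton(mf, rng) -> ExcitonState:
    """Normalized random excitation in the conduction subspace of ``mf``."""
    pc = mf.conduction_projector()
    b = rng.standard_normal((mf.n_valence, mf.n_sites)) @ pc.T
    b /= np.sqrt(np.sum(b * b))
    return ExcitonState(batches=b, mf_ref=mf, omega=None)
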