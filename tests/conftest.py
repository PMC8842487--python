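import numpy as np
import pytest

from micellex.chain import PairPotential
from micellex.equilibrium import ConformationEnsemble, ShellLattice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_lattice():
    """Three wide shells; roomy enough that toy ensembles stay dilute."""
    return ShellLattice(np.array([0.0, 4.0, 8.0, 12.0]), 4.0)


def make_toy_ensemble(lattice, M=6, seed=0, scale=1.0):
    """Small random toy ensemble with a uniform a-priori measure.

    Projections are arbitrary but kept dilute so the incompressibility
    closure stays in its smooth regime.
    """
    r = np.random.default_rng(seed)
    J = lattice.n_shells
    return ConformationEnsemble(
        n_EO=scale * r.integers(0, 10, (M, J)).astype(float),
        n_PO=scale * r.integers(0, 8, (M, J)).astype(float),
        Phi_EO=scale * r.uniform(0, 0.3, (M, J)),
        Phi_PO=scale * r.uniform(0, 0.3, (M, J)),
        U=r.uniform(0, 2, M),
        log_w0=np.log(np.full(M, lattice.V / M)),
        lattice=lattice,
    )


@pytest.fixture
def toy_ensemble(toy_lattice):
    return make_toy_ensemble(toy_lattice)


@pytest.fixture
def potential():
    return PairPotential()
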