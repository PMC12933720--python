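import numpy as np
import pytest

from cgbench.box import Box
from cgbench.forcefield import ForceField, ForceFieldParams
from cgbench.systems import (build_chain_liquid, build_chiral_mimic,
                             build_helix_chain, generate_reference)
from cgbench.topology import Topology, linear_chain_topology


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_liquid():
    """27 hexane-like chains in a periodic box (session-shared)."""
    return build_chain_liquid(27, 6, molecule_density=1.0, seed=1)


@pytest.fixture(scope="session")
def liquid_reference(small_liquid):
    return generate_reference(small_liquid, n_steps=600, stride=30, seed=2)


@pytest.fixture(scope="session")
def helix_system():
    return build_helix_chain(15)


@pytest.fixture(scope="session")
def helix_reference(helix_system):
    return generate_reference(helix_system, n_steps=2000, stride=20, seed=5)


@pytest.fixture
def dimer():
    """Two bonded sites with a stiff harmonic bond, open box."""
    top = Topology(["A", "A"], [12.0, 12.0], [0, 0], bonds=[(0, 1)])
    params = ForceFieldParams(bond_k=[1000.0], bond_r0=[0.3])
    return top, params, ForceField(top, params)


def random_chain_system(seed, n_chains=2, length=5):
    """Small vacuum chain system with all bonded term families."""
    top = linear_chain_topology(length, n_chains)
    rng = np.random.default_rng(seed)
    params = ForceFieldParams(
        bond_k=np.full(len(top.bonds), 800.0),
        bond_r0=np.full(len(top.bonds), 0.2),
        angle_k=np.full(len(top.angles), 60.0),
        angle_theta0=np.full(len(top.angles), np.radians(110.0)),
        dihedral_k=np.full(len(top.dihedrals), 3.0),
        dihedral_mult=np.full(len(top.dihedrals), 3, dtype=int),
        dihedral_phase=np.zeros(len(top.dihedrals)),
        lj={"C": (0.3, 0.25)}, r_cut=0.9, exclusion_rule="bonded123")
    # near-linear chains with jitter, no overlaps
    pos = np.zeros((top.n_atoms, 3))
    for c in range(n_chains):
        for i in range(length):
            pos[c * length + i] = [0.19 * i, 0.45 * c, 0.0]
    pos += rng.normal(scale=0.03, size=pos.shape)
    return top, params, pos
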