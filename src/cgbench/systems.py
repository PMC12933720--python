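"""Builders for the toy reference systems and reference-trajectory generation.

Three systems emulate the benchmark's study conditions at desk scale:

* a liquid of short united-site chains (hexane-like), with the ratio of the
  bond length to the Lennard-Jones diameter exposed so the bonded and
  nonbonded length scales can be made to overlap or not;
* a small capped molecule whose stereocenter is enforced by a double-well
  improper dihedral (both enantiomers, with variants that delete the
  center substituent or the whole side group);
* a helix-forming chain of C-alpha-like sites whose backbone dihedral bias
  makes a right-handed helix the global minimum.

All builders are deterministic given their seed, and all reference
trajectories store the exact forces at the stored configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .box import Box
from .forcefield import (IMPROPER_DOUBLEWELL, ForceField, ForceFieldParams)
from .geometry import dihedrals_and_grads
from .integrate import integrate_langevin
from .state import MDState, maxwell_boltzmann_velocities
from .topology import Topology, enumerate_bonded_terms, linear_chain_topology
from .trajectory import Trajectory

DEG = np.pi / 180.0


@dataclass
class SystemSpec:
    """A buildable system: topology + force-field parameters + initial state."""

    topology: Topology
    params: ForceFieldParams
    state: MDState
    label: str = ""

    def __post_init__(self):
        if self.topology.n_atoms != self.state.n_atoms:
            raise ValueError("topology/state size mismatch")

    @property
    def forcefield(self) -> ForceField:
        return ForceField(self.topology, self.params)


# ---------------------------------------------------------------------------
# chain liquid

def _zigzag(chain_length: int, r0: float, theta0: float) -> np.ndarray:
    """Planar zigzag chain advancing along +z, centered at the origin."""
    half = (np.pi - theta0) / 2.0
    dz = r0 * np.cos(half)
    dx = r0 * np.sin(half)
    pos = np.zeros((chain_length, 3))
    for i in range(1, chain_length):
        pos[i] = pos[i - 1] + [dx * (1 if i % 2 else -1), 0.0, dz]
    return pos - pos.mean(axis=0)


def build_chain_liquid(n_molecules: int = 100, chain_length: int = 6,
                       molecule_density: float = 2.5,
                       forcefield_overrides: dict | None = None,
                       seed: int = 0) -> SystemSpec:
    """Periodic liquid of linear united-site chains on a perturbed lattice.

    molecule_density is molecules per nm^3 and fixes the cubic box volume.
    Default force field: stiff harmonic bonds (r0 = 0.153 nm), harmonic
    angles (114 deg), a threefold torsion, and cut-shifted LJ
    (sigma = 0.395 nm) with 1-2/1-3 exclusions. ``forcefield_overrides``
    patches any ForceFieldParams field default (e.g. bond r0 relative to
    sigma, to tune bonded/nonbonded length-scale overlap).
    """
    defaults = dict(bond_k=30000.0, bond_r0=0.153, angle_k=250.0,
                    angle_theta0=114.0 * DEG, dihedral_k=4.0,
                    dihedral_mult=3, dihedral_phase=0.0,
                    lj={"C": (0.45, 0.395)}, r_cut=1.0,
                    exclusion_rule="bonded1234")
    defaults.update(forcefield_overrides or {})
    top = linear_chain_topology(chain_length, n_molecules, species="C",
                                mass=14.027, end_mass=15.035)
    params = ForceFieldParams(
        bond_k=np.full(len(top.bonds), defaults["bond_k"]),
        bond_r0=np.full(len(top.bonds), defaults["bond_r0"]),
        angle_k=np.full(len(top.angles), defaults["angle_k"]),
        angle_theta0=np.full(len(top.angles), defaults["angle_theta0"]),
        dihedral_k=np.full(len(top.dihedrals), defaults["dihedral_k"]),
        dihedral_mult=np.full(len(top.dihedrals), defaults["dihedral_mult"],
                              dtype=int),
        dihedral_phase=np.full(len(top.dihedrals), defaults["dihedral_phase"]),
        lj=defaults["lj"], r_cut=defaults["r_cut"],
        exclusion_rule=defaults["exclusion_rule"])

    edge = (n_molecules / molecule_density) ** (1.0 / 3.0)
    box = Box.cubic(edge)
    template = _zigzag(chain_length, defaults["bond_r0"],
                       defaults["angle_theta0"])
    extent = float(np.ptp(template[:, 2]))
    # columns along z; lateral square grid
    sigma = max(s for _, s in defaults["lj"].values())
    nx = int(edge // (0.45 if sigma > 0.3 else 0.3))
    if nx < 1:
        raise ValueError("density too high: no lateral lattice fits the box")
    nz = int(np.ceil(n_molecules / (nx * nx)))
    if edge / nz < extent + 0.15:
        raise ValueError("density too high: chains do not fit along z")
    rng = np.random.default_rng(seed)
    positions = np.zeros((top.n_atoms, 3))
    mol = 0
    for iz in range(nz):
        for ix in range(nx):
            for iy in range(nx):
                if mol >= n_molecules:
                    break
                angle = rng.uniform(0, 2 * np.pi)
                c, s = np.cos(angle), np.sin(angle)
                rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
                center = np.array([(ix + 0.5) * edge / nx,
                                   (iy + 0.5) * edge / nx,
                                   (iz + 0.5) * edge / nz])
                jitter = rng.normal(scale=0.02, size=3)
                chain = template @ rot.T + center + jitter
                positions[mol * chain_length:(mol + 1) * chain_length] = chain
                mol += 1
    state = MDState(positions, np.zeros_like(positions), top.masses, box)
    return SystemSpec(top, params, state,
                      label=f"chain_liquid(n={n_molecules},len={chain_length})")


def build_dimer_gas(n_dimers: int = 20, bond_k: float = 1000.0,
                    bond_r0: float = 0.3, lj_eps: float = 0.5,
                    lj_sigma: float = 0.33, edge: float = 3.2,
                    seed: int = 0) -> SystemSpec:
    """Periodic gas of harmonic dimers with LJ between non-bonded sites.

    A CG-resolution reference whose true pair interactions are known in
    closed form — the canonical fixture for force-matching recovery.
    """
    n = 2 * n_dimers
    bonds = [(2 * i, 2 * i + 1) for i in range(n_dimers)]
    top = Topology(["A"] * n, np.full(n, 12.0),
                   np.repeat(np.arange(n_dimers), 2), bonds=bonds)
    params = ForceFieldParams(
        bond_k=np.full(n_dimers, bond_k), bond_r0=np.full(n_dimers, bond_r0),
        lj={"A": (lj_eps, lj_sigma)}, r_cut=1.0, exclusion_rule="bonded12")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(n_dimers ** (1 / 3)))
    grid = np.linspace(0.4, edge - 0.4, side)
    centers = [(x, y, z) for x in grid for y in grid for z in grid]
    pos = []
    for i in range(n_dimers):
        c = np.array(centers[i]) + rng.normal(scale=0.05, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pos += [c - 0.5 * bond_r0 * d, c + 0.5 * bond_r0 * d]
    state = MDState(np.array(pos), np.zeros((n, 3)), top.masses,
                    Box.cubic(edge))
    return SystemSpec(top, params, state, label=f"dimer_gas(n={n_dimers})")


# ---------------------------------------------------------------------------
# chiral mimic

def _place_substituent(b2, b3, b4, direction_sign, tilt):
    """Unit direction from the center b3, mixing the in-plane outward
    bisector with the plane normal."""
    u = b2 - b3
    v = b4 - b3
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    outward = -(u + v)
    outward /= np.linalg.norm(outward)
    normal = np.cross(u, v)
    normal /= np.linalg.norm(normal)
    d = np.cos(tilt) * outward + np.sin(tilt) * direction_sign * normal
    return d / np.linalg.norm(d)


def build_chiral_mimic(enantiomer: str = "L", variant: str = "full",
                       improper_barrier: float = 40.0,
                       xi0_deg: float = 35.0) -> SystemSpec:
    """Capped-backbone toy with a stereocenter.

    Five backbone sites B1-B2-B3-B4-B5 with, at the center B3, a light
    substituent H and a side group S (per variant). Chirality is a
    double-well improper over (B2, B4, B3, S) with minima at +-xi0 and a
    barrier ``improper_barrier`` (kJ/mol) at the planar geometry — the
    force field itself is parity-even, so the two enantiomers differ only
    by which basin the geometry occupies.

    variant: 'full' (H and S), 'no_center_H' (S only), 'no_sidechain'
    (H only; the improper, and with it formal chirality, is gone).
    """
    if enantiomer not in ("L", "D"):
        raise ValueError("enantiomer must be 'L' or 'D'")
    if variant not in ("full", "no_center_H", "no_sidechain"):
        raise ValueError(f"unknown variant {variant!r}")
    r0_bb, r0_sub = 0.15, 0.15
    backbone = _zigzag(5, r0_bb, 111.0 * DEG)
    species = ["B1", "B2", "CA", "B4", "B5"]
    masses = [15.035, 14.027, 12.011, 14.027, 15.035]
    coords = [backbone[i] for i in range(5)]
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4)]
    b2, b3, b4 = backbone[1], backbone[2], backbone[3]

    has_h = variant in ("full", "no_sidechain")
    has_s = variant in ("full", "no_center_H")
    s_index = None
    xi0 = xi0_deg * DEG

    if has_s:
        s_index = len(coords)
        species.append("S")
        masses.append(15.035)
        bonds.append((2, s_index))

        # improper over (B3, B2, B4, S): 0 at the planar geometry, growing
        # with the out-of-plane tilt of the side group
        def xi_of_tilt(tilt):
            pos = np.array(coords + [b3 + r0_sub *
                                     _place_substituent(b2, b3, b4, +1.0, tilt)])
            quad = np.array([[2, 1, 3, s_index]])
            phi, _ = dihedrals_and_grads(pos, quad)
            return float(phi[0]) - xi0

        tilt = brentq(xi_of_tilt, 0.05, np.pi / 2 - 0.05)
        coords.append(b3 + r0_sub * _place_substituent(b2, b3, b4, +1.0, tilt))
    if has_h:
        h_dir = _place_substituent(b2, b3, b4, -1.0, 55.0 * DEG)
        species.append("H")
        masses.append(1.008)
        bonds.append((2, len(coords)))
        coords.append(b3 + 0.11 * h_dir)

    positions = np.array(coords)
    n = len(positions)
    bonds = np.array(bonds, dtype=int)
    angles, dihedrals = enumerate_bonded_terms(bonds, n)
    impropers = (np.array([[2, 1, 3, s_index]], dtype=int)
                 if has_s else np.zeros((0, 4), dtype=int))
    top = Topology(species, masses, np.zeros(n, dtype=int), bonds, angles,
                   dihedrals, impropers)

    bond_r0 = []
    for i, j in bonds:
        bond_r0.append(float(np.linalg.norm(positions[j] - positions[i])))
    theta0, _ = _measure_angles(positions, angles)
    lj = {s: (0.2, 0.30) for s in set(species)}
    lj["H"] = (0.1, 0.20)
    params = ForceFieldParams(
        bond_k=np.full(len(bonds), 8000.0), bond_r0=np.array(bond_r0),
        angle_k=np.full(len(angles), 300.0), angle_theta0=theta0,
        dihedral_k=np.full(len(dihedrals), 2.0),
        dihedral_mult=np.full(len(dihedrals), 3, dtype=int),
        dihedral_phase=np.zeros(len(dihedrals)),
        improper_kind=[IMPROPER_DOUBLEWELL] * len(impropers),
        improper_k=np.full(len(impropers), improper_barrier),
        improper_xi0=np.full(len(impropers), xi0),
        lj=lj, r_cut=1.0, exclusion_rule="bonded123")

    if enantiomer == "D":
        positions = positions * np.array([1.0, 1.0, -1.0])
    state = MDState(positions, np.zeros_like(positions), top.masses,
                    Box.open())
    return SystemSpec(top, params, state,
                      label=f"chiral_mimic({enantiomer},{variant})")


def _measure_angles(positions, angles):
    from .geometry import angles_and_grads
    if len(angles) == 0:
        return np.zeros(0), None
    theta, grads = angles_and_grads(positions, angles)
    return theta, grads


# ---------------------------------------------------------------------------
# helix chain

def ideal_helix(n_sites: int, d0: float = 0.5, radius: float = 0.23,
                twist_deg: float = 100.0) -> np.ndarray:
    """Right-handed helix of C-alpha-like sites whose (i, i+3) distances
    all equal d0 exactly (the rise is solved from radius and twist)."""
    twist = twist_deg * DEG
    chord3 = 2.0 * radius * abs(np.sin(1.5 * twist))
    if chord3 >= d0:
        raise ValueError("radius/twist incompatible with requested d0")
    rise = np.sqrt(d0 * d0 - chord3 * chord3) / 3.0
    i = np.arange(n_sites)
    return np.stack([radius * np.cos(i * twist), radius * np.sin(i * twist),
                     i * rise], axis=1)


def build_helix_chain(n_residues: int = 15, dihedral_k: float = 8.0,
                      seed: int = 0) -> SystemSpec:
    """Chain of C-alpha-like sites with a chiral backbone dihedral bias.

    Bond and angle minima are taken from the ideal right-handed helix; each
    (i..i+3) backbone dihedral carries U = k (1 - cos(phi - phi_helix)),
    whose single minimum at the right-handed value breaks parity (the
    chiral bias). The ideal helix is the initial state.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    positions = ideal_helix(n_residues)
    top = linear_chain_topology(n_residues, 1, species="CA", mass=12.011)
    r0 = float(np.linalg.norm(positions[1] - positions[0]))
    theta0, _ = _measure_angles(positions, top.angles)
    phi0, _ = dihedrals_and_grads(positions, top.dihedrals)
    params = ForceFieldParams(
        bond_k=np.full(len(top.bonds), 8000.0),
        bond_r0=np.full(len(top.bonds), r0),
        angle_k=np.full(len(top.angles), 100.0), angle_theta0=theta0,
        dihedral_k=np.full(len(top.dihedrals), dihedral_k),
        # U = k (1 + cos(phi - phi0 - pi)) has its minimum at phi0
        dihedral_mult=np.ones(len(top.dihedrals), dtype=int),
        dihedral_phase=phi0 + np.pi,
        lj={"CA": (0.30, 0.45)}, r_cut=1.2, exclusion_rule="bonded123")
    state = MDState(positions, np.zeros_like(positions), top.masses,
                    Box.open())
    return SystemSpec(top, params, state, label=f"helix_chain(n={n_residues})")


# ---------------------------------------------------------------------------
# reference generation and parity

def generate_reference(system: SystemSpec, temperature: float = 300.0,
                       dt: float = 0.002, n_steps: int = 1000,
                       stride: int = 10, friction: float = 5.0,
                       seed: int = 0) -> Trajectory:
    """Langevin NVT reference run with per-frame forces.

    Velocities are drawn from the Maxwell-Boltzmann distribution at the
    target temperature; the whole run is deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    state = system.state.copy()
    state.velocities = maxwell_boltzmann_velocities(state.masses, temperature,
                                                    rng)
    return integrate_langevin(state, system.forcefield, dt, temperature,
                              friction, n_steps, seed=int(rng.integers(2**31)),
                              stride=stride, species=system.topology.species)


def mirror(obj):
    """Reflect through the z = 0 plane (positions, velocities, forces).

    Accepts an (..., 3) array, an MDState or a Trajectory; returns the same
    type. Applying it twice is the identity.
    """
    flip = np.array([1.0, 1.0, -1.0])
    if isinstance(obj, np.ndarray):
        return obj * flip
    if isinstance(obj, MDState):
        return MDState(obj.positions * flip, obj.velocities * flip,
                       obj.masses.copy(), obj.box, obj.time)
    if isinstance(obj, Trajectory):
        return Trajectory(
            obj.positions * flip, obj.box, obj.times.copy(),
            None if obj.forces is None else obj.forces * flip,
            None if obj.velocities is None else obj.velocities * flip,
            None if obj.energies is None else obj.energies.copy(),
            obj.species, obj.masses)
    raise TypeError(f"cannot mirror {type(obj)!r}")
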