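"""Classical force field terms and their analytic forces.

Functional families (energies kJ/mol, lengths nm, angles rad):

* bond:      U = 1/2 k (r - r0)^2
* angle:     U = 1/2 k (theta - theta0)^2
* dihedral:  U = k (1 + cos(m*phi - phase))
* improper:  harmonic  U = 1/2 k (wrap(xi - xi0))^2
             doublewell U = h ((xi/xi0)^2 - 1)^2   (minima at +-xi0, barrier h
             at the planar geometry; used to encode a stereocenter whose
             inversion is a finite kinetic barrier)
* nonbonded: Lennard-Jones, energy shifted to zero at r_cut, with
             Lorentz-Berthelot mixing between species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .box import Box
from .geometry import (DegenerateGeometryError, angles_and_grads,
                       bond_lengths, dihedrals_and_grads, wrap_angle)
from .topology import Topology

_R_FLOOR = 1e-3  # nm; below this a nonbonded pair is treated as an overlap error

IMPROPER_HARMONIC = "harmonic"
IMPROPER_DOUBLEWELL = "doublewell"


@dataclass
class ForceFieldParams:
    """Per-term parameter arrays, aligned with the topology's term lists."""

    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedral_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedral_mult: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    dihedral_phase: np.ndarray = field(default_factory=lambda: np.zeros(0))
    improper_kind: list = field(default_factory=list)
    improper_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    improper_xi0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lj: dict = field(default_factory=dict)  # species -> (epsilon, sigma)
    r_cut: float = 1.0
    exclusion_rule: str = "bonded123"

    def __post_init__(self):
        for name in ("bond_k", "bond_r0", "angle_k", "angle_theta0",
                     "dihedral_k", "dihedral_phase", "improper_k",
                     "improper_xi0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.dihedral_mult = np.asarray(self.dihedral_mult, dtype=int)
        if np.any(self.bond_k < 0) or np.any(self.angle_k < 0):
            raise ValueError("force constants must be non-negative")
        for eps, sig in self.lj.values():
            if sig <= 0:
                raise ValueError("LJ sigma must be positive")
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")


def compute_bonded(positions: np.ndarray, box: Box | None, topology: Topology,
                   params: ForceFieldParams):
    """Energy and forces of all bonded terms. Forces are the exact negative
    analytic gradient of the energy."""
    n = len(positions)
    energy = 0.0
    forces = np.zeros((n, 3))

    if len(topology.bonds):
        r, rvec = bond_lengths(positions, topology.bonds, box)
        if np.any(r < 1e-10):
            bad = int(np.argmin(r))
            raise DegenerateGeometryError(
                f"zero-length bond term {bad} (atoms {tuple(topology.bonds[bad])})")
        dr = r - params.bond_r0
        energy += float(np.sum(0.5 * params.bond_k * dr * dr))
        dUdr = params.bond_k * dr
        fpair = -(dUdr / r)[:, None] * rvec  # force on atom j (i->j vector)
        np.add.at(forces, topology.bonds[:, 1], fpair)
        np.add.at(forces, topology.bonds[:, 0], -fpair)

    if len(topology.angles):
        theta, grads = angles_and_grads(positions, topology.angles, box, "angle")
        dth = theta - params.angle_theta0
        energy += float(np.sum(0.5 * params.angle_k * dth * dth))
        dUdth = params.angle_k * dth
        for col in range(3):
            np.add.at(forces, topology.angles[:, col],
                      -dUdth[:, None] * grads[:, col, :])

    if len(topology.dihedrals):
        phi, grads = dihedrals_and_grads(positions, topology.dihedrals, box,
                                         "dihedral")
        arg = params.dihedral_mult * phi - params.dihedral_phase
        energy += float(np.sum(params.dihedral_k * (1.0 + np.cos(arg))))
        dUdphi = -params.dihedral_k * params.dihedral_mult * np.sin(arg)
        for col in range(4):
            np.add.at(forces, topology.dihedrals[:, col],
                      -dUdphi[:, None] * grads[:, col, :])

    if len(topology.impropers):
        xi, grads = dihedrals_and_grads(positions, topology.impropers, box,
                                        "improper")
        dUdxi = np.zeros_like(xi)
        for t, kind in enumerate(params.improper_kind):
            if kind == IMPROPER_HARMONIC:
                d = float(wrap_angle(xi[t] - params.improper_xi0[t]))
                energy += 0.5 * params.improper_k[t] * d * d
                dUdxi[t] = params.improper_k[t] * d
            elif kind == IMPROPER_DOUBLEWELL:
                x0 = params.improper_xi0[t]
                h = params.improper_k[t]
                q = (xi[t] / x0) ** 2 - 1.0
                energy += h * q * q
                dUdxi[t] = 4.0 * h * xi[t] * q / (x0 * x0)
            else:
                raise ValueError(f"unknown improper kind {kind!r}")
        for col in range(4):
            np.add.at(forces, topology.impropers[:, col],
                      -dUdxi[:, None] * grads[:, col, :])

    return energy, forces


def lj_pair_tables(species: list, lj: dict):
    """Species-index array plus epsilon/sigma matrices under
    Lorentz-Berthelot mixing."""
    labels = sorted(lj.keys())
    index = {s: i for i, s in enumerate(labels)}
    sidx = np.array([index[s] for s in species], dtype=int)
    eps = np.array([lj[s][0] for s in labels])
    sig = np.array([lj[s][1] for s in labels])
    eps_mat = np.sqrt(np.outer(eps, eps))
    sig_mat = 0.5 * (sig[:, None] + sig[None, :])
    return sidx, eps_mat, sig_mat


def compute_nonbonded(positions: np.ndarray, box: Box | None, species: list,
                      params: ForceFieldParams, pairs: np.ndarray,
                      exclusions: set | None = None):
    """Cut-and-shifted Lennard-Jones over a pair list.

    ``pairs`` must cover every non-excluded pair within r_cut (a Verlet list
    with skin is fine; pairs beyond r_cut contribute exactly zero).
    """
    n = len(positions)
    forces = np.zeros((n, 3))
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if len(pairs) == 0 or not params.lj:
        return 0.0, forces
    if exclusions:
        keys = pairs.min(axis=1).astype(np.int64) * n + pairs.max(axis=1)
        exkeys = np.array([i * n + j for i, j in exclusions], dtype=np.int64)
        pairs = pairs[~np.isin(keys, exkeys)]
        if len(pairs) == 0:
            return 0.0, forces

    rvec = positions[pairs[:, 1]] - positions[pairs[:, 0]]
    if box is not None:
        rvec = box.minimum_image(rvec)
    r = np.linalg.norm(rvec, axis=1)
    if np.any(r < _R_FLOOR):
        bad = int(np.argmin(r))
        raise DegenerateGeometryError(
            f"overlapping particles {tuple(pairs[bad])} at r={r[bad]:.2e} nm")
    within = r < params.r_cut
    if not np.any(within):
        return 0.0, forces
    pairs, rvec, r = pairs[within], rvec[within], r[within]

    sidx, eps_mat, sig_mat = lj_pair_tables(species, params.lj)
    eps = eps_mat[sidx[pairs[:, 0]], sidx[pairs[:, 1]]]
    sig = sig_mat[sidx[pairs[:, 0]], sidx[pairs[:, 1]]]
    sr6 = (sig / r) ** 6
    src6 = (sig / params.r_cut) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6)
    u_shift = 4.0 * eps * (src6 * src6 - src6)
    energy = float(np.sum(u - u_shift))
    dUdr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    fpair = -(dUdr / r)[:, None] * rvec  # force on atom j
    np.add.at(forces, pairs[:, 1], fpair)
    np.add.at(forces, pairs[:, 0], -fpair)
    return energy, forces


class ForceField:
    """Topology-bound evaluator: total energy and forces at a configuration.

    Owns the exclusion set (derived once from the topology and the params'
    exclusion rule) and, when asked to evaluate without an explicit pair
    list, enumerates all in-range pairs itself.
    """

    def __init__(self, topology: Topology, params: ForceFieldParams):
        self.topology = topology
        self.params = params
        self.exclusions = (topology.exclusion_pairs(params.exclusion_rule)
                           if params.lj else set())

    def energy_forces(self, positions: np.ndarray, box: Box | None,
                      pairs: np.ndarray | None = None):
        e_b, f_b = compute_bonded(positions, box, self.topology, self.params)
        if self.params.lj:
            if pairs is None:
                from .neighbors import build_neighbor_list
                pairs = build_neighbor_list(positions, box, self.params.r_cut,
                                            skin=0.0)
            e_nb, f_nb = compute_nonbonded(positions, box, self.topology.species,
                                           self.params, pairs, self.exclusions)
        else:
            e_nb, f_nb = 0.0, 0.0
        return e_b + e_nb, f_b + f_nb

    def __call__(self, positions, box, pairs=None):
        return self.energy_forces(positions, box, pairs)
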