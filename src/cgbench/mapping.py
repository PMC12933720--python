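"""Center-of-mass coarse-grained mapping.

Bead positions are mass-weighted averages R_I = sum_i w_Ii r_i with
w_Ii = m_i / sum_j m_j over the bead's atom set (weights normalized to 1);
bead forces are the plain sums f_I = sum_i f_i. Atom sets must be disjoint
(each atom contributes to at most one bead); atoms left out of every bead
are dropped, forces included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import sparse

from .box import Box
from .topology import Topology, enumerate_bonded_terms
from .trajectory import Trajectory

SPECIES_MODES = ("element", "unique", "single", "alternating", "symmetric")


@dataclass
class BeadDef:
    """One CG bead: member atom indices, COM weights, label, molecule id."""

    atoms: np.ndarray
    weights: np.ndarray
    species: str = ""
    mol_id: int = 0

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.atoms) != len(self.weights) or len(self.atoms) == 0:
            raise ValueError("bead needs matching, non-empty atoms/weights")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be >= 0 and sum to 1")


def com_weights(topology: Topology, atom_sets: list) -> list:
    """BeadDefs with mass-normalized weights for disjoint atom index sets."""
    seen: set = set()
    beads = []
    for atoms in atom_sets:
        atoms = np.asarray(atoms, dtype=int)
        if len(atoms) == 0:
            raise ValueError("empty bead atom set")
        if atoms.min() < 0 or atoms.max() >= topology.n_atoms:
            raise ValueError("bead atom index out of range")
        overlap = seen.intersection(atoms.tolist())
        if overlap:
            raise ValueError(
                f"atom(s) {sorted(overlap)} assigned to more than one bead")
        seen.update(atoms.tolist())
        m = topology.masses[atoms]
        mols = set(topology.mol_ids[atoms].tolist())
        if len(mols) != 1:
            raise ValueError("bead spans multiple molecules")
        beads.append(BeadDef(atoms, m / m.sum(), mol_id=mols.pop()))
    return beads


def assign_species(beads: list, mode: str, topology: Topology) -> list:
    """Bead species labels under the requested encoding.

    element: label of the dominant-mass member atom; unique: positional
    label within the molecule; single: one shared label; alternating:
    ABAB... along each molecule; symmetric: palindromic along each molecule.
    """
    if mode not in SPECIES_MODES:
        raise ValueError(f"unknown species mode {mode!r}")
    labels = [""] * len(beads)
    by_mol: dict = {}
    for idx, bead in enumerate(beads):
        by_mol.setdefault(bead.mol_id, []).append(idx)
    for mol_beads in by_mol.values():
        n = len(mol_beads)
        for pos, idx in enumerate(mol_beads):
            bead = beads[idx]
            if mode == "element":
                dom = bead.atoms[int(np.argmax(topology.masses[bead.atoms]))]
                labels[idx] = topology.species[dom]
            elif mode == "unique":
                labels[idx] = f"U{pos}"
            elif mode == "single":
                labels[idx] = "X"
            elif mode == "alternating":
                labels[idx] = "A" if pos % 2 == 0 else "B"
            elif mode == "symmetric":
                labels[idx] = f"S{min(pos, n - 1 - pos)}"
    return labels


def derive_cg_topology(topology: Topology, beads: list):
    """CG bonds (bead pairs joined by at least one atomistic bond) plus
    angles and dihedrals enumerated from the CG bond graph."""
    bead_of = -np.ones(topology.n_atoms, dtype=int)
    for b, bead in enumerate(beads):
        bead_of[bead.atoms] = b
    cg_bonds = set()
    for i, j in topology.bonds:
        bi, bj = bead_of[i], bead_of[j]
        if bi >= 0 and bj >= 0 and bi != bj:
            cg_bonds.add((min(bi, bj), max(bi, bj)))
    cg_bonds = np.array(sorted(cg_bonds), dtype=int).reshape(-1, 2)
    angles, dihedrals = enumerate_bonded_terms(cg_bonds, len(beads))
    return cg_bonds, angles, dihedrals


@dataclass
class MappingScheme:
    """Ordered bead definitions plus derived CG connectivity and species."""

    beads: list
    species_mode: str
    n_atoms: int
    cg_bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    cg_angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    cg_dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), int))

    def __post_init__(self):
        self._wmat = None
        self._smat = None

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def species(self) -> list:
        return [b.species for b in self.beads]

    def weight_matrix(self) -> sparse.csr_matrix:
        """(n_beads, n_atoms) COM weight matrix."""
        if self._wmat is None:
            rows, cols, vals = [], [], []
            for b, bead in enumerate(self.beads):
                rows += [b] * len(bead.atoms)
                cols += bead.atoms.tolist()
                vals += bead.weights.tolist()
            self._wmat = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(self.n_beads, self.n_atoms))
        return self._wmat

    def sum_matrix(self) -> sparse.csr_matrix:
        """(n_beads, n_atoms) 0/1 force-aggregation matrix."""
        if self._smat is None:
            rows, cols = [], []
            for b, bead in enumerate(self.beads):
                rows += [b] * len(bead.atoms)
                cols += bead.atoms.tolist()
            self._smat = sparse.csr_matrix(
                (np.ones(len(rows)), (rows, cols)),
                shape=(self.n_beads, self.n_atoms))
        return self._smat

    def cg_topology(self, topology: Topology) -> Topology:
        """Bead-level Topology (species, summed masses, connectivity)."""
        masses = np.array([topology.masses[b.atoms].sum() for b in self.beads])
        mol_ids = np.array([b.mol_id for b in self.beads])
        return Topology(self.species, masses, mol_ids, self.cg_bonds,
                        self.cg_angles, self.cg_dihedrals)


def make_mapping(topology: Topology, atom_sets: list,
                 species_mode: str = "element") -> MappingScheme:
    """Build a MappingScheme from atom index sets: COM weights, species
    labels, and derived CG connectivity."""
    beads = com_weights(topology, atom_sets)
    labels = assign_species(beads, species_mode, topology)
    for bead, lab in zip(beads, labels):
        bead.species = lab
    bonds, angles, dihedrals = derive_cg_topology(topology, beads)
    return MappingScheme(beads, species_mode, topology.n_atoms, bonds,
                         angles, dihedrals)


def chain_mapping(topology: Topology, pattern: list,
                  species_mode: str = "element") -> MappingScheme:
    """Per-molecule mapping of chains: ``pattern`` gives consecutive group
    sizes (e.g. [2, 1, 1, 2] maps a 6-chain onto 4 beads, A-B-B-A style).
    Atoms beyond sum(pattern) in each molecule are left unmapped."""
    atom_sets = []
    for mol in np.unique(topology.mol_ids):
        atoms = np.flatnonzero(topology.mol_ids == mol)
        off = 0
        for size in pattern:
            if off + size > len(atoms):
                raise ValueError("pattern longer than molecule")
            atom_sets.append(atoms[off:off + size])
            off += size
    return make_mapping(topology, atom_sets, species_mode)


def identity_mapping(topology: Topology,
                     species_mode: str = "element") -> MappingScheme:
    return make_mapping(topology, [[i] for i in range(topology.n_atoms)],
                        species_mode)


def map_positions(positions: np.ndarray, scheme: MappingScheme) -> np.ndarray:
    """Weighted COM positions; expects whole (unwrapped) molecules."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != scheme.n_atoms:
        raise ValueError("position count does not match mapping")
    return scheme.weight_matrix() @ positions


def map_forces(forces: np.ndarray, scheme: MappingScheme) -> np.ndarray:
    """Unweighted per-bead force sums."""
    forces = np.asarray(forces, dtype=float)
    if forces.shape[0] != scheme.n_atoms:
        raise ValueError("force count does not match mapping")
    return scheme.sum_matrix() @ forces


def unwrap_molecules(positions: np.ndarray, topology: Topology,
                     box: Box) -> np.ndarray:
    """Make molecules whole across periodic boundaries by walking the bond
    graph from each molecule's first atom."""
    out = positions.copy()
    adj = topology.adjacency()
    for mol in np.unique(topology.mol_ids):
        atoms = np.flatnonzero(topology.mol_ids == mol)
        root = int(atoms[0])
        seen = {root}
        stack = [root]
        while stack:
            a = stack.pop()
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    out[b] = out[a] + box.minimum_image(positions[b] - out[a])
                    stack.append(b)
    return out


@dataclass
class CGTrajectory(Trajectory):
    """Mapped trajectory: bead positions and aggregated forces, plus the
    bead-level topology."""

    topology: Topology | None = None


def map_trajectory(traj: Trajectory, scheme: MappingScheme,
                   topology: Topology) -> CGTrajectory:
    """Framewise COM mapping of a reference trajectory with forces.

    Molecules are unwrapped before weighting; mapped bead positions are
    re-wrapped into the box.
    """
    if traj.forces is None:
        raise ValueError("reference trajectory must carry forces")
    periodic = bool(np.any(traj.box.periodic))
    R, F = [], []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        if periodic:
            pos = unwrap_molecules(pos, topology, traj.box)
        r = map_positions(pos, scheme)
        if periodic:
            r = traj.box.wrap(r)
        R.append(r)
        F.append(map_forces(traj.forces[f], scheme))
    cg_top = scheme.cg_topology(topology)
    return CGTrajectory(np.array(R), traj.box, traj.times.copy(),
                        forces=np.array(F), species=scheme.species,
                        masses=cg_top.masses, topology=cg_top)


def save_mapping(path, scheme: MappingScheme):
    """Structured text schema: species mode plus per-bead atom lists."""
    payload = {
        "species_mode": scheme.species_mode,
        "beads": [{"atoms": b.atoms.tolist(), "species": b.species}
                  for b in scheme.beads],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_mapping(path, topology: Topology) -> MappingScheme:
    payload = yaml.safe_load(Path(path).read_text())
    scheme = make_mapping(topology, [b["atoms"] for b in payload["beads"]],
                          payload.get("species_mode", "element"))
    for bead, rec in zip(scheme.beads, payload["beads"]):
        if rec.get("species"):
            bead.species = rec["species"]
    return scheme
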