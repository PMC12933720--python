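"""Molecular topology: atom records and bonded term index lists."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Topology:
    """Atoms plus bonded connectivity.

    species : list of str, per-atom type label
    masses : (n,) array, amu
    mol_ids : (n,) int array, molecule membership (each atom in exactly one)
    bonds/angles/dihedrals/impropers : (m, k) int index arrays
    """

    species: list
    masses: np.ndarray
    mol_ids: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=int))
    impropers: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=int))

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=int).reshape(-1, 3)
        self.dihedrals = np.asarray(self.dihedrals, dtype=int).reshape(-1, 4)
        self.impropers = np.asarray(self.impropers, dtype=int).reshape(-1, 4)
        n = self.n_atoms
        if len(self.species) != n or len(self.mol_ids) != n:
            raise ValueError("species/masses/mol_ids lengths disagree")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        for name, arr in (("bonds", self.bonds), ("angles", self.angles),
                          ("dihedrals", self.dihedrals), ("impropers", self.impropers)):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError(f"{name} reference atoms out of range")
        if self.bonds.size:
            canon = np.sort(self.bonds, axis=1)
            if len({tuple(b) for b in canon}) != len(canon):
                raise ValueError("duplicate bonds")
            if np.any(canon[:, 0] == canon[:, 1]):
                raise ValueError("self-bond")

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    def adjacency(self) -> list:
        """Neighbor lists of the bond graph."""
        adj = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].append(int(j))
            adj[j].append(int(i))
        return adj

    def exclusion_pairs(self, rule: str = "bonded123") -> set:
        """Set of (i, j) pairs (i < j) excluded from nonbonded interactions.

        rule: 'bonded12' (1-2 only), 'bonded123' (1-2 and 1-3),
        'bonded1234' (1-2, 1-3, 1-4).
        """
        depth = {"bonded12": 1, "bonded123": 2, "bonded1234": 3}[rule]
        adj = self.adjacency()
        excl = set()
        for start in range(self.n_atoms):
            frontier = {start}
            seen = {start}
            for _ in range(depth):
                nxt = set()
                for a in frontier:
                    for b in adj[a]:
                        if b not in seen:
                            nxt.add(b)
                seen |= nxt
                frontier = nxt
            for other in seen - {start}:
                excl.add((min(start, other), max(start, other)))
        return excl


def enumerate_bonded_terms(bonds: np.ndarray, n_atoms: int):
    """Angles and dihedrals as simple paths of length 2 and 3 in the bond
    graph; each path counted once (canonical direction)."""
    adj = [[] for _ in range(n_atoms)]
    for i, j in np.asarray(bonds, dtype=int).reshape(-1, 2):
        adj[i].append(int(j))
        adj[j].append(int(i))
    angles = []
    for j in range(n_atoms):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    dihedrals = []
    for j in range(n_atoms):
        for k in adj[j]:
            if j >= k:
                continue
            for i in adj[j]:
                if i == k:
                    continue
                for l in adj[k]:
                    if l == j or l == i:
                        continue
                    dihedrals.append((i, j, k, l))
    return (np.array(angles, dtype=int).reshape(-1, 3),
            np.array(dihedrals, dtype=int).reshape(-1, 4))


def linear_chain_topology(chain_length: int, n_chains: int = 1,
                          species: str = "C", mass: float = 14.027,
                          end_mass: float | None = None):
    """Topology of n identical linear chains with auto-enumerated angles
    and dihedrals. End sites may carry a different mass (e.g. united CH3)."""
    n = chain_length * n_chains
    masses = np.full(n, mass)
    if end_mass is not None and chain_length >= 2:
        for c in range(n_chains):
            masses[c * chain_length] = end_mass
            masses[c * chain_length + chain_length - 1] = end_mass
    mol_ids = np.repeat(np.arange(n_chains), chain_length)
    bonds = []
    for c in range(n_chains):
        off = c * chain_length
        bonds += [(off + i, off + i + 1) for i in range(chain_length - 1)]
    bonds = np.array(bonds, dtype=int).reshape(-1, 2)
    angles, dihedrals = enumerate_bonded_terms(bonds, n)
    return Topology([species] * n, masses, mol_ids, bonds, angles, dihedrals)
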