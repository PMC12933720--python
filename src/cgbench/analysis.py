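"""Structural observables for reference and CG trajectories.

Conventions: histograms use right-open bins; dihedral histograms live on
(-180, 180] degrees; free-energy surfaces come from Boltzmann inversion
F = -k_B T ln P with empty bins masked (NaN), shifted so the global
minimum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .box import Box
from .constants import KB
from .geometry import (angles_and_grads, bond_lengths, dihedrals_and_grads)
from .neighbors import build_neighbor_list
from .topology import Topology
from .trajectory import Trajectory


@dataclass
class Histogram1D:
    edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray = None
    n_samples: int = 0

    def __post_init__(self):
        if self.density is None and self.n_samples > 0:
            widths = np.diff(self.edges)
            self.density = self.counts / (self.n_samples * widths)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class Histogram2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray = None
    n_samples: int = 0

    def __post_init__(self):
        if self.density is None and self.n_samples > 0:
            area = np.outer(np.diff(self.x_edges), np.diff(self.y_edges))
            self.density = self.counts / (self.n_samples * area)


# ---------------------------------------------------------------------------
# pair structure

def rdf(traj: Trajectory, species_a: str, species_b: str,
        bin_width: float = 0.01, r_max: float | None = None,
        topology: Topology | None = None,
        exclusion: str = "bonds") -> Histogram1D:
    """Radial distribution function g_{A-B}(r), shell-normalized by
    4 pi r^2 rho_A dr, with bonded beads excluded.

    exclusion: 'none', 'bonds' (1-2, default) or 'bonds_angles' (1-3).
    """
    box = traj.box
    if not np.all(box.periodic):
        raise ValueError("RDF requires a fully periodic box")
    half = float(np.min(box.lengths)) / 2.0
    if r_max is None:
        r_max = half * 0.99
    if r_max > half:
        raise ValueError(f"r_max {r_max} exceeds half the box edge {half}")
    species = np.asarray(traj.species)
    idx_a = np.flatnonzero(species == species_a)
    idx_b = np.flatnonzero(species == species_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("no particles of the requested species")
    excl = set()
    if topology is not None and exclusion != "none":
        excl = topology.exclusion_pairs(
            "bonded12" if exclusion == "bonds" else "bonded123")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        pairs = build_neighbor_list(pos, box, min(r_max, half * 0.999))
        sp_i = species[pairs[:, 0]]
        sp_j = species[pairs[:, 1]]
        hit = (((sp_i == species_b) & (sp_j == species_a)) |
               ((sp_i == species_a) & (sp_j == species_b)))
        pairs = pairs[hit]
        if excl:
            pairs = np.array([p for p in pairs
                              if (min(p), max(p)) not in excl],
                             dtype=int).reshape(-1, 2)
        if len(pairs) == 0:
            continue
        r, _ = bond_lengths(pos, pairs, box)
        # A == B: each unordered pair is seen from both centrals
        weight = 2.0 if species_a == species_b else 1.0
        h, _ = np.histogram(r, bins=edges)
        counts += weight * h
    rho_a = len(idx_a) / box.volume
    shell = 4.0 * np.pi * (0.5 * (edges[:-1] + edges[1:])) ** 2 * bin_width
    # average A count per central B particle and frame, shell-normalized
    norm = traj.n_frames * len(idx_b) * shell * rho_a
    g = counts / norm
    return Histogram1D(edges, counts, density=g,
                       n_samples=traj.n_frames * len(idx_b))


def adf(traj: Trajectory, species_triplet: tuple, r_shell: float,
        bin_width_deg: float = 2.0) -> Histogram1D:
    """Angular distribution: angles at the central bead (middle species of
    the triplet) subtended by neighbor pairs of the flanking species
    within the shell radius."""
    s_left, s_center, s_right = species_triplet
    species = np.asarray(traj.species)
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    counts = np.zeros(len(edges) - 1)
    n_samples = 0
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        for c in np.flatnonzero(species == s_center):
            d = pos - pos[c]
            if traj.box is not None:
                d = traj.box.minimum_image(d)
            r = np.linalg.norm(d, axis=1)
            nb = np.flatnonzero((r < r_shell) & (r > 1e-9))
            left = [j for j in nb if species[j] == s_left]
            right = [j for j in nb if species[j] == s_right]
            for a in left:
                for b in right:
                    if a >= b and s_left == s_right:
                        continue
                    if a == b:
                        continue
                    ca = d[a] / r[a]
                    cb = d[b] / r[b]
                    ang = np.degrees(np.arccos(np.clip(ca @ cb, -1, 1)))
                    h, _ = np.histogram([ang], bins=edges)
                    counts += h
                    n_samples += 1
    return Histogram1D(edges, counts, n_samples=max(n_samples, 1))


# ---------------------------------------------------------------------------
# bonded distributions and free energies

def bonded_distributions(traj: Trajectory, topology: Topology,
                         bond_bin: float = 0.002,
                         angle_bin_deg: float = 2.0) -> dict:
    """Normalized histograms per bond/angle/dihedral type (types keyed by
    canonical species tuples)."""
    species = topology.species

    def canon(idx_row):
        s = tuple(species[i] for i in idx_row)
        if len(s) == 2:
            return tuple(sorted(s))
        return min(s, s[::-1])

    out = {"bond": {}, "angle": {}, "dihedral": {}}
    groups = {"bond": {}, "angle": {}, "dihedral": {}}
    for kind, arr in (("bond", topology.bonds), ("angle", topology.angles),
                      ("dihedral", topology.dihedrals)):
        for row in arr:
            groups[kind].setdefault(canon(row), []).append(row)
    for kind, grp in groups.items():
        for key, rows in grp.items():
            rows = np.array(rows, dtype=int)
            vals = []
            for f in range(traj.n_frames):
                pos = traj.positions[f]
                if kind == "bond":
                    q, _ = bond_lengths(pos, rows, traj.box)
                elif kind == "angle":
                    q = np.degrees(angles_and_grads(pos, rows, traj.box)[0])
                else:
                    q = np.degrees(dihedrals_and_grads(pos, rows, traj.box)[0])
                vals.append(q)
            vals = np.concatenate(vals)
            if kind == "bond":
                lo, hi = vals.min() - 5 * bond_bin, vals.max() + 5 * bond_bin
                edges = np.arange(lo, hi + bond_bin, bond_bin)
            elif kind == "angle":
                edges = np.arange(0.0, 180.0 + angle_bin_deg, angle_bin_deg)
            else:
                edges = np.arange(-180.0, 180.0 + angle_bin_deg, angle_bin_deg)
            counts, _ = np.histogram(vals, bins=edges)
            out[kind][key] = Histogram1D(edges, counts.astype(float),
                                         n_samples=len(vals))
    return out


def boltzmann_invert(hist, temperature: float):
    """F = -k_B T ln P on occupied bins; empty bins are NaN; the global
    minimum is shifted to zero. Works for 1D and 2D histograms."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    counts = np.asarray(hist.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    p = counts / counts.sum()
    F = np.full_like(p, np.nan)
    occ = p > 0
    F[occ] = -KB * temperature * np.log(p[occ])
    F -= np.nanmin(F)
    return F


def point_symmetry_score(density: np.ndarray) -> float:
    """Cosine similarity between a 2D density and its 180-degree rotation
    about the grid center; 1 means perfectly point-symmetric."""
    d = np.asarray(density, dtype=float)
    r = d[::-1, ::-1]
    num = float(np.sum(d * r))
    den = float(np.sqrt(np.sum(d * d) * np.sum(r * r)))
    return num / den if den > 0 else 0.0


def reflection_symmetry_score(density: np.ndarray, axis: int = 0) -> float:
    """Cosine similarity between a 2D density and its reflection along one
    axis (e.g. handedness chi -> -chi); 1 means perfectly mirror-symmetric."""
    d = np.asarray(density, dtype=float)
    r = np.flip(d, axis=axis)
    num = float(np.sum(d * r))
    den = float(np.sqrt(np.sum(d * d) * np.sum(r * r)))
    return num / den if den > 0 else 0.0


def ramachandran_fes(traj: Trajectory, phi_quads, psi_quads,
                     bins: int = 36, temperature: float = 300.0):
    """2D (phi, psi) histogram over (-180, 180]^2, its Boltzmann-inverted
    free energy surface, and the point-symmetry score of the density
    (quantifying enantiomer-symmetry artifacts)."""
    phi_quads = np.asarray(phi_quads, dtype=int).reshape(-1, 4)
    psi_quads = np.asarray(psi_quads, dtype=int).reshape(-1, 4)
    phis, psis = [], []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        phis.append(np.degrees(dihedrals_and_grads(pos, phi_quads,
                                                   traj.box)[0]))
        psis.append(np.degrees(dihedrals_and_grads(pos, psi_quads,
                                                   traj.box)[0]))
    phis = np.concatenate(phis)
    psis = np.concatenate(psis)
    edges = np.linspace(-180.0, 180.0, bins + 1)
    counts, _, _ = np.histogram2d(phis, psis, bins=[edges, edges])
    hist = Histogram2D(edges, edges, counts, n_samples=len(phis))
    fes = boltzmann_invert(hist, temperature)
    score = point_symmetry_score(hist.density)
    return hist, fes, score


# ---------------------------------------------------------------------------
# helicity and handedness

def q_hel(ca_positions: np.ndarray, d0: float = 0.5,
          sigma2: float = 0.02) -> float:
    """Fractional helix content: mean Gaussian score of the N_CA - 3
    third-neighbor distances around the optimal distance d0 (nm);
    1 is a perfect alpha helix, 0 completely unstructured."""
    pos = np.asarray(ca_positions, dtype=float).reshape(-1, 3)
    n = len(pos)
    if n < 4:
        raise ValueError("need at least 4 sites")
    d = np.linalg.norm(pos[3:] - pos[:-3], axis=1)
    return float(np.mean(np.exp(-(d - d0) ** 2 / (2.0 * sigma2))))


def chi_hel(ca_positions: np.ndarray) -> float:
    """Handedness index: mean mixed product v_i . (v_{i+1} x v_{i+2}) of
    consecutive bond vectors between neighboring sites (nm^3). Positive
    for right-handed helices, negative for left-handed; parity-odd."""
    pos = np.asarray(ca_positions, dtype=float).reshape(-1, 3)
    n = len(pos)
    if n < 4:
        raise ValueError("need at least 4 sites")
    v = pos[1:] - pos[:-1]
    mixed = np.einsum("ij,ij->i", v[:-2], np.cross(v[1:-1], v[2:]))
    return float(np.mean(mixed))


def helix_series(traj: Trajectory, d0: float = 0.5, sigma2: float = 0.02):
    """Per-frame (Q_hel, chi_hel) series."""
    Q = np.array([q_hel(traj.positions[f], d0, sigma2)
                  for f in range(traj.n_frames)])
    X = np.array([chi_hel(traj.positions[f]) for f in range(traj.n_frames)])
    return Q, X


def helix_fes(traj: Trajectory, bins: int = 30, temperature: float = 300.0,
              d0: float = 0.5, sigma2: float = 0.02):
    """Joint free energy F(chi_hel, Q_hel) by Boltzmann inversion, plus the
    left-/right-handed population fractions (chi < 0 vs chi > 0)."""
    Q, X = helix_series(traj, d0, sigma2)
    xmax = max(np.abs(X).max() * 1.05, 1e-6)
    x_edges = np.linspace(-xmax, xmax, bins + 1)
    q_edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _, _ = np.histogram2d(X, Q, bins=[x_edges, q_edges])
    hist = Histogram2D(x_edges, q_edges, counts, n_samples=len(X))
    fes = boltzmann_invert(hist, temperature)
    n_left = int(np.sum(X < 0))
    n_right = int(np.sum(X > 0))
    tot = max(n_left + n_right, 1)
    fractions = {"left": n_left / tot, "right": n_right / tot}
    return hist, fes, fractions


def rank_frames_for_refolding(q_series: np.ndarray, chi_series: np.ndarray,
                              n_select: int = 100) -> np.ndarray:
    """Indices of the n_select frames with the smallest |chi_hel * Q_hel|,
    ascending, ties broken by frame index (candidate unfolded starting
    structures for refolding runs)."""
    import warnings
    score = np.abs(np.asarray(q_series) * np.asarray(chi_series))
    if n_select > len(score):
        warnings.warn("n_select exceeds frame count; returning all frames")
        n_select = len(score)
    order = np.argsort(score, kind="stable")
    return order[:n_select]


# ---------------------------------------------------------------------------
# bond-partner permutation

@dataclass
class BondSwapReport:
    swap_counts: np.ndarray          # per frame
    identity_fraction: float         # fraction of (frame, bead) checks intact
    bonded_hist: Histogram1D         # distances to the initial bond partner
    nearest_hist: Histogram1D        # distances to the nearest compatible bead
    first_swap_frame: int | None = None


def bond_swap_analysis(traj: Trajectory, topology: Topology,
                       compatibility: str = "same_species",
                       bin_width: float = 0.005) -> BondSwapReport:
    """Detect bond-partner permutation against the initial bond list.

    For every bead with exactly one bonded partner, compare the distance
    to that partner with the distance to the nearest compatible bead
    ('same_species' or 'any'); a swap is counted when they differ.
    """
    species = np.asarray(topology.species)
    adj = topology.adjacency()
    centers = [i for i in range(topology.n_atoms) if len(adj[i]) >= 1]
    partner = {i: adj[i][0] if len(adj[i]) == 1 else None for i in centers}
    bonded_d, nearest_d = [], []
    swap_counts = np.zeros(traj.n_frames, dtype=int)
    checks = 0
    intact = 0
    first_swap = None
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        for i in centers:
            p = partner[i]
            if p is None:
                continue
            d = pos - pos[i]
            if traj.box is not None:
                d = traj.box.minimum_image(d)
            r = np.linalg.norm(d, axis=1)
            r[i] = np.inf
            if compatibility == "same_species":
                mask = species == species[p]
            else:
                mask = np.ones(len(r), dtype=bool)
            mask[i] = False
            cand = np.flatnonzero(mask)
            nearest = cand[np.argmin(r[cand])]
            bonded_d.append(r[p])
            nearest_d.append(r[nearest])
            checks += 1
            if nearest == p:
                intact += 1
            else:
                swap_counts[f] += 1
                if first_swap is None:
                    first_swap = f
    all_d = np.concatenate([bonded_d, nearest_d])
    edges = np.arange(0.0, all_d.max() + 2 * bin_width, bin_width)
    cb, _ = np.histogram(bonded_d, bins=edges)
    cn, _ = np.histogram(nearest_d, bins=edges)
    return BondSwapReport(
        swap_counts, intact / max(checks, 1),
        Histogram1D(edges, cb.astype(float), n_samples=len(bonded_d)),
        Histogram1D(edges, cn.astype(float), n_samples=len(nearest_d)),
        first_swap)


def count_modes(hist: Histogram1D, min_prominence: float = 0.1) -> int:
    """Number of local maxima in a (lightly smoothed) histogram density
    with prominence above min_prominence * max density."""
    from scipy.signal import find_peaks
    d = hist.density.copy()
    if len(d) > 4:
        kernel = np.array([0.25, 0.5, 0.25])
        d = np.convolve(d, kernel, mode="same")
    peaks, _ = find_peaks(d, prominence=min_prominence * d.max())
    return int(len(peaks))
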