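"""Structural observables: RDF, ADF, Boltzmann inversion, helicity,
handedness, frame ranking, bond-swap detection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgbench.analysis import (Histogram1D, adf, boltzmann_invert,
                              bond_swap_analysis, bonded_distributions,
                              chi_hel, count_modes, helix_fes, helix_series,
                              point_symmetry_score, q_hel, ramachandran_fes,
                              rank_frames_for_refolding, rdf)
from cgbench.box import Box
from cgbench.constants import KB
from cgbench.systems import ideal_helix, mirror
from cgbench.topology import Topology, linear_chain_topology
from cgbench.trajectory import Trajectory


def poisson_gas_traj(rng, n=400, edge=4.0, frames=6):
    pos = rng.uniform(0, edge, size=(frames, n, 3))
    return Trajectory(pos, Box.cubic(edge), np.arange(float(frames)),
                      species=["A"] * n)


class TestRDF:
    def test_ideal_gas_is_flat(self, rng):
        traj = poisson_gas_traj(rng)
        hist = rdf(traj, "A", "A", bin_width=0.05, r_max=1.8)
        sel = hist.centers > 0.3
        # counting noise: relative sigma ~ 1/sqrt(counts per bin)
        counts = np.maximum(hist.counts[sel], 1.0)
        dev = np.abs(hist.density[sel] - 1.0)
        assert np.all(dev < 4.0 / np.sqrt(counts) + 0.05)
        assert abs(np.mean(hist.density[sel]) - 1.0) < 0.02

    def test_hard_exclusion_zone(self, rng):
        """No pair closer than c => g(r) = 0 below c."""
        edge, c = 4.0, 0.5
        pos = [rng.uniform(0, edge, size=3)]
        box = Box.cubic(edge)
        while len(pos) < 80:
            cand = rng.uniform(0, edge, size=3)
            if all(np.linalg.norm(box.minimum_image(cand - p)) > c
                   for p in pos):
                pos.append(cand)
        traj = Trajectory(np.array(pos)[None], box, np.zeros(1),
                          species=["A"] * 80)
        hist = rdf(traj, "A", "A", bin_width=0.05, r_max=1.5)
        assert np.all(hist.density[hist.centers < c - 0.05] == 0.0)

    def test_matches_brute_force_histogram(self, rng):
        """Neighbor-list RDF counting equals a direct O(N^2) histogram."""
        traj = poisson_gas_traj(rng, n=50, frames=2)
        hist = rdf(traj, "A", "A", bin_width=0.1, r_max=1.5)
        edges = hist.edges
        brute = np.zeros(len(edges) - 1)
        for f in range(2):
            pos = traj.positions[f]
            for i in range(50):
                for j in range(i + 1, 50):
                    r = np.linalg.norm(traj.box.minimum_image(pos[j] - pos[i]))
                    if r < 1.5:
                        k = np.searchsorted(edges, r, side="right") - 1
                        if 0 <= k < len(brute):
                            brute[k] += 2
        assert np.array_equal(hist.counts, brute)

    def test_bonded_pairs_excluded(self):
        top = linear_chain_topology(2, 10, mass=1.0)
        box = Box.cubic(3.0)
        rng = np.random.default_rng(0)
        pos = np.zeros((20, 3))
        for m in range(10):
            base = rng.uniform(0.5, 2.5, size=3)
            pos[2 * m] = base
            pos[2 * m + 1] = base + [0.2, 0, 0]
        traj = Trajectory(pos[None], box, np.zeros(1), species=["C"] * 20)
        with_excl = rdf(traj, "C", "C", bin_width=0.05, r_max=1.4,
                        topology=top, exclusion="bonds")
        without = rdf(traj, "C", "C", bin_width=0.05, r_max=1.4,
                      topology=top, exclusion="none")
        near = np.abs(with_excl.centers - 0.2) < 0.06
        assert without.counts[near].sum() - with_excl.counts[near].sum() == 20

    def test_r_max_too_large_raises(self, rng):
        traj = poisson_gas_traj(rng, n=10, frames=1)
        with pytest.raises(ValueError, match="r_max"):
            rdf(traj, "A", "A", r_max=3.0)


class TestADF:
    def _traj(self, pos, species):
        return Trajectory(np.asarray(pos)[None], Box.cubic(10.0),
                          np.zeros(1), species=species)

    def test_collinear_triplet(self):
        traj = self._traj([[1.0, 1, 1], [1.5, 1, 1], [2.0, 1, 1]],
                          ["A", "A", "A"])
        hist = adf(traj, ("A", "A", "A"), r_shell=0.7)
        assert hist.counts[-1] == hist.counts.sum() > 0

    def test_equilateral_triplet(self):
        a = 0.5
        pos = [[1.0, 1, 1], [1 + a, 1, 1],
               [1 + a / 2, 1 + a * np.sqrt(3) / 2, 1]]
        hist = adf(self._traj(pos, ["A"] * 3), ("A", "A", "A"), r_shell=0.7)
        assert hist.counts.sum() == 3
        near60 = np.abs(hist.centers - 60.0) < 3.0
        assert hist.counts[near60].sum() == 3

    def test_matches_brute_force_enumeration(self, rng):
        n = 20
        pos = rng.uniform(2, 6, size=(n, 3))
        traj = self._traj(pos, ["A"] * n)
        hist = adf(traj, ("A", "A", "A"), r_shell=1.5, bin_width_deg=5.0)
        brute = np.zeros(len(hist.edges) - 1)
        for c in range(n):
            for a in range(n):
                for b in range(a + 1, n):
                    if c in (a, b):
                        continue
                    va, vb = pos[a] - pos[c], pos[b] - pos[c]
                    if np.linalg.norm(va) < 1.5 and np.linalg.norm(vb) < 1.5:
                        ang = np.degrees(np.arccos(np.clip(
                            va @ vb / np.linalg.norm(va) / np.linalg.norm(vb),
                            -1, 1)))
                        k = min(np.searchsorted(hist.edges, ang,
                                                side="right") - 1,
                                len(brute) - 1)
                        brute[k] += 1
        assert np.array_equal(hist.counts, brute)


class TestBondedDistributionsAndFES:
    def test_rigid_fixture_delta_histogram(self):
        top = linear_chain_topology(3, 1, mass=1.0)
        pos = np.array([[0.0, 0, 0], [0.3, 0, 0], [0.6, 0, 0]])
        traj = Trajectory(np.repeat(pos[None], 4, axis=0), Box.open(),
                          np.arange(4.0), species=["C"] * 3)
        dists = bonded_distributions(traj, top)
        bond_hist = dists["bond"][("C", "C")]
        assert (bond_hist.counts > 0).sum() == 1

    def test_harmonic_bond_variance(self):
        """Bond samples at temperature T: var within 10% of k_B T / k."""
        k, r0, T = 2000.0, 0.3, 300.0
        rng = np.random.default_rng(3)
        r = rng.normal(r0, np.sqrt(KB * T / k), size=4000)
        top = Topology(["C", "C"], [1.0, 1.0], [0, 0], bonds=[(0, 1)])
        pos = np.zeros((4000, 2, 3))
        pos[:, 1, 0] = r
        traj = Trajectory(pos, Box.open(), np.arange(4000.0),
                          species=["C", "C"])
        hist = bonded_distributions(traj, top, bond_bin=0.001)["bond"][
            ("C", "C")]
        var = np.sum(hist.density * np.diff(hist.edges) *
                     (hist.centers - np.sum(hist.density * hist.centers *
                                            np.diff(hist.edges))) ** 2)
        assert var == pytest.approx(KB * T / k, rel=0.1)

    def test_dihedral_histogram_normalized(self, rng):
        top = linear_chain_topology(4, 1, mass=1.0)
        pos = rng.normal(scale=0.4, size=(20, 4, 3))
        traj = Trajectory(pos, Box.open(), np.arange(20.0),
                          species=["C"] * 4)
        hist = bonded_distributions(traj, top)["dihedral"][
            ("C", "C", "C", "C")]
        assert np.sum(hist.density * np.diff(hist.edges)) == \
            pytest.approx(1.0, abs=1e-9)

    def test_boltzmann_uniform_is_flat_zero(self):
        hist = Histogram1D(np.linspace(0, 1, 11), np.full(10, 7.0),
                           n_samples=70)
        F = boltzmann_invert(hist, 300.0)
        assert np.allclose(F, 0.0, atol=1e-12)

    def test_boltzmann_two_to_one_ratio(self):
        """P ratio 2:1 at 300 K gives dF = k_B 300 ln 2 = 1.729 kJ/mol."""
        hist = Histogram1D(np.array([0.0, 1.0, 2.0]), np.array([200.0, 100.0]),
                           n_samples=300)
        F = boltzmann_invert(hist, 300.0)
        assert F[1] - F[0] == pytest.approx(KB * 300 * np.log(2), abs=1e-12)
        assert F[1] - F[0] == pytest.approx(1.729, abs=2e-3)

    def test_boltzmann_invariant_to_count_rescaling(self):
        a = Histogram1D(np.array([0.0, 1, 2, 3]), np.array([5.0, 10, 2]),
                        n_samples=17)
        b = Histogram1D(np.array([0.0, 1, 2, 3]), np.array([50.0, 100, 20]),
                        n_samples=170)
        assert np.allclose(boltzmann_invert(a, 300), boltzmann_invert(b, 300))

    def test_boltzmann_roundtrip(self):
        counts = np.array([3.0, 9, 1, 7])
        hist = Histogram1D(np.arange(5.0), counts, n_samples=20)
        F = boltzmann_invert(hist, 300.0)
        p = np.exp(-F / (KB * 300))
        p /= p.sum()
        assert np.allclose(p, counts / counts.sum(), atol=1e-9)

    def test_empty_histogram_raises(self):
        hist = Histogram1D(np.arange(5.0), np.zeros(4), n_samples=0)
        with pytest.raises(ValueError, match="empty"):
            boltzmann_invert(hist, 300.0)

    def test_masked_empty_bins(self):
        hist = Histogram1D(np.arange(4.0), np.array([5.0, 0.0, 5.0]),
                           n_samples=10)
        F = boltzmann_invert(hist, 300.0)
        assert np.isnan(F[1]) and np.isfinite(F[0])


class TestRamachandran:
    def _traj(self, frames):
        return Trajectory(np.asarray(frames), Box.open(),
                          np.arange(float(len(frames))), species=["C"] * 5)

    def test_mirrored_input_is_point_symmetric(self, rng):
        frames = rng.normal(scale=0.4, size=(200, 5, 3))
        both = np.concatenate([frames, frames * [1, 1, -1]])
        _, _, score = ramachandran_fes(self._traj(both), [(0, 1, 2, 3)],
                                       [(1, 2, 3, 4)], bins=12)
        assert score > 0.999

    def test_single_frame_single_bin(self, rng):
        frame = rng.normal(scale=0.4, size=(1, 5, 3))
        hist, fes, _ = ramachandran_fes(self._traj(frame), [(0, 1, 2, 3)],
                                        [(1, 2, 3, 4)], bins=12)
        assert (hist.counts > 0).sum() == 1
        assert np.nanmin(fes) == 0.0

    def test_one_sided_basin_not_symmetric(self, rng):
        """Samples concentrated in one quadrant score low."""
        phis = rng.normal(60, 8, size=400)
        psis = rng.normal(-45, 8, size=400)
        edges = np.linspace(-180, 180, 13)
        counts, _, _ = np.histogram2d(phis, psis, bins=[edges, edges])
        density = counts / counts.sum()
        assert point_symmetry_score(density) < 0.5


class TestHelixOrderParameters:
    def test_perfect_helix_scores_one(self):
        pos = ideal_helix(15, d0=0.5)
        assert q_hel(pos) == pytest.approx(1.0, abs=1e-12)

    def test_unstructured_scores_zero(self):
        pos = np.zeros((10, 3))
        pos[:, 0] = np.arange(10) * 5.0  # fully extended, d >> d0
        assert q_hel(pos) < 1e-8

    def test_single_pair_one_sigma(self):
        """Four sites with the single (i, i+3) distance at d0 + sqrt(2 s2):
        score exp(-1/2) = 0.6065."""
        d = 0.5 + np.sqrt(0.02)  # one sigma: (d-d0)^2/(2 s2) = 1/2
        pos = np.array([[0.0, 0, 0], [0.1, 0.2, 0], [0.3, 0.1, 0.1],
                        [d, 0, 0]])
        assert q_hel(pos) == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_coplanar_zigzag_chi_zero(self):
        pos = np.zeros((8, 3))
        pos[:, 0] = np.arange(8) * 0.3
        pos[::2, 1] = 0.1
        assert chi_hel(pos) == pytest.approx(0.0, abs=1e-15)

    def test_ideal_right_handed_helix_positive(self):
        assert chi_hel(ideal_helix(15)) > 0

    def test_mirror_negates_chi(self):
        pos = ideal_helix(12)
        assert chi_hel(mirror(pos)) == pytest.approx(-chi_hel(pos),
                                                     abs=1e-15)

    def test_too_few_sites_raise(self):
        with pytest.raises(ValueError):
            q_hel(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            chi_hel(np.zeros((3, 3)))


class TestHelixFES:
    def test_mirrored_trajectory_balanced_fractions(self, rng):
        base = ideal_helix(10) + rng.normal(scale=0.02, size=(60, 10, 3))
        both = np.concatenate([base, base * [1, 1, -1]])
        traj = Trajectory(both, Box.open(), np.arange(120.0),
                          species=["CA"] * 10)
        _, _, fr = helix_fes(traj)
        assert fr["left"] == pytest.approx(fr["right"], abs=1e-12)
        assert fr["left"] + fr["right"] == pytest.approx(1.0)

    def test_ideal_frames_single_right_handed_basin(self, rng):
        base = ideal_helix(10) + rng.normal(scale=0.005, size=(40, 10, 3))
        traj = Trajectory(base, Box.open(), np.arange(40.0),
                          species=["CA"] * 10)
        hist, fes, fr = helix_fes(traj)
        assert fr["right"] == 1.0
        Q, X = helix_series(traj)
        assert Q.min() > 0.9 and X.min() > 0


class TestFrameRanking:
    def test_single_selection(self):
        idx = rank_frames_for_refolding(np.array([1.0, 1.0, 1.0]),
                                        np.array([3.0, 0.1, 2.0]), 1)
        assert idx.tolist() == [1]

    def test_tie_break_by_frame_index(self):
        idx = rank_frames_for_refolding(np.ones(5), np.ones(5), 3)
        assert idx.tolist() == [0, 1, 2]

    def test_matches_full_sort(self, rng):
        q = rng.uniform(size=50)
        x = rng.normal(size=50)
        idx = rank_frames_for_refolding(q, x, 10)
        ref = np.argsort(np.abs(q * x), kind="stable")[:10]
        assert np.array_equal(idx, ref)

    def test_overlong_selection_warns_and_returns_all(self):
        with pytest.warns(UserWarning):
            idx = rank_frames_for_refolding(np.ones(3), np.ones(3), 10)
        assert len(idx) == 3


class TestBondSwaps:
    def _dimer_system(self):
        top = linear_chain_topology(2, 2, mass=1.0)
        return top

    def test_static_fixture_no_swaps(self):
        top = self._dimer_system()
        pos = np.array([[0.0, 0, 0], [0.3, 0, 0],
                        [2.0, 0, 0], [2.3, 0, 0]])
        traj = Trajectory(np.repeat(pos[None], 5, axis=0), Box.open(),
                          np.arange(5.0), species=["C"] * 4)
        rep = bond_swap_analysis(traj, top)
        assert rep.swap_counts.sum() == 0
        assert rep.identity_fraction == 1.0
        assert np.array_equal(rep.bonded_hist.counts, rep.nearest_hist.counts)

    def test_constructed_partner_exchange(self):
        """Two dimers swap partners at midrun: swaps are detected from the
        exchange frame; the initial-bond-list histogram is bimodal while
        the nearest-neighbor histogram is unimodal."""
        top = self._dimer_system()
        frames = []
        for f in range(20):
            if f < 10:
                frames.append([[0.0, 0, 0], [0.30, 0, 0],
                               [0.0, 0.8, 0], [0.30, 0.8, 0]])
            else:  # partners exchanged: 0-3 and 2-1 now closest
                frames.append([[0.0, 0, 0], [0.30, 0.8, 0],
                               [0.0, 0.8, 0], [0.30, 0.0, 0]])
        traj = Trajectory(np.array(frames, dtype=float), Box.open(),
                          np.arange(20.0), species=["C"] * 4)
        rep = bond_swap_analysis(traj, top)
        assert rep.first_swap_frame == 10
        assert np.all(rep.swap_counts[:10] == 0)
        assert np.all(rep.swap_counts[10:] > 0)
        assert count_modes(rep.bonded_hist) == 2
        assert count_modes(rep.nearest_hist) == 1

    def test_swap_count_rotation_invariant(self, rng):
        top = self._dimer_system()
        frames = rng.normal(scale=0.5, size=(8, 4, 3))
        traj = Trajectory(frames, Box.open(), np.arange(8.0),
                          species=["C"] * 4)
        R = Rotation.random(random_state=11).as_matrix()
        rot = Trajectory(frames @ R.T, Box.open(), np.arange(8.0),
                         species=["C"] * 4)
        a = bond_swap_analysis(traj, top)
        b = bond_swap_analysis(rot, top)
        assert np.array_equal(a.swap_counts, b.swap_counts)
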