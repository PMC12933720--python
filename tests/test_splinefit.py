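"""Spline CG potential and linear force matching."""

import numpy as np
import pytest

from cgbench.box import Box
from cgbench.mapping import CGTrajectory, chain_mapping, map_trajectory
from cgbench.splinefit import (FMProblem, UniformBSpline,
                               assemble_design_matrix, build_spline_terms,
                               chi_squared, eval_spline_potential,
                               load_termset, save_termset,
                               solve_force_matching, split_frames)
from cgbench.systems import build_chain_liquid, generate_reference
from cgbench.topology import Topology


@pytest.fixture(scope="module")
def cg_liquid():
    sys = build_chain_liquid(27, 6, molecule_density=1.0, seed=1)
    traj = generate_reference(sys, n_steps=400, stride=20, seed=2)
    scheme = chain_mapping(sys.topology, [3, 3], "single")
    return map_trajectory(traj, scheme, sys.topology)


def small_termset(cg):
    return build_spline_terms(cg, bond_spacing=0.01, pair_spacing=0.05,
                              r_cut=1.0)


class TestBasis:
    def test_partition_of_unity(self):
        basis = UniformBSpline(0.0, 1.0, 0.1)
        x = np.linspace(0.0, 1.0, 57)
        B, _ = basis.design(x)
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_periodic_wraps(self):
        basis = UniformBSpline(-np.pi, np.pi, 0.5, mode="periodic")
        B1, _ = basis.design(np.array([np.pi - 0.01]))
        B2, _ = basis.design(np.array([-np.pi - 0.01]))
        assert np.allclose(B1, B2, atol=1e-12)

    def test_cutoff_mode_vanishes_at_and_beyond_cutoff(self):
        basis = UniformBSpline(0.2, 1.0, 0.1, mode="cutoff")
        B, dB = basis.design(np.array([1.0, 1.2, 5.0]))
        assert np.allclose(B, 0.0) and np.allclose(dB, 0.0)

    def test_out_of_domain_error_mode(self):
        basis = UniformBSpline(0.2, 1.0, 0.1, out_of_domain="error")
        with pytest.raises(ValueError, match="outside"):
            basis.design(np.array([0.1]))

    def test_derivative_matches_finite_difference(self):
        basis = UniformBSpline(0.0, 1.0, 0.07)
        x = np.linspace(0.05, 0.95, 31)
        B, dB = basis.design(x)
        Bp, _ = basis.design(x + 1e-6)
        Bm, _ = basis.design(x - 1e-6)
        assert np.allclose((Bp - Bm) / 2e-6, dB, atol=1e-5)


class TestEvaluation:
    def test_zero_coefficients_zero_everything(self, cg_liquid):
        ts = small_termset(cg_liquid)
        e, f = eval_spline_potential(cg_liquid.positions[0], cg_liquid.box,
                                     ts, cg_liquid.topology)
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_harmonic_bond_representable_on_grid(self):
        """Spline fitted to 1/2 k (r - r0)^2 reproduces the analytic force
        within a small fraction of the maximum force on the grid."""
        basis = UniformBSpline(0.2, 0.4, 0.005)
        r = np.linspace(0.2, 0.4, 400)
        B, dB = basis.design(r)
        k, r0 = 1000.0, 0.3
        coeffs, *_ = np.linalg.lstsq(B, 0.5 * k * (r - r0) ** 2, rcond=None)
        force = -(dB @ coeffs)
        ref = -k * (r - r0)
        inner = (r > 0.21) & (r < 0.39)
        rmse = np.sqrt(np.mean((force[inner] - ref[inner]) ** 2))
        assert rmse < 0.005 * np.abs(ref).max()

    def test_forces_match_finite_difference(self, cg_liquid, rng):
        ts = small_termset(cg_liquid)
        ts.set_coeffs(rng.normal(size=ts.n_coef))
        pos = cg_liquid.positions[3].copy()
        e0, f = eval_spline_potential(pos, cg_liquid.box, ts,
                                      cg_liquid.topology)
        eps = 1e-6
        for a in (0, 7, 21):
            for c in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[a, c] += eps
                pm[a, c] -= eps
                ep = eval_spline_potential(pp, cg_liquid.box, ts,
                                           cg_liquid.topology)[0]
                em = eval_spline_potential(pm, cg_liquid.box, ts,
                                           cg_liquid.topology)[0]
                fd = -(ep - em) / (2 * eps)
                assert abs(fd - f[a, c]) / max(abs(f[a, c]), 1.0) < 1e-5


class TestDesignMatrix:
    def test_shape_contract(self, cg_liquid):
        ts = small_termset(cg_liquid)
        D, y = assemble_design_matrix(cg_liquid, ts)
        assert D.shape == (3 * cg_liquid.n_atoms * cg_liquid.n_frames,
                           ts.n_coef)
        assert y.shape == (D.shape[0],)

    def test_design_times_coeffs_equals_forces(self, cg_liquid, rng):
        ts = small_termset(cg_liquid)
        theta = rng.normal(size=ts.n_coef)
        ts.set_coeffs(theta)
        D, _ = assemble_design_matrix(cg_liquid, ts)
        for f in (0, cg_liquid.n_frames - 1):
            _, forces = eval_spline_potential(cg_liquid.positions[f],
                                              cg_liquid.box, ts,
                                              cg_liquid.topology)
            rows = slice(3 * cg_liquid.n_atoms * f,
                         3 * cg_liquid.n_atoms * (f + 1))
            assert np.allclose(D[rows] @ theta, forces.reshape(-1),
                               atol=1e-9)

    def test_duplicate_frame_duplicates_rows(self, cg_liquid):
        ts = small_termset(cg_liquid)
        one = cg_liquid.slice([0])
        two = CGTrajectory(
            np.repeat(one.positions, 2, axis=0), cg_liquid.box,
            np.array([0.0, 1.0]), forces=np.repeat(one.forces, 2, axis=0),
            species=cg_liquid.species, topology=cg_liquid.topology)
        D, _ = assemble_design_matrix(two, ts)
        half = D.shape[0] // 2
        assert np.array_equal(D[:half], D[half:])

    def test_empty_trajectory_raises(self, cg_liquid):
        ts = small_termset(cg_liquid)
        empty = cg_liquid.slice(slice(0, 0))
        with pytest.raises(ValueError, match="empty"):
            assemble_design_matrix(
                CGTrajectory(empty.positions, cg_liquid.box, empty.times,
                             forces=empty.forces, species=cg_liquid.species,
                             topology=cg_liquid.topology), ts)


class TestForceMatching:
    def _with_targets(self, cg, theta_seed=0):
        ts = small_termset(cg)
        rng = np.random.default_rng(theta_seed)
        theta = rng.normal(size=ts.n_coef)
        ts.set_coeffs(theta)
        D, _ = assemble_design_matrix(cg, ts)
        targets = (D @ theta).reshape(cg.n_frames, cg.n_atoms, 3)
        return CGTrajectory(cg.positions, cg.box, cg.times, forces=targets,
                            species=cg.species, masses=cg.masses,
                            topology=cg.topology)

    def test_exact_recovery(self, cg_liquid):
        cg = self._with_targets(cg_liquid)
        ts = small_termset(cg)
        _, chi_tr, chi_val = solve_force_matching(
            FMProblem(cg, ts, ridge=1e-9, val_fraction=0.2, seed=0))
        assert chi_tr < 1e-10
        assert chi_val < 1e-10

    def test_chi2_matches_direct_summation(self, cg_liquid):
        """Solver-reported chi^2 equals an independent recomputation from
        the fitted potential's forces."""
        ts = small_termset(cg_liquid)
        ts_fit, chi_tr, _ = solve_force_matching(
            FMProblem(cg_liquid, ts, ridge=1e-6, val_fraction=0.0, seed=0))
        preds = []
        for f in range(cg_liquid.n_frames):
            _, F = eval_spline_potential(cg_liquid.positions[f],
                                         cg_liquid.box, ts_fit,
                                         cg_liquid.topology)
            preds.append(F)
        direct = chi_squared(np.array(preds), cg_liquid.forces)
        assert chi_tr == pytest.approx(direct, rel=1e-9)

    def test_frame_order_invariance(self, cg_liquid):
        ts1 = small_termset(cg_liquid)
        solve_force_matching(FMProblem(cg_liquid, ts1, ridge=1e-6,
                                       val_fraction=0.0))
        perm = np.random.default_rng(5).permutation(cg_liquid.n_frames)
        shuffled = CGTrajectory(cg_liquid.positions[perm], cg_liquid.box,
                                cg_liquid.times, forces=cg_liquid.forces[perm],
                                species=cg_liquid.species,
                                topology=cg_liquid.topology)
        ts2 = small_termset(cg_liquid)
        _, chi2_shuffled, _ = solve_force_matching(
            FMProblem(shuffled, ts2, ridge=1e-6, val_fraction=0.0))
        _, chi2_orig, _ = solve_force_matching(
            FMProblem(cg_liquid, small_termset(cg_liquid), ridge=1e-6,
                      val_fraction=0.0))
        assert chi2_shuffled == pytest.approx(chi2_orig, rel=1e-9)
        for t1, t2 in zip(ts1.terms, ts2.terms):
            _, _, f1 = ts1.tabulate(t1)
            _, _, f2 = ts2.tabulate(t2)
            scale = max(np.abs(f1).max(), 1.0)
            assert np.abs(f1 - f2).max() / scale < 1e-3

    def test_nested_grids_never_increase_train_chi2(self, cg_liquid):
        """Dyadic refinement of uniform B-spline grids nests the function
        spaces, so the training residual cannot increase."""
        chis = []
        for refine in (1, 2, 4):
            ts = build_spline_terms(cg_liquid, bond_spacing=0.04,
                                    pair_spacing=0.1, r_cut=1.0,
                                    dihedral_spacing_deg=30.0, pad=0.002,
                                    refine=refine)
            _, chi_tr, _ = solve_force_matching(
                FMProblem(cg_liquid, ts, ridge=0.0, val_fraction=0.0))
            chis.append(chi_tr)
        assert chis[1] <= chis[0] * (1 + 1e-9)
        assert chis[2] <= chis[1] * (1 + 1e-9)

    def test_rank_deficient_without_ridge_raises(self, cg_liquid):
        ts = build_spline_terms(cg_liquid, bond_spacing=0.0005,
                                pair_spacing=0.002, r_cut=1.0)
        with pytest.raises(np.linalg.LinAlgError, match="regularization"):
            solve_force_matching(FMProblem(cg_liquid, ts, ridge=0.0,
                                           val_fraction=0.0))

    def test_split_is_contiguous_and_disjoint(self):
        train, val = split_frames(100, 0.2, seed=3)
        assert len(val) == 20
        assert np.array_equal(val, np.arange(val[0], val[0] + 20))
        assert len(np.intersect1d(train, val)) == 0

    def test_serialization_roundtrip(self, cg_liquid, tmp_path, rng):
        ts = small_termset(cg_liquid)
        ts.set_coeffs(rng.normal(size=ts.n_coef))
        path = tmp_path / "model.npz"
        save_termset(path, ts)
        back = load_termset(path)
        e1, f1 = eval_spline_potential(cg_liquid.positions[0], cg_liquid.box,
                                       ts, cg_liquid.topology)
        e2, f2 = eval_spline_potential(cg_liquid.positions[0], cg_liquid.box,
                                       back, cg_liquid.topology)
        assert e1 == pytest.approx(e2, abs=1e-10)
        assert np.allclose(f1, f2, atol=1e-10)
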