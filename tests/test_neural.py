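"""Invariant descriptors and the learnable CG potential."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgbench.box import Box
from cgbench.invariants import DescriptorConfig, descriptor_features
from cgbench.mapping import CGTrajectory
from cgbench.neuralcg import NeuralCGPotential, chi_squared_direct

MIRROR = np.array([1.0, 1.0, -1.0])


def chiral_cluster(rng=None):
    """Four beads with no symmetry: a genuinely chiral arrangement."""
    return np.array([[0.0, 0.0, 0.0], [0.25, 0.05, -0.02],
                     [0.10, 0.45, 0.05], [0.20, 0.10, 0.60]])


@pytest.fixture
def full_config():
    return DescriptorConfig(species=["A", "B"], r_cut=1.0, n_radial=4,
                            n_angular=2, angular=True, parity_odd=True,
                            hidden=(8, 8))


class TestDescriptors:
    def test_isolated_bead_zero_features(self, full_config):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        X = descriptor_features(pos, None, ["A", "B"], full_config)
        assert np.all(X == 0.0)

    def test_rotation_invariance(self, full_config, rng):
        pos = rng.normal(scale=0.3, size=(6, 3))
        species = ["A", "B"] * 3
        X = descriptor_features(pos, None, species, full_config)
        R = Rotation.random(random_state=2).as_matrix()
        Xr = descriptor_features(pos @ R.T, None, species, full_config)
        assert np.allclose(X, Xr, atol=1e-12)

    def test_mirror_flips_only_parity_feature(self, full_config, rng):
        pos = rng.normal(scale=0.3, size=(5, 3))
        species = ["A", "B", "A", "B", "A"]
        X = descriptor_features(pos, None, species, full_config)
        Xm = descriptor_features(pos * MIRROR, None, species, full_config)
        assert np.array_equal(X[:, :-1], Xm[:, :-1])
        assert np.array_equal(X[:, -1], -Xm[:, -1])
        assert np.abs(X[:, -1]).max() > 0

    def test_parity_feature_nonzero_on_chiral_cluster(self):
        cfg = DescriptorConfig(species=["A"], r_cut=1.0, n_radial=3,
                               parity_odd=True)
        X = descriptor_features(chiral_cluster(), None, ["A"] * 4, cfg)
        assert np.abs(X[:, -1]).max() > 1e-4

    def test_jacobian_matches_finite_difference(self, full_config, rng):
        pos = rng.normal(scale=0.3, size=(5, 3))
        species = ["A", "B", "A", "B", "A"]
        X, J = descriptor_features(pos, None, species, full_config,
                                   jacobian=True)
        eps = 1e-6
        for j in range(5):
            for c in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[j, c] += eps
                pm[j, c] -= eps
                fd = (descriptor_features(pp, None, species, full_config) -
                      descriptor_features(pm, None, species, full_config)) \
                    / (2 * eps)
                assert np.abs(fd - J[:, :, j, c]).max() < 1e-7

    def test_smooth_at_cutoff(self, full_config):
        """Features stay continuous as a neighbor crosses r_cut."""
        base = np.array([[0.0, 0, 0], [0.5, 0, 0], [0.0, 0.4, 0.0]])
        species = ["A", "B", "A"]
        inside = base.copy()
        inside[1, 0] = 0.999
        outside = base.copy()
        outside[1, 0] = 1.001
        Xi = descriptor_features(inside, None, species, full_config)
        Xo = descriptor_features(outside, None, species, full_config)
        assert np.abs(Xi - Xo).max() < 1e-4

    def test_nu_tilde_controls_body_order(self):
        for nu, ang, par in ((1, False, False), (2, True, False),
                             (3, True, True)):
            cfg = DescriptorConfig(species=["A"], nu_tilde=nu)
            assert cfg.angular is ang and cfg.parity_odd is par

    def test_unknown_species_raises(self, full_config):
        with pytest.raises(ValueError, match="not in embedding table"):
            descriptor_features(np.zeros((1, 3)), None, ["Z"], full_config)


class TestNeuralPotential:
    def test_forces_match_finite_difference(self, full_config, rng):
        model = NeuralCGPotential(full_config, seed=0)
        pos = rng.normal(scale=0.3, size=(5, 3))
        species = ["A", "B", "A", "B", "A"]
        _, F = model.energy_forces(pos, None, species)
        eps = 1e-6
        for a in range(5):
            for c in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[a, c] += eps
                pm[a, c] -= eps
                fd = -(model.energy(pp, None, species) -
                       model.energy(pm, None, species)) / (2 * eps)
                assert abs(fd - F[a, c]) / max(abs(F[a, c]), 1e-3) < 1e-5

    def test_mirror_blind_without_parity_feature(self, rng):
        """With parity-odd features off, E(mirror(R)) == E(R) exactly: a
        scalar-energy invariant model cannot distinguish enantiomers."""
        cfg = DescriptorConfig(species=["A"], r_cut=1.0, n_radial=4,
                               angular=True, parity_odd=False, hidden=(8,))
        model = NeuralCGPotential(cfg, seed=1)
        pos = chiral_cluster()
        assert model.energy(pos, None, ["A"] * 4) == \
            model.energy(pos * MIRROR, None, ["A"] * 4)

    def test_mirror_detected_with_parity_feature(self):
        cfg = DescriptorConfig(species=["A"], r_cut=1.0, n_radial=4,
                               angular=True, parity_odd=True, hidden=(8,))
        model = NeuralCGPotential(cfg, seed=1)
        pos = chiral_cluster()
        e = model.energy(pos, None, ["A"] * 4)
        em = model.energy(pos * MIRROR, None, ["A"] * 4)
        assert abs(e - em) > 1e-6

    def test_permutation_of_identical_beads(self, rng):
        """Swapping two beads of the same species leaves the energy
        unchanged (features are per-bead sums)."""
        cfg = DescriptorConfig(species=["A"], r_cut=1.5, n_radial=4,
                               angular=True, hidden=(8,))
        model = NeuralCGPotential(cfg, seed=2)
        pos = rng.normal(scale=0.3, size=(5, 3))
        perm = pos[[1, 0, 2, 3, 4]]
        assert model.energy(pos, None, ["A"] * 5) == pytest.approx(
            model.energy(perm, None, ["A"] * 5), abs=1e-12)

    def test_rotation_translation_invariance(self, full_config, rng):
        model = NeuralCGPotential(full_config, seed=3)
        pos = rng.normal(scale=0.3, size=(6, 3))
        species = ["A", "B"] * 3
        e = model.energy(pos, None, species)
        R = Rotation.random(random_state=5).as_matrix()
        assert model.energy(pos @ R.T + rng.normal(size=3), None,
                            species) == pytest.approx(e, abs=1e-10)

    def test_serialization_roundtrip(self, full_config, tmp_path, rng):
        model = NeuralCGPotential(full_config, seed=4)
        pos = rng.normal(scale=0.3, size=(4, 3))
        species = ["A", "B", "A", "B"]
        path = tmp_path / "model.npz"
        model.save(path)
        back = NeuralCGPotential.load(path)
        e1, f1 = model.energy_forces(pos, None, species)
        e2, f2 = back.energy_forces(pos, None, species)
        assert e1 == e2
        assert np.array_equal(f1, f2)


def _dimer_dataset(n_frames, rng, k=100.0, r0=0.4):
    frames, forces = [], []
    for _ in range(n_frames):
        r = rng.uniform(0.25, 0.7)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        frames.append(np.stack([np.zeros(3), r * d]))
        fmag = -k * (r - r0)
        forces.append(np.stack([-fmag * d, fmag * d]))
    return CGTrajectory(np.array(frames), Box.open(),
                        np.arange(float(n_frames)), forces=np.array(forces),
                        species=["A", "A"])


class TestTraining:
    def test_recovers_known_pair_force(self, rng):
        """Two-bead harmonic reference: learned pair force within 5% RMSE
        of the analytic curve over the sampled range."""
        traj = _dimer_dataset(120, rng)
        cfg = DescriptorConfig(species=["A"], r_cut=1.0, n_radial=6,
                               angular=False, hidden=(16,))
        model = NeuralCGPotential(cfg, seed=3)
        model.train(traj, lr=5e-3, n_epochs=400, seed=1)
        rs = np.linspace(0.3, 0.65, 25)
        err = []
        ref = []
        for r in rs:
            pos = np.stack([np.zeros(3), [r, 0, 0]])
            _, F = model.energy_forces(pos, None, ["A", "A"])
            ref_f = -100.0 * (r - 0.4)
            err.append(F[1, 0] - ref_f)
            ref.append(ref_f)
        rmse = np.sqrt(np.mean(np.square(err)))
        assert rmse < 0.05 * np.abs(ref).max()

    def test_self_consistent_targets_keep_zero_residual(self, rng):
        """Targets produced by the model's own random initialization are
        exactly realizable; training (with early stopping) keeps the
        residual at numerical zero."""
        cfg = DescriptorConfig(species=["A"], r_cut=1.0, n_radial=4,
                               angular=True, hidden=(8,))
        model = NeuralCGPotential(cfg, seed=7)
        frames = rng.normal(scale=0.25, size=(20, 4, 3))
        forces = np.array([model.energy_forces(f, None, ["A"] * 4)[1]
                           for f in frames])
        traj = CGTrajectory(frames, Box.open(), np.arange(20.0),
                            forces=forces, species=["A"] * 4)
        out = model.train(traj, lr=1e-3, n_epochs=50, val_fraction=0.0,
                          seed=0)
        assert out["chi2_train"] < 1e-6

    def test_perturbed_teacher_recovered(self, rng):
        """A student started near a teacher recovers the teacher's forces:
        the residual drops by orders of magnitude from its start."""
        cfg = DescriptorConfig(species=["A"], r_cut=1.0, n_radial=4,
                               angular=True, hidden=(8,))
        teacher = NeuralCGPotential(cfg, seed=7)
        frames = rng.normal(scale=0.25, size=(30, 4, 3))
        forces = np.array([teacher.energy_forces(f, None, ["A"] * 4)[1]
                           for f in frames])
        traj = CGTrajectory(frames, Box.open(), np.arange(30.0),
                            forces=forces, species=["A"] * 4)
        student = NeuralCGPotential(cfg, seed=7)
        pert = np.random.default_rng(0)
        for W in student.Ws:
            W += pert.normal(scale=0.05, size=W.shape)
        chi0 = chi_squared_direct(student, traj)
        out = student.train(traj, lr=5e-3, n_epochs=400, val_fraction=0.0,
                            seed=0, lr_decay=0.995)
        assert out["chi2_train"] < 1e-2 * chi0

    def test_fixed_seed_identical_parameters(self, rng):
        traj = _dimer_dataset(40, rng)
        cfg = DescriptorConfig(species=["A"], r_cut=1.0, n_radial=4,
                               angular=False, hidden=(8,))
        runs = []
        for _ in range(2):
            m = NeuralCGPotential(cfg, seed=5)
            m.train(traj, lr=3e-3, n_epochs=50, seed=5)
            runs.append([W.copy() for W in m.Ws])
        for W1, W2 in zip(*runs):
            assert np.array_equal(W1, W2)

    def test_reported_chi2_matches_direct_oracle(self, rng):
        """Trainer-internal chi^2 equals an independent direct-summation
        recomputation through energy_forces."""
        traj = _dimer_dataset(30, rng)
        cfg = DescriptorConfig(species=["A"], r_cut=1.0, n_radial=4,
                               angular=False, hidden=(8,))
        model = NeuralCGPotential(cfg, seed=6)
        out = model.train(traj, lr=3e-3, n_epochs=40, val_fraction=0.0,
                          seed=2, patience=10_000)
        # after restoring the best epoch, recompute on the training set
        direct = chi_squared_direct(model, traj)
        assert direct == pytest.approx(out["chi2_train"], rel=1e-9)

    def test_validation_chi2_positive_on_noisy_targets(self, rng):
        """Mapped-force targets carry irreducible noise: the validation
        residual stays bounded away from zero."""
        traj = _dimer_dataset(60, rng)
        noisy = CGTrajectory(traj.positions, traj.box, traj.times,
                             forces=traj.forces +
                             rng.normal(scale=2.0, size=traj.forces.shape),
                             species=traj.species)
        cfg = DescriptorConfig(species=["A"], r_cut=1.0, n_radial=4,
                               angular=False, hidden=(8,))
        model = NeuralCGPotential(cfg, seed=8)
        out = model.train(noisy, lr=3e-3, n_epochs=60, seed=3)
        assert out["chi2_val"] > 0.5
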