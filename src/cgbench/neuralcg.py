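"""Minimal learnable CG potential: invariant descriptors, species one-hot
embedding, and a small feed-forward readout per bead.

The total energy is a sum of per-bead scalar energies
E(R) = sum_I g(x_I(R) ++ onehot(s_I); theta), with forces obtained as the
exact negative gradient through the descriptor Jacobians. Training
minimizes the force-matching residual chi^2 by full-batch Adam; the
gradient of chi^2 with respect to theta runs through the forces, i.e.
through mixed second derivatives of g, implemented as a manual
forward-over-reverse pass (tangent = the per-bead chain-rule vector).

Because every feature is rotation/translation invariant, the energy is
too; with the parity-odd feature disabled the energy is exactly equal for
a configuration and its mirror image — a scalar-energy model is then
blind to chirality by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .box import Box
from .invariants import DescriptorConfig, descriptor_features
from .mapping import CGTrajectory
from .splinefit import split_frames


class TrainingDivergedError(RuntimeError):
    pass


def _init_params(config: DescriptorConfig, rng: np.random.Generator):
    dims = [config.n_features + config.n_species, *config.hidden, 1]
    Ws, bs = [], []
    for din, dout in zip(dims[:-1], dims[1:]):
        Ws.append(rng.normal(scale=1.0 / np.sqrt(din), size=(dout, din)))
        bs.append(np.zeros(dout))
    return Ws, bs


class NeuralCGPotential:
    """Descriptor + MLP potential with analytic forces and trainer."""

    def __init__(self, config: DescriptorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.Ws, self.bs = _init_params(config, rng)

    # ---------------- forward passes ----------------

    def _mlp(self, X: np.ndarray):
        """Batched forward; returns per-row energy, input gradient, and the
        caches needed for double backprop."""
        H = [X]
        for W, b in zip(self.Ws[:-1], self.bs[:-1]):
            H.append(np.tanh(H[-1] @ W.T + b))
        e = (H[-1] @ self.Ws[-1].T + self.bs[-1]).ravel()
        # reverse pass for d e / d x
        G = np.broadcast_to(self.Ws[-1], (X.shape[0], self.Ws[-1].shape[1]))
        for l in range(len(self.Ws) - 2, -1, -1):
            G = (G * (1.0 - H[l + 1] ** 2)) @ self.Ws[l]
        return e, G, H

    def _inputs(self, features: np.ndarray, species_idx: np.ndarray):
        onehot = np.eye(self.config.n_species)[species_idx]
        return np.concatenate([features, onehot], axis=1)

    def energy_forces(self, positions: np.ndarray, box: Box | None,
                      species: list):
        """Total energy (kJ/mol) and forces (kJ/mol/nm) at a configuration."""
        X, J = descriptor_features(positions, box, species, self.config,
                                   jacobian=True)
        sidx = self.config.species_index(species)
        e, G, _ = self._mlp(self._inputs(X, sidx))
        U = G[:, :self.config.n_features]        # d e_I / d x_I
        forces = -np.einsum("if,ifjc->jc", U, J)
        return float(e.sum()), forces

    def energy(self, positions, box, species) -> float:
        X = descriptor_features(positions, box, species, self.config)
        sidx = self.config.species_index(species)
        e, _, _ = self._mlp(self._inputs(X, sidx))
        return float(e.sum())

    # ---------------- double backprop ----------------

    def _grad_directional(self, Xin: np.ndarray, A: np.ndarray):
        """Parameter gradients of S = sum_rows a_row . (d e/d x)_row.

        Forward-mode tangent (xdot = a) through the network, then reverse
        accumulation over the joint (value, tangent) graph.
        """
        H = [Xin]
        for W, b in zip(self.Ws[:-1], self.bs[:-1]):
            H.append(np.tanh(H[-1] @ W.T + b))
        Hd = [A]
        Zd = [None]
        for l, W in enumerate(self.Ws[:-1]):
            zd = Hd[-1] @ W.T
            Zd.append(zd)
            Hd.append((1.0 - H[l + 1] ** 2) * zd)
        gW = [np.zeros_like(W) for W in self.Ws]
        gb = [np.zeros_like(b) for b in self.bs]
        # output layer: S = sum rows (Hd[-1] @ Wout.T)
        gW[-1] += Hd[-1].sum(axis=0, keepdims=True)
        Adh = np.broadcast_to(self.Ws[-1],
                              (Xin.shape[0], self.Ws[-1].shape[1])).copy()
        Ah = np.zeros_like(Adh)
        for l in range(len(self.Ws) - 2, -1, -1):
            hp = 1.0 - H[l + 1] ** 2
            Az_dot = Adh * hp
            Ah = Ah + Adh * (-2.0 * H[l + 1] * Zd[l + 1])
            Az = Ah * hp
            gW[l] += Az_dot.T @ Hd[l] + Az.T @ H[l]
            gb[l] += Az.sum(axis=0)
            Adh = Az_dot @ self.Ws[l]
            Ah = Az @ self.Ws[l]
        return gW, gb

    # ---------------- training ----------------

    def train(self, cg_traj: CGTrajectory, lr: float = 3e-3,
              n_epochs: int = 400, val_fraction: float = 0.2,
              patience: int = 50, seed: int = 0, lr_decay: float = 1.0,
              verbose: bool = False):
        """Full-batch Adam on the force-matching residual.

        ``lr_decay`` is a per-epoch multiplicative factor (1.0 keeps the
        rate constant; ~0.995 anneals for deep convergence). Returns a
        dict with chi^2 curves and the best (early-stopped) epoch;
        identical seeds give identical final parameters.
        """
        species = cg_traj.species
        sidx = self.config.species_index(species)
        Xs, Js = [], []
        for f in range(cg_traj.n_frames):
            X, J = descriptor_features(cg_traj.positions[f], cg_traj.box,
                                       species, self.config, jacobian=True)
            Xs.append(X)
            Js.append(J)
        train_idx, val_idx = split_frames(cg_traj.n_frames, val_fraction, seed)
        n = cg_traj.n_atoms
        scale = 2.0 / (3.0 * n * len(train_idx))

        mW = [np.zeros_like(W) for W in self.Ws]
        vW = [np.zeros_like(W) for W in self.Ws]
        mb = [np.zeros_like(b) for b in self.bs]
        vb = [np.zeros_like(b) for b in self.bs]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        history = {"train": [], "val": []}
        best = (np.inf, None, -1)
        for epoch in range(n_epochs):
            gW = [np.zeros_like(W) for W in self.Ws]
            gb = [np.zeros_like(b) for b in self.bs]
            chi_tr = 0.0
            for f in train_idx:
                X, J, Fref = Xs[f], Js[f], cg_traj.forces[f]
                Xin = self._inputs(X, sidx)
                _, G, _ = self._mlp(Xin)
                U = G[:, :self.config.n_features]
                Fpred = -np.einsum("if,ifjc->jc", U, J)
                rho = Fpred - Fref
                chi_tr += np.sum(rho ** 2) / (3.0 * n)
                a_feat = -scale * np.einsum("ifjc,jc->if", J, rho)
                A = np.concatenate(
                    [a_feat, np.zeros((len(X), self.config.n_species))], axis=1)
                dW, db = self._grad_directional(Xin, A)
                for l in range(len(gW)):
                    gW[l] += dW[l]
                    gb[l] += db[l]
            chi_tr /= len(train_idx)
            if not np.isfinite(chi_tr):
                raise TrainingDivergedError(
                    f"chi^2 diverged at epoch {epoch}")
            chi_val = (self._chi_frames(Xs, Js, cg_traj.forces, val_idx, sidx,
                                        n) if len(val_idx) else chi_tr)
            history["train"].append(chi_tr)
            history["val"].append(chi_val)
            if chi_val < best[0]:
                best = (chi_val, ([W.copy() for W in self.Ws],
                                  [b.copy() for b in self.bs]), epoch)
            elif epoch - best[2] > patience:
                break
            t = epoch + 1
            lr_t = lr * lr_decay ** epoch
            for l in range(len(self.Ws)):
                mW[l] = beta1 * mW[l] + (1 - beta1) * gW[l]
                vW[l] = beta2 * vW[l] + (1 - beta2) * gW[l] ** 2
                mb[l] = beta1 * mb[l] + (1 - beta1) * gb[l]
                vb[l] = beta2 * vb[l] + (1 - beta2) * gb[l] ** 2
                mhW = mW[l] / (1 - beta1 ** t)
                vhW = vW[l] / (1 - beta2 ** t)
                mhb = mb[l] / (1 - beta1 ** t)
                vhb = vb[l] / (1 - beta2 ** t)
                self.Ws[l] -= lr_t * mhW / (np.sqrt(vhW) + eps)
                self.bs[l] -= lr_t * mhb / (np.sqrt(vhb) + eps)
            if verbose and epoch % 20 == 0:
                print(f"epoch {epoch}: chi2 train {chi_tr:.3e} val {chi_val:.3e}")
        if best[1] is not None:
            self.Ws = [W.copy() for W in best[1][0]]
            self.bs = [b.copy() for b in best[1][1]]
        return {"history": history, "best_epoch": best[2],
                "chi2_val": best[0],
                "chi2_train": history["train"][best[2]]
                if best[2] >= 0 else float("nan")}

    def _chi_frames(self, Xs, Js, forces, idx, sidx, n):
        total = 0.0
        for f in idx:
            _, G, _ = self._mlp(self._inputs(Xs[f], sidx))
            U = G[:, :self.config.n_features]
            Fpred = -np.einsum("if,ifjc->jc", U, Js[f])
            total += np.sum((Fpred - forces[f]) ** 2) / (3.0 * n)
        return total / len(idx)

    # ---------------- serialization ----------------

    def save(self, path):
        arrays = {}
        for l, (W, b) in enumerate(zip(self.Ws, self.bs)):
            arrays[f"W{l}"] = W
            arrays[f"b{l}"] = b
        np.savez(path, n_layers=len(self.Ws),
                 species=np.array(self.config.species, dtype="U16"),
                 r_cut=self.config.r_cut, n_radial=self.config.n_radial,
                 n_angular=self.config.n_angular,
                 angular=self.config.angular,
                 parity_odd=self.config.parity_odd,
                 hidden=np.array(self.config.hidden, dtype=int), **arrays)

    @classmethod
    def load(cls, path) -> "NeuralCGPotential":
        data = np.load(path, allow_pickle=False)
        config = DescriptorConfig(
            species=list(data["species"]), r_cut=float(data["r_cut"]),
            n_radial=int(data["n_radial"]), n_angular=int(data["n_angular"]),
            angular=bool(data["angular"]), parity_odd=bool(data["parity_odd"]),
            hidden=tuple(int(h) for h in data["hidden"]))
        model = cls(config)
        n_layers = int(data["n_layers"])
        model.Ws = [data[f"W{l}"] for l in range(n_layers)]
        model.bs = [data[f"b{l}"] for l in range(n_layers)]
        return model


def chi_squared_direct(model: NeuralCGPotential, cg_traj: CGTrajectory) -> float:
    """Independent direct-summation chi^2: recompute forces frame by frame
    through energy_forces and average the squared residual per component."""
    total = 0.0
    for f in range(cg_traj.n_frames):
        _, F = model.energy_forces(cg_traj.positions[f], cg_traj.box,
                                   cg_traj.species)
        total += np.sum((F - cg_traj.forces[f]) ** 2) / (3.0 * cg_traj.n_atoms)
    return total / cg_traj.n_frames
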