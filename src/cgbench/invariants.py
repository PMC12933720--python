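"""Invariant many-body descriptors for the learnable CG potential.

Per-bead features built from the neighborhood within a smooth cutoff:

* radial (2-body): species-resolved Gaussian density moments,
  sum_J one_hot(s_J) * exp(-(r - mu_k)^2 / 2 delta^2) * fc(r);
* angular (3-body): cosine moments over neighbor pairs,
  sum_{J<K} fc(r_J) fc(r_K) cos^p(theta_JIK);
* parity-odd (4-body): a signed-volume invariant over neighbor triplets,
  sum_{J<K<L} fc fc fc * [v_J . (v_K x v_L)] * (r_J - r_K)(r_K - r_L)(r_J - r_L) / r_cut^6.

All features are invariant under rotation and translation. The radial and
angular blocks are also invariant under reflection; the signed-volume
block changes sign, which is exactly what a scalar-energy model needs to
distinguish enantiomers. The triple product and the Vandermonde distance
factor are each totally antisymmetric under neighbor permutation, so
their product is symmetric and the sum over unordered triplets is
well defined.

The body-order knob nu_tilde maps onto the feature blocks: 1 keeps only
radial features, 2 adds angular, 3 adds the parity-odd block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .box import Box


@dataclass
class DescriptorConfig:
    species: list
    r_cut: float = 1.0
    n_radial: int = 6
    n_angular: int = 2
    angular: bool = True
    parity_odd: bool = False
    hidden: tuple = (16,)
    nu_tilde: int | None = None

    def __post_init__(self):
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.nu_tilde is not None:
            if self.nu_tilde < 1:
                raise ValueError("nu_tilde must be >= 1")
            self.angular = self.nu_tilde >= 2
            self.parity_odd = self.nu_tilde >= 3
        self.species = list(self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_features(self) -> int:
        n = self.n_species * self.n_radial
        if self.angular:
            n += self.n_angular
        if self.parity_odd:
            n += 1
        return n

    def species_index(self, labels: list) -> np.ndarray:
        table = {s: i for i, s in enumerate(self.species)}
        try:
            return np.array([table[s] for s in labels], dtype=int)
        except KeyError as err:
            raise ValueError(f"species {err} not in embedding table") from err


def _cutoff(r, rc):
    """Smooth cosine cutoff envelope, C1 at r = rc."""
    fc = 0.5 * (np.cos(np.pi * r / rc) + 1.0)
    dfc = -0.5 * np.pi / rc * np.sin(np.pi * r / rc)
    return fc, dfc


def descriptor_features(positions: np.ndarray, box: Box | None,
                        species: list, config: DescriptorConfig,
                        jacobian: bool = False):
    """Per-bead feature matrix X (N, n_features); with ``jacobian=True``
    also d X / d R as a dense (N, n_features, N, 3) array."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    sidx = config.species_index(species)
    nf = config.n_features
    rc = config.r_cut
    mu = np.linspace(0.0, rc, config.n_radial)
    delta = rc / config.n_radial
    X = np.zeros((n, nf))
    J = np.zeros((n, nf, n, 3)) if jacobian else None

    ang_off = config.n_species * config.n_radial
    par_off = ang_off + (config.n_angular if config.angular else 0)
    # bring the 4-body invariant onto the same scale as the 2/3-body blocks
    vol_scale = 100.0 / rc ** 6

    for i in range(n):
        d = positions - positions[i]
        if box is not None:
            d = box.minimum_image(d)
        r = np.linalg.norm(d, axis=1)
        nb = np.flatnonzero((r < rc) & (np.arange(n) != i))
        if len(nb) == 0:
            continue
        v = d[nb]
        rr = r[nb]
        u = v / rr[:, None]
        fc, dfc = _cutoff(rr, rc)

        # radial block
        for k in range(config.n_radial):
            g = np.exp(-((rr - mu[k]) ** 2) / (2 * delta * delta))
            gp = g * (-(rr - mu[k]) / (delta * delta))
            val = g * fc
            dval = gp * fc + g * dfc
            cols = sidx[nb] * config.n_radial + k
            np.add.at(X[i], cols, val)
            if jacobian:
                for m, jat in enumerate(nb):
                    J[i, cols[m], jat] += dval[m] * u[m]
                    J[i, cols[m], i] -= dval[m] * u[m]

        # angular block
        if config.angular and len(nb) >= 2:
            for a, b in combinations(range(len(nb)), 2):
                c = float(u[a] @ u[b])
                w = fc[a] * fc[b]
                dca = (u[b] - c * u[a]) / rr[a]
                dcb = (u[a] - c * u[b]) / rr[b]
                for p in range(1, config.n_angular + 1):
                    col = ang_off + p - 1
                    X[i, col] += w * c ** p
                    if jacobian:
                        cpm1 = p * c ** (p - 1)
                        ga = (dfc[a] * fc[b] * c ** p) * u[a] + w * cpm1 * dca
                        gb = (fc[a] * dfc[b] * c ** p) * u[b] + w * cpm1 * dcb
                        J[i, col, nb[a]] += ga
                        J[i, col, nb[b]] += gb
                        J[i, col, i] -= ga + gb
        # parity-odd block
        if config.parity_odd and len(nb) >= 3:
            col = par_off
            for a, b, cdx in combinations(range(len(nb)), 3):
                ra, rb, rcd = rr[a], rr[b], rr[cdx]
                w3 = fc[a] * fc[b] * fc[cdx]
                cross_bc = np.cross(v[b], v[cdx])
                V = float(v[a] @ cross_bc)
                W = (ra - rb) * (rb - rcd) * (ra - rcd)
                X[i, col] += vol_scale * w3 * V * W
                if jacobian:
                    cross_ca = np.cross(v[cdx], v[a])
                    cross_ab = np.cross(v[a], v[b])
                    dW_da = (rb - rcd) * ((ra - rcd) + (ra - rb))
                    dW_db = (ra - rcd) * ((ra - rb) - (rb - rcd))
                    dW_dc = -(ra - rb) * ((ra - rcd) + (rb - rcd))
                    ga = vol_scale * ((dfc[a] * fc[b] * fc[cdx] * V * W +
                                       w3 * V * dW_da) * u[a] +
                                      w3 * W * cross_bc)
                    gb = vol_scale * ((fc[a] * dfc[b] * fc[cdx] * V * W +
                                       w3 * V * dW_db) * u[b] +
                                      w3 * W * cross_ca)
                    gc = vol_scale * ((fc[a] * fc[b] * dfc[cdx] * V * W +
                                       w3 * V * dW_dc) * u[cdx] +
                                      w3 * W * cross_ab)
                    J[i, col, nb[a]] += ga
                    J[i, col, nb[b]] += gb
                    J[i, col, nb[cdx]] += gc
                    J[i, col, i] -= ga + gb + gc
    if jacobian:
        return X, J
    return X
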