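"""Internal-coordinate geometry: bonds, angles, signed dihedrals and their
analytic gradients.

Dihedrals follow the IUPAC sign convention: the signed angle lies in
(-pi, pi], computed via atan2 of the plane normals, positive for a
clockwise rotation of the far bond looking down the central bond.
All functions are vectorized over term lists and apply the minimum-image
convention when a periodic box is given.
"""

from __future__ import annotations

import numpy as np

from .box import Box


class DegenerateGeometryError(ValueError):
    """Raised when an internal coordinate is undefined (zero-length or
    collinear vectors), naming the offending term."""


def _disp(positions: np.ndarray, i: np.ndarray, j: np.ndarray, box: Box | None):
    d = positions[j] - positions[i]
    if box is not None:
        d = box.minimum_image(d)
    return d


def bond_lengths(positions: np.ndarray, pairs: np.ndarray, box: Box | None = None):
    """Lengths and unit vectors for index pairs; returns (r, rvec)."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    rvec = _disp(positions, pairs[:, 0], pairs[:, 1], box)
    r = np.linalg.norm(rvec, axis=1)
    return r, rvec


def angles_and_grads(positions: np.ndarray, triples: np.ndarray,
                     box: Box | None = None, name: str = "angle"):
    """Angles theta (rad) at the central (middle) index of each triple and
    gradients d theta/d r with shape (n, 3, 3)."""
    triples = np.asarray(triples, dtype=int).reshape(-1, 3)
    u = _disp(positions, triples[:, 1], triples[:, 0], box)   # center -> i
    v = _disp(positions, triples[:, 1], triples[:, 2], box)   # center -> k
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-10) or np.any(nv < 1e-10):
        bad = int(np.argmax((nu < 1e-10) | (nv < 1e-10)))
        raise DegenerateGeometryError(
            f"zero-length bond vector in {name} term {bad} "
            f"(atoms {tuple(triples[bad])})")
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-14))
    # d theta / d r_i = (c*uh - vh) / (|u| * sin)
    gi = (c[:, None] * uh - vh) / (nu * s)[:, None]
    gk = (c[:, None] * vh - uh) / (nv * s)[:, None]
    gj = -(gi + gk)
    grads = np.stack([gi, gj, gk], axis=1)
    return theta, grads


def dihedrals_and_grads(positions: np.ndarray, quads: np.ndarray,
                        box: Box | None = None, name: str = "dihedral"):
    """Signed dihedrals phi in (-pi, pi] over quadruples (i, j, k, l) and
    gradients d phi/d r with shape (n, 4, 3)."""
    quads = np.asarray(quads, dtype=int).reshape(-1, 4)
    b1 = _disp(positions, quads[:, 0], quads[:, 1], box)
    b2 = _disp(positions, quads[:, 1], quads[:, 2], box)
    b3 = _disp(positions, quads[:, 2], quads[:, 3], box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    nn1 = np.einsum("ij,ij->i", n1, n1)
    nn2 = np.einsum("ij,ij->i", n2, n2)
    if np.any(nb2 < 1e-10) or np.any(nn1 < 1e-18) or np.any(nn2 < 1e-18):
        bad = int(np.argmax((nb2 < 1e-10) | (nn1 < 1e-18) | (nn2 < 1e-18)))
        raise DegenerateGeometryError(
            f"degenerate (collinear or zero-length) geometry in {name} term "
            f"{bad} (atoms {tuple(quads[bad])})")
    # phi = atan2((n1 x n2).b2hat, n1.n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / nb2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    phi = np.arctan2(y, x)

    # standard analytic gradient
    gi = -(nb2 / nn1)[:, None] * n1
    gl = (nb2 / nn2)[:, None] * n2
    c12 = (np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2))[:, None]
    c32 = (np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2))[:, None]
    gj = -(1.0 + c12) * gi + c32 * gl
    gk = c12 * gi - (1.0 + c32) * gl
    grads = np.stack([gi, gj, gk, gl], axis=1)
    return phi, grads


def wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap angle(s) in radians into (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    out = phi - 2.0 * np.pi * np.floor(phi / (2.0 * np.pi) + 0.5)
    # floor maps pi -> -pi; keep the convention half-open on the left
    if out.ndim == 0:
        return np.array(np.pi) if out == -np.pi else out
    out[out == -np.pi] = np.pi
    return out


def wrap_angle_deg(phi: np.ndarray) -> np.ndarray:
    """Wrap angle(s) in degrees into (-180, 180]."""
    phi = np.asarray(phi, dtype=float)
    out = phi - 360.0 * np.floor(phi / 360.0 + 0.5)
    if out.ndim == 0:
        return np.array(180.0) if out == -180.0 else out
    out[out == -180.0] = 180.0
    return out
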