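"""Verlet neighbor lists with cell-linked acceleration."""

from __future__ import annotations

import numpy as np

from .box import Box


def _brute_pairs(positions: np.ndarray, box: Box | None, cutoff: float):
    n = len(positions)
    if n < 2:
        return np.zeros((0, 2), dtype=int)
    iu, ju = np.triu_indices(n, k=1)
    d = positions[ju] - positions[iu]
    if box is not None:
        d = box.minimum_image(d)
    r2 = np.einsum("ij,ij->i", d, d)
    keep = r2 < cutoff * cutoff
    return np.stack([iu[keep], ju[keep]], axis=1)


def build_neighbor_list(positions: np.ndarray, box: Box | None, r_cut: float,
                        skin: float = 0.0) -> np.ndarray:
    """All pairs (i < j) with minimum-image distance < r_cut + skin.

    Uses a cell-linked list when the box accommodates >= 3 cells per
    periodic axis, otherwise falls back to the O(N^2) scan. Raises if a
    periodic edge is too small for the requested cutoff.
    """
    positions = np.asarray(positions, dtype=float)
    cutoff = r_cut + skin
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if box is not None and np.any(box.periodic):
        min_edge = np.min(box.lengths[box.periodic])
        if cutoff >= 0.5 * min_edge:
            raise ValueError(
                f"cutoff {cutoff} >= half the smallest periodic edge "
                f"{min_edge / 2}; box too small")
    n = len(positions)
    use_cells = (box is not None and np.all(box.periodic) and n > 64
                 and np.all(np.floor(box.lengths / cutoff) >= 3))
    if not use_cells:
        return _brute_pairs(positions, box, cutoff)

    ncell = np.floor(box.lengths / cutoff).astype(int)
    wrapped = box.wrap(positions)
    cell_of = np.minimum((wrapped / (box.lengths / ncell)).astype(int), ncell - 1)
    cell_id = (cell_of[:, 0] * ncell[1] + cell_of[:, 1]) * ncell[2] + cell_of[:, 2]
    order = np.argsort(cell_id, kind="stable")
    members: dict = {}
    for idx in order:
        members.setdefault(int(cell_id[idx]), []).append(int(idx))

    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1)]
    out_i, out_j = [], []
    c2 = cutoff * cutoff
    for cid, atoms in members.items():
        cx, rem = divmod(cid, ncell[1] * ncell[2])
        cy, cz = divmod(rem, ncell[2])
        a = np.array(atoms)
        for dx, dy, dz in offsets:
            nx = (cx + dx) % ncell[0]
            ny = (cy + dy) % ncell[1]
            nz = (cz + dz) % ncell[2]
            nid = (nx * ncell[1] + ny) * ncell[2] + nz
            if nid < cid:
                continue
            b = members.get(int(nid))
            if b is None:
                continue
            b = np.array(b)
            if nid == cid:
                ii, jj = np.triu_indices(len(a), k=1)
                cand_i, cand_j = a[ii], a[jj]
            else:
                cand_i = np.repeat(a, len(b))
                cand_j = np.tile(b, len(a))
            d = box.minimum_image(wrapped[cand_j] - wrapped[cand_i])
            keep = np.einsum("ij,ij->i", d, d) < c2
            out_i.append(cand_i[keep])
            out_j.append(cand_j[keep])
    if not out_i:
        return np.zeros((0, 2), dtype=int)
    i = np.concatenate(out_i)
    j = np.concatenate(out_j)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    pairs = np.unique(np.stack([lo, hi], axis=1), axis=0)
    return pairs


class VerletList:
    """Skin-buffered pair list, rebuilt when any particle has moved more
    than skin/2 since the last build (standard correctness bound)."""

    def __init__(self, box: Box | None, r_cut: float, skin: float = 0.15):
        self.box = box
        self.r_cut = r_cut
        self.skin = skin
        self._ref = None
        self.pairs = None

    def update(self, positions: np.ndarray) -> np.ndarray:
        if self._ref is not None:
            d = positions - self._ref
            if self.box is not None:
                d = self.box.minimum_image(d)
            if np.max(np.einsum("ij,ij->i", d, d)) < (0.5 * self.skin) ** 2:
                return self.pairs
        self.pairs = build_neighbor_list(positions, self.box, self.r_cut,
                                         self.skin)
        self._ref = positions.copy()
        return self.pairs
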