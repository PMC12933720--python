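"""Trajectory container: stacked frames of positions, forces, velocities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .box import Box


@dataclass
class Trajectory:
    """Frames of an MD run.

    positions : (F, N, 3) nm
    forces    : (F, N, 3) kJ/mol/nm or None
    velocities: (F, N, 3) nm/ps or None
    times     : (F,) ps
    energies  : (F,) total energy kJ/mol or None
    box       : shared Box
    species   : per-site labels (list of str) or None
    masses    : (N,) amu or None
    """

    positions: np.ndarray
    box: Box
    times: np.ndarray
    forces: np.ndarray | None = None
    velocities: np.ndarray | None = None
    energies: np.ndarray | None = None
    species: list | None = None
    masses: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must be (frames, atoms, 3)")
        self.times = np.asarray(self.times, dtype=float)
        for name in ("forces", "velocities"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.positions.shape:
                    raise ValueError(f"{name} shape mismatch")
                setattr(self, name, arr)
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def slice(self, idx) -> "Trajectory":
        sl = np.atleast_1d(np.arange(self.n_frames)[idx])
        return Trajectory(
            self.positions[sl], self.box, self.times[sl],
            None if self.forces is None else self.forces[sl],
            None if self.velocities is None else self.velocities[sl],
            None if self.energies is None else self.energies[sl],
            self.species, self.masses)

    @staticmethod
    def concatenate(trajs: list) -> "Trajectory":
        first = trajs[0]

        def cat(attr):
            arrs = [getattr(t, attr) for t in trajs]
            if any(a is None for a in arrs):
                return None
            return np.concatenate(arrs, axis=0)

        return Trajectory(
            np.concatenate([t.positions for t in trajs], axis=0), first.box,
            np.concatenate([t.times for t in trajs]), cat("forces"),
            cat("velocities"), cat("energies"), first.species, first.masses)
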