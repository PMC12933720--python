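"""Orthorhombic simulation box with per-axis periodicity."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Box:
    """Orthorhombic box.

    Parameters
    ----------
    lengths : (3,) array
        Edge lengths in nm.
    periodic : (3,) bool array
        Which axes wrap. Edge lengths must be positive on periodic axes.
    """

    lengths: np.ndarray
    periodic: np.ndarray = field(default_factory=lambda: np.ones(3, dtype=bool))

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        self.periodic = np.asarray(self.periodic, dtype=bool).reshape(3)
        if np.any(self.lengths[self.periodic] <= 0):
            raise ValueError("periodic box edges must be positive")

    @classmethod
    def cubic(cls, edge: float, periodic: bool = True) -> "Box":
        return cls(np.full(3, float(edge)), np.full(3, periodic))

    @classmethod
    def open(cls) -> "Box":
        """Non-periodic (vacuum) box."""
        return cls(np.ones(3), np.zeros(3, dtype=bool))

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Wrap displacement(s) into [-L/2, L/2) on periodic axes.

        Accepts a single 3-vector or an (..., 3) array.
        """
        d = np.asarray(d, dtype=float)
        out = d.copy()
        for ax in range(3):
            if self.periodic[ax]:
                L = self.lengths[ax]
                out[..., ax] -= L * np.floor(d[..., ax] / L + 0.5)
        return out

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap absolute positions into [0, L) on periodic axes."""
        pos = np.asarray(positions, dtype=float).copy()
        for ax in range(3):
            if self.periodic[ax]:
                L = self.lengths[ax]
                pos[..., ax] -= L * np.floor(pos[..., ax] / L)
        return pos


def minimum_image(displacement: np.ndarray, box: Box) -> np.ndarray:
    """Functional alias for :meth:`Box.minimum_image`."""
    return box.minimum_image(displacement)
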