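"""Instantaneous MD state and kinetic observables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .box import Box


@dataclass
class MDState:
    """Positions (nm), velocities (nm/ps), masses (amu), box, time (ps)."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    box: Box
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.positions)
        if len(self.velocities) != n or len(self.masses) != n:
            raise ValueError("array lengths disagree")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "MDState":
        return MDState(self.positions.copy(), self.velocities.copy(),
                       self.masses.copy(), self.box, self.time)


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kJ/mol (amu nm^2/ps^2 == kJ/mol)."""
    v = np.asarray(velocities, dtype=float)
    return float(0.5 * np.sum(np.asarray(masses) * np.einsum("ij,ij->i", v, v)))


def instantaneous_thermal_energy(velocities: np.ndarray, masses: np.ndarray,
                                 n_dof: int | None = None) -> float:
    """Instantaneous thermal energy 2*KE/n_dof in kJ/mol.

    Defaults to n_dof = 3N (no COM-momentum removal); an estimate of k_B*T
    at equipartition. Configurable via n_dof.
    """
    v = np.asarray(velocities, dtype=float).reshape(-1, 3)
    if len(v) == 0:
        raise ValueError("need at least one particle")
    if n_dof is None:
        n_dof = 3 * len(v)
    return 2.0 * kinetic_energy(v, masses) / n_dof


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Velocities drawn from the Maxwell-Boltzmann distribution (nm/ps)."""
    from .constants import KB
    masses = np.asarray(masses, dtype=float)
    sigma = np.sqrt(KB * temperature / masses)
    return rng.standard_normal((len(masses), 3)) * sigma[:, None]
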