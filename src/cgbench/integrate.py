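"""Time integration: velocity-Verlet NVE and BAOAB Langevin NVT.

The BAOAB splitting (velocity half-kick, half-drift, Ornstein-Uhlenbeck
velocity refresh, half-drift, force update, half-kick) gives accurate
configurational sampling at practical time steps. With a fixed seed the
stochastic trajectory is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .constants import KB
from .forcefield import ForceField
from .neighbors import VerletList
from .state import MDState, kinetic_energy
from .trajectory import Trajectory


class IntegrationError(RuntimeError):
    """Non-finite energy or force encountered during a run."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(f"integration aborted at step {step}: {message}")


def _force_evaluator(forcefield, state: MDState, skin: float):
    """Wraps a ForceField (or bare callable (positions, box) -> (E, F))
    with Verlet-list bookkeeping."""
    if isinstance(forcefield, ForceField) and forcefield.params.lj:
        vlist = VerletList(state.box, forcefield.params.r_cut, skin)

        def fn(positions):
            pairs = vlist.update(positions)
            return forcefield.energy_forces(positions, state.box, pairs)
    else:
        def fn(positions):
            return forcefield(positions, state.box)
    return fn


def _check_finite(step: int, energy: float, forces: np.ndarray):
    if not np.isfinite(energy) or not np.all(np.isfinite(forces)):
        raise IntegrationError(step, "non-finite energy or force")


def _collect(frames, state, energy, forces):
    frames["positions"].append(state.positions.copy())
    frames["velocities"].append(state.velocities.copy())
    frames["forces"].append(forces.copy())
    frames["energies"].append(energy + kinetic_energy(state.velocities,
                                                      state.masses))
    frames["times"].append(state.time)


def _finish(frames, state, species):
    return Trajectory(np.array(frames["positions"]), state.box,
                      np.array(frames["times"]), np.array(frames["forces"]),
                      np.array(frames["velocities"]),
                      np.array(frames["energies"]), species, state.masses)


def integrate_nve(state: MDState, forcefield, dt: float, n_steps: int,
                  stride: int = 1, skin: float = 0.15,
                  species: list | None = None) -> Trajectory:
    """Velocity-Verlet microcanonical run. Stores the initial frame and
    every ``stride``-th step; energies are total (potential + kinetic)."""
    state = state.copy()
    fn = _force_evaluator(forcefield, state, skin)
    energy, forces = fn(state.positions)
    _check_finite(0, energy, forces)
    frames = {k: [] for k in ("positions", "velocities", "forces",
                              "energies", "times")}
    _collect(frames, state, energy, forces)
    inv_m = 1.0 / state.masses[:, None]
    for step in range(1, n_steps + 1):
        state.velocities += 0.5 * dt * forces * inv_m
        state.positions += dt * state.velocities
        energy, forces = fn(state.positions)
        _check_finite(step, energy, forces)
        state.velocities += 0.5 * dt * forces * inv_m
        state.time += dt
        if step % stride == 0:
            _collect(frames, state, energy, forces)
    return _finish(frames, state, species)


def integrate_langevin(state: MDState, forcefield, dt: float,
                       temperature: float, friction: float, n_steps: int,
                       seed: int, stride: int = 1, skin: float = 0.15,
                       species: list | None = None) -> Trajectory:
    """BAOAB Langevin (NVT) run; identical seed => identical trajectory."""
    if temperature <= 0 or friction <= 0:
        raise ValueError("temperature and friction must be positive")
    state = state.copy()
    rng = np.random.default_rng(seed)
    fn = _force_evaluator(forcefield, state, skin)
    energy, forces = fn(state.positions)
    _check_finite(0, energy, forces)
    frames = {k: [] for k in ("positions", "velocities", "forces",
                              "energies", "times")}
    _collect(frames, state, energy, forces)
    inv_m = 1.0 / state.masses[:, None]
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * KB * temperature / state.masses)[:, None]
    for step in range(1, n_steps + 1):
        state.velocities += 0.5 * dt * forces * inv_m          # B
        state.positions += 0.5 * dt * state.velocities          # A
        state.velocities = (c1 * state.velocities +             # O
                            c2 * rng.standard_normal(state.velocities.shape))
        state.positions += 0.5 * dt * state.velocities          # A
        energy, forces = fn(state.positions)
        _check_finite(step, energy, forces)
        state.velocities += 0.5 * dt * forces * inv_m          # B
        state.time += dt
        if step % stride == 0:
            _collect(frames, state, energy, forces)
    return _finish(frames, state, species)
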