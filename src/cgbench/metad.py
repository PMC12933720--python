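"""Well-tempered metadynamics along dihedral collective variables.

The history-dependent bias is a sum of Gaussians whose deposited heights
decay with the bias already accumulated at the deposition point,

    V(s, t) = sum_{t' < t} h exp(-V(s(t'), t') / (k_B T (gamma - 1)))
                           exp(-(s - s(t'))^2 / (2 sigma^2)),

with bias factor gamma = T*/T > 1 (the collective variable is effectively
sampled at temperature T* = gamma T). The free energy estimate uses the
standard asymptotic rescaling of the final bias,
F(s) = -(gamma/(gamma-1)) V(s, t_final), shifted to zero at its minimum.

Angular CVs are periodic on (-180, 180] degrees; Gaussian distances use
the nearest periodic image (widths are assumed small against the period).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .geometry import dihedrals_and_grads
from .state import MDState, maxwell_boltzmann_velocities
from .systems import SystemSpec
from .trajectory import Trajectory


@dataclass
class CollectiveVariable:
    """A signed (improper) dihedral CV in degrees over a site quadruple."""

    kind: str                # 'dihedral' or 'improper_dihedral'
    quadruple: tuple
    periodic: bool = True

    def __post_init__(self):
        if self.kind not in ("dihedral", "improper_dihedral"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if len(set(self.quadruple)) != 4:
            raise ValueError("CV quadruple must have 4 distinct indices")


def eval_cv(positions: np.ndarray, cv: CollectiveVariable, box=None):
    """CV value (degrees) and analytic gradient (degrees/nm) per site."""
    quad = np.array([cv.quadruple], dtype=int)
    phi, grads = dihedrals_and_grads(positions, quad, box, cv.kind)
    return float(np.degrees(phi[0])), np.degrees(grads[0])


@dataclass
class BiasHistory:
    """Deposited Gaussians plus the well-tempered bookkeeping."""

    initial_height: float            # h, kJ/mol
    sigma: float                     # CV units
    gamma: float                     # bias factor T*/T
    temperature: float               # K
    period: float | None = 360.0     # CV period; None for non-periodic
    centers: list = field(default_factory=list)
    heights: list = field(default_factory=list)
    times: list = field(default_factory=list)

    def __post_init__(self):
        if self.gamma <= 1:
            raise ValueError("bias factor gamma must exceed 1")
        if self.sigma <= 0 or self.initial_height <= 0:
            raise ValueError("sigma and height must be positive")


def _cv_delta(s, centers, period):
    d = s - np.asarray(centers)
    if period is not None:
        d -= period * np.round(d / period)
    return d


def eval_bias(history: BiasHistory, s: float):
    """Bias V(s) in kJ/mol and its derivative dV/ds from the deposited
    Gaussians (wrapped distances for periodic CVs)."""
    if not history.centers:
        return 0.0, 0.0
    d = _cv_delta(s, history.centers, history.period)
    h = np.asarray(history.heights)
    g = h * np.exp(-d * d / (2.0 * history.sigma ** 2))
    return float(g.sum()), float(np.sum(g * (-d / history.sigma ** 2)))


def deposit(history: BiasHistory, s: float, t: float) -> float:
    """Deposit a Gaussian at s with well-tempered height rescaling;
    returns the deposited height."""
    v_here, _ = eval_bias(history, s)
    height = history.initial_height * np.exp(
        -v_here / (KB * history.temperature * (history.gamma - 1.0)))
    history.centers.append(float(s))
    history.heights.append(float(height))
    history.times.append(float(t))
    return float(height)


def run_wtmetad(system: SystemSpec, cv: CollectiveVariable,
                height: float = 1.2, sigma: float = 10.0,
                gamma: float = 6.0, stride: int = 500,
                temperature: float = 300.0, dt: float = 0.002,
                friction: float = 5.0, n_steps: int = 100_000,
                seed: int = 0, frame_stride: int = 100,
                potential=None):
    """WTMetaD on a molecular system: BAOAB Langevin dynamics with the
    bias force added along the CV gradient. Deterministic per seed.

    ``potential`` defaults to the system's own force field; any callable
    (positions, box) -> (energy, forces) may be substituted (e.g. a
    fitted CG potential).
    """
    rng = np.random.default_rng(seed)
    state = system.state.copy()
    state.velocities = maxwell_boltzmann_velocities(state.masses, temperature,
                                                    rng)
    rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    ff = potential if potential is not None else system.forcefield
    history = BiasHistory(height if height > 0 else 1.0, sigma, gamma,
                          temperature, period=360.0)
    biased = height > 0
    inv_m = 1.0 / state.masses[:, None]
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * KB * temperature / state.masses)[:, None]

    def total_force(positions):
        e, f = ff(positions, state.box) if callable(ff) else \
            ff.energy_forces(positions, state.box)
        s, dsdr = eval_cv(positions, cv, state.box)
        _, dVds = eval_bias(history, s)
        f = f - dVds * dsdr_full(dsdr, len(positions))
        return e, f, s

    def dsdr_full(grads, n):
        full = np.zeros((n, 3))
        for k, atom in enumerate(cv.quadruple):
            full[atom] = grads[k]
        return full

    energy, forces, s = total_force(state.positions)
    frames = {"positions": [state.positions.copy()],
              "velocities": [state.velocities.copy()],
              "forces": [forces.copy()], "times": [state.time],
              "cv": [s]}
    for step in range(1, n_steps + 1):
        state.velocities += 0.5 * dt * forces * inv_m
        state.positions += 0.5 * dt * state.velocities
        state.velocities = (c1 * state.velocities +
                            c2 * rng.standard_normal(state.velocities.shape))
        state.positions += 0.5 * dt * state.velocities
        energy, forces, s = total_force(state.positions)
        if not np.isfinite(energy) or not np.all(np.isfinite(forces)):
            raise RuntimeError(
                f"WTMetaD unstable at step {step}; "
                f"{len(history.centers)} Gaussians deposited")
        state.velocities += 0.5 * dt * forces * inv_m
        state.time += dt
        if biased and step % stride == 0:
            deposit(history, s, state.time)
        if step % frame_stride == 0:
            frames["positions"].append(state.positions.copy())
            frames["velocities"].append(state.velocities.copy())
            frames["forces"].append(forces.copy())
            frames["times"].append(state.time)
            frames["cv"].append(s)
    traj = Trajectory(np.array(frames["positions"]), state.box,
                      np.array(frames["times"]), np.array(frames["forces"]),
                      np.array(frames["velocities"]),
                      species=system.topology.species, masses=state.masses)
    return traj, history, np.array(frames["cv"])


def run_wtmetad_1d(potential, grad, s0: float, mass: float = 12.0,
                   height: float = 1.2, sigma: float = 0.1,
                   gamma: float = 6.0, stride: int = 500,
                   temperature: float = 300.0, dt: float = 0.002,
                   friction: float = 5.0, n_steps: int = 200_000,
                   seed: int = 0, period: float | None = None,
                   grid_points: int = 1024, grid_range: tuple = (-3.0, 3.0)):
    """WTMetaD for a scalar coordinate s with analytic potential U(s).

    The accumulated bias and its derivative are kept on a dense grid
    (updated at each deposition) so per-step bias evaluation is an
    interpolation — the standard grid trick. Returns the sampled s series
    and the BiasHistory.
    """
    rng = np.random.default_rng(seed)
    history = BiasHistory(height, sigma, gamma, temperature, period=period)
    grid = np.linspace(grid_range[0], grid_range[1], grid_points)
    Vg = np.zeros_like(grid)
    dVg = np.zeros_like(grid)
    s = float(s0)
    v = rng.normal() * np.sqrt(KB * temperature / mass)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * KB * temperature / mass)
    series = np.empty(n_steps // 10 + 1)
    series[0] = s
    k = 1
    f = -grad(s) - np.interp(s, grid, dVg)
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f / mass
        s += 0.5 * dt * v
        v = c1 * v + c2 * rng.normal()
        s += 0.5 * dt * v
        f = -grad(s) - np.interp(s, grid, dVg)
        v += 0.5 * dt * f / mass
        if step % stride == 0:
            h_dep = deposit(history, s, step * dt)
            d = _cv_delta_grid(grid, s, period)
            gauss = h_dep * np.exp(-d * d / (2.0 * sigma ** 2))
            Vg += gauss
            dVg += gauss * (-d / sigma ** 2)
        if step % 10 == 0:
            series[k] = s
            k += 1
    return series[:k], history


def _cv_delta_grid(grid, center, period):
    d = grid - center
    if period is not None:
        d -= period * np.round(d / period)
    return d


def reconstruct_fes(history: BiasHistory, grid: np.ndarray):
    """F(s) = -(gamma/(gamma-1)) V(s, final), shifted so min F = 0."""
    if not history.centers:
        raise ValueError("empty bias history")
    V = np.array([eval_bias(history, s)[0] for s in grid])
    F = -history.gamma / (history.gamma - 1.0) * V
    return F - F.min()


def barrier_height(grid: np.ndarray, profile: np.ndarray,
                   basin_a: tuple, basin_b: tuple):
    """Barrier from basin A to basin B: the maximum of F along the path
    between the two basin minima, minus the basin-A minimum (kJ/mol and
    kcal/mol)."""
    from .constants import KJ_PER_KCAL
    grid = np.asarray(grid)
    profile = np.asarray(profile)

    def basin_min(lo, hi):
        m = (grid >= lo) & (grid <= hi) & np.isfinite(profile)
        if not np.any(m):
            raise ValueError(f"basin [{lo}, {hi}] not sampled")
        idx = np.flatnonzero(m)
        return idx[np.argmin(profile[m])]

    ia = basin_min(*basin_a)
    ib = basin_min(*basin_b)
    lo, hi = min(ia, ib), max(ia, ib)
    path = profile[lo:hi + 1]
    if np.any(~np.isfinite(path)):
        raise ValueError("unsampled gap between basins")
    barrier = float(path.max() - profile[ia])
    return barrier, barrier / KJ_PER_KCAL
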