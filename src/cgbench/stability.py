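"""Stability classifiers for CG trajectories.

Two criteria, applied per frame with truncation at first failure (a
failing frame and all subsequent frames are excluded):

* thermal-energy criterion for bulk systems: the instantaneous thermal
  energy 2 KE / (3N) must stay below a threshold (default 5 kJ/mol,
  about twice k_B T at 300 K);
* bond-distance criterion for molecular systems: no bond may deviate by
  more than a tolerance (default 0.05 nm) from its type's equilibrium
  length, where equilibrium lengths are pooled means over a reference
  trajectory.

Both thresholds are strict inequalities at the boundary: a frame exactly
at the threshold passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import bond_lengths
from .state import instantaneous_thermal_energy
from .topology import Topology
from .trajectory import Trajectory


@dataclass
class StabilityReport:
    criterion: str
    passed: np.ndarray              # per-frame flags, monotone after failure
    first_failure: int | None
    stable_duration: float          # ps

    @property
    def stable(self) -> bool:
        return self.first_failure is None


def _truncate(flags: np.ndarray) -> np.ndarray:
    """A failing frame excludes all subsequent frames."""
    out = flags.copy()
    bad = np.flatnonzero(~flags)
    if len(bad):
        out[bad[0]:] = False
    return out


def _report(criterion: str, flags: np.ndarray, times: np.ndarray):
    flags = _truncate(flags)
    bad = np.flatnonzero(~flags)
    first = int(bad[0]) if len(bad) else None
    if first is None:
        duration = float(times[-1] - times[0]) if len(times) > 1 else 0.0
    elif first == 0:
        duration = 0.0
    else:
        duration = float(times[first - 1] - times[0])
    return StabilityReport(criterion, flags, first, duration)


def energy_stability(traj: Trajectory, threshold: float = 5.0,
                     window: int = 1) -> StabilityReport:
    """Thermal-energy criterion: pass while 2 KE/(3N) < threshold (kJ/mol).

    window > 1 averages the instantaneous value over a trailing window of
    frames before comparing (the default is instantaneous).
    """
    if traj.velocities is None:
        raise ValueError("trajectory has no velocities")
    if traj.masses is None:
        raise ValueError("trajectory has no masses")
    te = np.array([instantaneous_thermal_energy(traj.velocities[f],
                                                traj.masses)
                   for f in range(traj.n_frames)])
    if window > 1:
        kernel = np.ones(window)
        te = np.array([te[max(0, f - window + 1):f + 1].mean()
                       for f in range(len(te))])
    flags = te < threshold
    return _report("thermal_energy", flags, traj.times)


def equilibrium_bond_lengths(reference: Trajectory,
                             topology: Topology) -> dict:
    """Mean bond length per bond type (canonical species pair), pooled
    over all frames and bond instances of the reference."""
    if reference.n_frames == 0:
        raise ValueError("empty reference trajectory")
    species = topology.species
    groups: dict = {}
    for i, j in topology.bonds:
        key = tuple(sorted((species[i], species[j])))
        groups.setdefault(key, []).append((i, j))
    out = {}
    for key, rows in groups.items():
        rows = np.array(rows, dtype=int)
        vals = [bond_lengths(reference.positions[f], rows, reference.box)[0]
                for f in range(reference.n_frames)]
        out[key] = float(np.mean(np.concatenate(vals)))
    return out


def distance_stability(traj: Trajectory, topology: Topology,
                       equilibrium: dict,
                       tol: float = 0.05) -> StabilityReport:
    """Bond-distance criterion: a frame fails when ANY bond deviates by
    strictly more than tol (nm) from its type's equilibrium length."""
    species = topology.species
    keys = []
    for i, j in topology.bonds:
        key = tuple(sorted((species[i], species[j])))
        if key not in equilibrium:
            raise ValueError(f"bond type {key} missing from equilibrium lengths")
        keys.append(key)
    eq = np.array([equilibrium[k] for k in keys])
    flags = np.ones(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        r, _ = bond_lengths(traj.positions[f], topology.bonds, traj.box)
        flags[f] = not np.any(np.abs(r - eq) > tol)
    return _report("bond_distance", flags, traj.times)
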