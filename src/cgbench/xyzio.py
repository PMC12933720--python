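"""Trajectory I/O: extended XYZ (with force columns), an HDF5 container,
and YAML run manifests.

Extended-XYZ frames carry a key=value comment line with
``Lattice="ax 0 0 0 ay 0 0 0 az"``, ``Properties=species:S:1:pos:R:3[:forces:R:3]``,
``Time=<ps>`` and optionally ``Energy=<kJ/mol>``, the de-facto standard
layout for per-atom force columns.
"""

from __future__ import annotations

import re
import shlex
from pathlib import Path

import h5py
import numpy as np
import yaml

from .box import Box
from .trajectory import Trajectory


def _comment_line(traj: Trajectory, frame: int, with_forces: bool) -> str:
    L = traj.box.lengths
    lattice = f"{L[0]} 0.0 0.0 0.0 {L[1]} 0.0 0.0 0.0 {L[2]}"
    props = "species:S:1:pos:R:3" + (":forces:R:3" if with_forces else "")
    parts = [f'Lattice="{lattice}"', f"Properties={props}",
             f"Time={traj.times[frame]:.6f}",
             f'pbc="{" ".join("T" if p else "F" for p in traj.box.periodic)}"']
    if traj.energies is not None:
        parts.append(f"Energy={traj.energies[frame]:.8f}")
    return " ".join(parts)


def write_extxyz(path, traj: Trajectory, species: list | None = None):
    """Write all frames; includes force columns when the trajectory has
    forces."""
    species = species or traj.species or ["X"] * traj.n_atoms
    with_forces = traj.forces is not None
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(_comment_line(traj, f, with_forces) + "\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.positions[f, a]
                line = f"{species[a]} {x:.10f} {y:.10f} {z:.10f}"
                if with_forces:
                    fx, fy, fz = traj.forces[f, a]
                    line += f" {fx:.10f} {fy:.10f} {fz:.10f}"
                fh.write(line + "\n")


def read_extxyz(path) -> Trajectory:
    positions, forces, times, energies, species = [], [], [], [], None
    box = None
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            comment = fh.readline()
            kv = dict(re.findall(r'(\w+)=("[^"]*"|\S+)', comment))
            kv = {k: v.strip('"') for k, v in kv.items()}
            if box is None:
                lat = np.array([float(v) for v in kv["Lattice"].split()])
                lengths = lat.reshape(3, 3).diagonal()
                periodic = np.array([t == "T" for t in
                                     kv.get("pbc", "T T T").split()])
                box = Box(lengths.copy(), periodic)
            times.append(float(kv.get("Time", 0.0)))
            if "Energy" in kv:
                energies.append(float(kv["Energy"]))
            has_forces = "forces" in kv.get("Properties", "")
            pos, frc, spec = [], [], []
            for _ in range(n):
                fields = fh.readline().split()
                spec.append(fields[0])
                pos.append([float(v) for v in fields[1:4]])
                if has_forces:
                    frc.append([float(v) for v in fields[4:7]])
            positions.append(pos)
            if has_forces:
                forces.append(frc)
            species = spec
    return Trajectory(np.array(positions), box, np.array(times),
                      np.array(forces) if forces else None, None,
                      np.array(energies) if energies else None, species)


def write_h5(path, traj: Trajectory):
    """Compact binary container: datasets positions/forces/velocities/box/
    times (+ energies, species)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("positions", data=traj.positions)
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("box/lengths", data=traj.box.lengths)
        fh.create_dataset("box/periodic", data=traj.box.periodic)
        for name in ("forces", "velocities", "energies"):
            arr = getattr(traj, name)
            if arr is not None:
                fh.create_dataset(name, data=arr)
        if traj.species is not None:
            fh.create_dataset("species",
                              data=np.array(traj.species, dtype="S16"))
        if traj.masses is not None:
            fh.create_dataset("masses", data=traj.masses)


def read_h5(path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        box = Box(fh["box/lengths"][...], fh["box/periodic"][...])
        def opt(name):
            return fh[name][...] if name in fh else None
        species = opt("species")
        if species is not None:
            species = [s.decode() for s in species]
        return Trajectory(fh["positions"][...], box, fh["times"][...],
                          opt("forces"), opt("velocities"), opt("energies"),
                          species, opt("masses"))


def write_manifest(path, payload: dict):
    """YAML manifest recording builder/stage name, parameters and seeds."""
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
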