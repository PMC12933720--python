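"""Config-driven orchestration of the benchmark workflow.

Stages: generate (reference trajectory with forces) -> map (COM mapping)
-> fit (force matching) -> simulate (CG MD with the fitted potential)
-> analyze (structural observables / stability) -> metad (well-tempered
metadynamics) -> report. Each stage writes its outputs plus a YAML
manifest (stage name, the config block it consumed, input checksums,
seeds); a stage whose manifest matches the current config is skipped on
rerun, so pipelines are resumable and, with fixed seeds, byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import systems as systems_mod
from .analysis import (bond_swap_analysis, bonded_distributions, helix_fes,
                       helix_series, rdf)
from .mapping import (chain_mapping, identity_mapping, load_mapping,
                      make_mapping, map_trajectory, save_mapping)
from .metad import (CollectiveVariable, reconstruct_fes, run_wtmetad)
from .neuralcg import NeuralCGPotential
from .invariants import DescriptorConfig
from .splinefit import (FMProblem, build_spline_terms, eval_spline_potential,
                        load_termset, save_termset, solve_force_matching)
from .stability import (distance_stability, energy_stability,
                        equilibrium_bond_lengths)
from .state import MDState, maxwell_boltzmann_velocities
from .integrate import integrate_langevin
from .xyzio import read_h5, write_extxyz, write_h5, write_manifest

log = logging.getLogger(__name__)

STAGES = ("generate", "map", "fit", "simulate", "analyze", "metad", "report")

BUILDERS = {
    "chain_liquid": systems_mod.build_chain_liquid,
    "chiral_mimic": systems_mod.build_chiral_mimic,
    "helix_chain": systems_mod.build_helix_chain,
}


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


class StageError(RuntimeError):
    """A stage failed after config validation."""


def _hash_block(block) -> str:
    return hashlib.sha256(
        json.dumps(block, sort_keys=True, default=str).encode()).hexdigest()


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    if "system" not in config:
        raise ConfigError("missing field: system")
    sysblk = config["system"]
    if "builder" not in sysblk:
        raise ConfigError("missing field: system.builder")
    if sysblk["builder"] not in BUILDERS:
        raise ConfigError(f"unknown system.builder: {sysblk['builder']}")
    stages = config.get("stages", ["generate"])
    for st in stages:
        if st not in STAGES:
            raise ConfigError(f"unknown stage: {st}")
    if "map" in stages or "fit" in stages:
        mp = config.get("mapping")
        if mp is None:
            raise ConfigError("missing field: mapping")
        if "file" in mp and not Path(mp["file"]).exists():
            raise ConfigError(f"mapping.file does not exist: {mp['file']}")
        if "file" not in mp and "pattern" not in mp and \
                not mp.get("identity", False):
            raise ConfigError("mapping needs 'pattern', 'file' or 'identity'")
    config.setdefault("seed", 0)
    return config


def _build_system(config):
    blk = config["system"]
    return BUILDERS[blk["builder"]](**blk.get("params", {}))


def _stage_fresh(outdir: Path, name: str, block) -> bool:
    mpath = outdir / f"manifest_{name}.yaml"
    if not mpath.exists():
        return True
    try:
        manifest = yaml.safe_load(mpath.read_text())
    except Exception:
        return True
    return manifest.get("config_hash") != _hash_block(block)


def _finish_stage(outdir: Path, name: str, block, outputs: dict, seed: int):
    checksums = {}
    for key, rel in outputs.items():
        p = outdir / rel
        if p.exists():
            checksums[key] = _file_checksum(p)
    write_manifest(outdir / f"manifest_{name}.yaml", {
        "stage": name, "config_hash": _hash_block(block), "seed": seed,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "checksums": checksums})


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured stages into ``outdir``; returns a summary dict.

    Raises ConfigError for schema problems and StageError when a stage
    fails (partial results are preserved on disk).
    """
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["generate"])
    summary: dict = {"outdir": str(outdir), "stages": {}}

    try:
        system = _build_system(config)
    except ConfigError:
        raise
    except Exception as err:
        raise StageError(f"system build failed: {err}") from err

    for stage in stages:
        fn = _STAGE_FNS[stage]
        block = {"stage_config": config.get(stage if stage != "generate"
                                            else "protocol", {}),
                 "system": config["system"],
                 "mapping": config.get("mapping"), "seed": seed}
        if stage != "report" and not _stage_fresh(outdir, stage, block):
            log.info("stage %s up to date; skipping", stage)
            summary["stages"][stage] = "cached"
            continue
        try:
            result = fn(config, system, outdir, seed)
        except (ConfigError, StageError):
            raise
        except Exception as err:
            raise StageError(f"stage {stage} failed: {err}") from err
        if stage != "report":
            _finish_stage(outdir, stage, block, result.get("outputs", {}),
                          seed)
        summary["stages"][stage] = result.get("summary", "done")
    return summary


# ---------------------------------------------------------------------------
# stage implementations

def _stage_generate(config, system, outdir, seed):
    proto = dict(temperature=300.0, dt=0.002, n_steps=2000, stride=10,
                 friction=5.0)
    proto.update(config.get("protocol", {}))
    traj = systems_mod.generate_reference(system, seed=seed, **proto)
    write_h5(outdir / "reference.h5", traj)
    write_extxyz(outdir / "reference.extxyz", traj)
    return {"outputs": {"h5": "reference.h5", "extxyz": "reference.extxyz"},
            "summary": {"frames": traj.n_frames, "atoms": traj.n_atoms}}


def _get_scheme(config, system, outdir):
    mp = config["mapping"]
    if "file" in mp:
        return load_mapping(mp["file"], system.topology)
    mode = mp.get("species_mode", "element")
    if mp.get("identity"):
        return identity_mapping(system.topology, mode)
    if "pattern" in mp:
        return chain_mapping(system.topology, mp["pattern"], mode)
    return make_mapping(system.topology, mp["atom_sets"], mode)


def _stage_map(config, system, outdir, seed):
    traj = read_h5(outdir / "reference.h5")
    scheme = _get_scheme(config, system, outdir)
    cg = map_trajectory(traj, scheme, system.topology)
    save_mapping(outdir / "mapping.yaml", scheme)
    write_h5(outdir / "cg_reference.h5", cg)
    return {"outputs": {"mapping": "mapping.yaml", "cg": "cg_reference.h5"},
            "summary": {"beads": cg.n_atoms, "species": sorted(set(cg.species))}}


def _load_cg(config, system, outdir):
    cg = read_h5(outdir / "cg_reference.h5")
    scheme = _get_scheme(config, system, outdir)
    from .mapping import CGTrajectory
    top = scheme.cg_topology(system.topology)
    return CGTrajectory(cg.positions, cg.box, cg.times, forces=cg.forces,
                        species=top.species, masses=top.masses,
                        topology=top)


def _stage_fit(config, system, outdir, seed):
    blk = config.get("fit", {})
    cg = _load_cg(config, system, outdir)
    family = blk.get("family", "spline")
    if family == "spline":
        termset = build_spline_terms(cg, **blk.get("spline", {}))
        problem = FMProblem(cg, termset, ridge=blk.get("ridge", 1e-4),
                            val_fraction=blk.get("val_fraction", 0.2),
                            seed=seed)
        termset, chi_tr, chi_val = solve_force_matching(problem)
        save_termset(outdir / "spline_model.npz", termset)
        outputs = {"model": "spline_model.npz"}
    elif family == "neural":
        nb = dict(blk.get("neural", {}))
        train_kwargs = {k: nb.pop(k) for k in
                        ("lr", "n_epochs", "patience") if k in nb}
        nb.setdefault("species", sorted(set(cg.species)))
        nb["hidden"] = tuple(nb.get("hidden", (16,)))
        model = NeuralCGPotential(DescriptorConfig(**nb), seed=seed)
        out = model.train(cg, val_fraction=blk.get("val_fraction", 0.2),
                          seed=seed, **train_kwargs)
        chi_tr, chi_val = out["chi2_train"], out["chi2_val"]
        model.save(outdir / "neural_model.npz")
        outputs = {"model": "neural_model.npz"}
    else:
        raise ConfigError(f"unknown fit.family: {family}")
    fit_info = {"family": family, "chi2_train": float(chi_tr),
                "chi2_val": float(chi_val)}
    (outdir / "fit.yaml").write_text(yaml.safe_dump(fit_info))
    outputs["fit"] = "fit.yaml"
    return {"outputs": outputs, "summary": fit_info}


def _cg_potential(config, system, outdir):
    blk = config.get("fit", {})
    cg = _load_cg(config, system, outdir)
    if blk.get("family", "spline") == "spline":
        termset = load_termset(outdir / "spline_model.npz")

        def potential(positions, box):
            return eval_spline_potential(positions, box, termset,
                                         cg.topology, cg.species)
    else:
        model = NeuralCGPotential.load(outdir / "neural_model.npz")

        def potential(positions, box):
            return model.energy_forces(positions, box, cg.species)
    return potential, cg


def _stage_simulate(config, system, outdir, seed):
    blk = dict(temperature=300.0, dt=0.002, n_steps=2000, stride=10,
               friction=5.0)
    blk.update(config.get("simulate", {}))
    potential, cg = _cg_potential(config, system, outdir)
    rng = np.random.default_rng(seed + 1)
    state = MDState(cg.positions[0].copy(),
                    maxwell_boltzmann_velocities(cg.masses,
                                                 blk["temperature"], rng),
                    cg.masses, cg.box)
    traj = integrate_langevin(state, potential, blk["dt"],
                              blk["temperature"], blk["friction"],
                              blk["n_steps"], seed=seed + 2,
                              stride=blk["stride"], species=cg.species)
    traj.masses = cg.masses
    write_h5(outdir / "cg_run.h5", traj)
    return {"outputs": {"cg_run": "cg_run.h5"},
            "summary": {"frames": traj.n_frames}}


def _stage_analyze(config, system, outdir, seed):
    blk = config.get("analyze", {})
    cg_ref = _load_cg(config, system, outdir)
    results: dict = {}
    target = cg_ref
    if (outdir / "cg_run.h5").exists():
        run = read_h5(outdir / "cg_run.h5")
        from .mapping import CGTrajectory
        target = CGTrajectory(run.positions, run.box, run.times,
                              forces=run.forces, velocities=run.velocities,
                              species=cg_ref.species, masses=cg_ref.masses,
                              topology=cg_ref.topology)
    if "rdf" in blk:
        spec = blk["rdf"]
        hist = rdf(target, spec["species"][0], spec["species"][1],
                   bin_width=spec.get("bin_width", 0.02),
                   topology=target.topology)
        np.savetxt(outdir / "rdf.tsv",
                   np.column_stack([hist.centers, hist.density]),
                   header="r_nm\tg(r)")
        results["rdf_file"] = "rdf.tsv"
    if blk.get("bonded"):
        dists = bonded_distributions(target, target.topology)
        results["bonded_types"] = {k: sorted(map(str, v))
                                   for k, v in ((kind, d.keys())
                                                for kind, d in dists.items())}
    if blk.get("helix"):
        Q, X = helix_series(target)
        _, _, fractions = helix_fes(target)
        results["helicity"] = {"mean_Q": float(Q.mean()),
                               "mean_chi": float(X.mean()),
                               "fractions": fractions}
    if blk.get("bond_swaps"):
        rep = bond_swap_analysis(target, target.topology)
        results["bond_swaps"] = {
            "total": int(rep.swap_counts.sum()),
            "identity_fraction": float(rep.identity_fraction),
            "first_swap_frame": (None if rep.first_swap_frame is None
                                 else int(rep.first_swap_frame))}
    if blk.get("stability"):
        if target.velocities is not None:
            er = energy_stability(target)
            results["energy_stability"] = {
                "stable": bool(er.stable),
                "stable_duration_ps": er.stable_duration}
        eq = equilibrium_bond_lengths(cg_ref, cg_ref.topology)
        dr = distance_stability(target, target.topology, eq)
        results["distance_stability"] = {
            "stable": bool(dr.stable), "stable_duration_ps": dr.stable_duration}
    (outdir / "analysis.yaml").write_text(yaml.safe_dump(results))
    return {"outputs": {"analysis": "analysis.yaml"}, "summary": results}


def _stage_metad(config, system, outdir, seed):
    blk = config.get("metad", {})
    if "cv_quadruple" not in blk:
        raise ConfigError("missing field: metad.cv_quadruple")
    cv = CollectiveVariable(blk.get("cv_kind", "improper_dihedral"),
                            tuple(blk["cv_quadruple"]))
    params = {k: blk[k] for k in ("height", "sigma", "gamma", "stride",
                                  "temperature", "dt", "friction", "n_steps")
              if k in blk}
    traj, history, cv_series = run_wtmetad(system, cv, seed=seed, **params)
    np.savetxt(outdir / "hills.tsv",
               np.column_stack([history.times, history.centers,
                                history.heights]),
               header="time_ps\tcenter_deg\theight_kJmol")
    grid = np.linspace(-180.0, 180.0, 361)
    fes = reconstruct_fes(history, grid)
    np.savetxt(outdir / "metad_fes.tsv", np.column_stack([grid, fes]),
               header="cv_deg\tF_kJmol")
    return {"outputs": {"hills": "hills.tsv", "fes": "metad_fes.tsv"},
            "summary": {"n_gaussians": len(history.centers),
                        "cv_range": [float(cv_series.min()),
                                     float(cv_series.max())]}}


def report(run_dir) -> dict:
    """Collate stage outputs in a run directory into one summary table.

    Missing stages are listed as absent; never raises for missing data.
    """
    run_dir = Path(run_dir)
    out: dict = {"run_dir": str(run_dir), "stages": {}, "absent": []}
    for stage in STAGES[:-1]:
        mpath = run_dir / f"manifest_{stage}.yaml"
        if mpath.exists():
            out["stages"][stage] = yaml.safe_load(mpath.read_text())
        else:
            out["absent"].append(stage)
    for name in ("fit.yaml", "analysis.yaml"):
        p = run_dir / name
        if p.exists():
            out[name.split(".")[0]] = yaml.safe_load(p.read_text())
    if not out["stages"]:
        log.warning("no stage manifests found in %s", run_dir)
    return out


def format_report(summary: dict) -> str:
    lines = [f"run directory: {summary['run_dir']}"]
    for stage, manifest in summary["stages"].items():
        lines.append(f"  [{stage}] outputs: "
                     f"{', '.join(manifest.get('outputs', {}).values()) or '-'}")
    if summary.get("fit"):
        fit = summary["fit"]
        lines.append(f"  force matching ({fit['family']}): "
                     f"chi2 train {fit['chi2_train']:.4g}, "
                     f"val {fit['chi2_val']:.4g}")
    if summary.get("analysis"):
        lines.append("  analysis: " + yaml.safe_dump(
            summary["analysis"], default_flow_style=True).strip())
    if summary["absent"]:
        lines.append("  absent stages: " + ", ".join(summary["absent"]))
    return "\n".join(lines)


_STAGE_FNS = {
    "generate": _stage_generate,
    "map": _stage_map,
    "fit": _stage_fit,
    "simulate": _stage_simulate,
    "analyze": _stage_analyze,
    "metad": _stage_metad,
    "report": lambda config, system, outdir, seed: {
        "summary": format_report(report(outdir))},
}
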