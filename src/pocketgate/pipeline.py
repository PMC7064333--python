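"""Config-driven orchestration of the full analysis.

A single YAML/dict config names the inputs of each stage (trajectories
per system, selections, pocket geometry, landscape/divergence/hydrogen
bond settings, binding datasets).  Stages are independent: one failing
stage is reported in the manifest and does not corrupt the others.  The
manifest records the package version, the seeds, a hash of the config
and every output file, so a run is fully reconstructable.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import ResidueSelection, read_trajectory
from .flexibility import rmsf_profile
from .pocket import (PocketSpec, PocketVolumeSeries, ranksum_test,
                     volume_distance_series)
from .landscape import build_fel, basin_summary
from .divergence import extract_dihedrals, kl_profile
from .hbonds import HBondCriteria, hbond_occupancy, occupancy_table
from .binding import FPDataset, Sensorgram, BLIDataset, fit_fp, fit_bli


class ConfigError(ValueError):
    """Raised with every validation problem enumerated, before any compute."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _parse_residue(text: str) -> tuple[str, int]:
    chain, _, seq = str(text).partition(":")
    return chain, int(seq)


def _validate(config: dict) -> list[str]:
    problems = []
    if "output_dir" not in config:
        problems.append("missing field: output_dir")
    stages = config.get("stages", {})
    if not stages:
        problems.append("missing field: stages")
    for name, stage in stages.items():
        if name in ("rmsf", "pocket", "fel", "hbonds"):
            if "trajectories" not in stage:
                problems.append(f"stage {name}: missing field trajectories")
            else:
                for system, paths in stage["trajectories"].items():
                    for p in paths:
                        if not Path(p).exists():
                            problems.append(f"stage {name}/{system}: "
                                            f"missing file {p}")
        if name in ("pocket", "fel") and "pocket_spec" not in stage:
            problems.append(f"stage {name}: missing field pocket_spec")
        if name in ("pocket", "fel") and "distance_pair" not in stage:
            problems.append(f"stage {name}: missing field distance_pair")
        if name == "kld":
            for side in ("ensemble_a", "ensemble_b"):
                if side not in stage:
                    problems.append(f"stage kld: missing field {side}")
                else:
                    for p in stage[side]:
                        if not Path(p).exists():
                            problems.append(f"stage kld/{side}: missing file {p}")
        if name == "hbonds" and "loop" not in stage:
            problems.append("stage hbonds: missing field loop")
        if name == "binding":
            for kind in ("fp", "bli"):
                p = stage.get(kind)
                if p and not Path(p).exists():
                    problems.append(f"stage binding/{kind}: missing file {p}")
    return problems


def _pocket_spec(block: dict) -> PocketSpec:
    spheres = [(np.asarray(s["center"], float), float(s["radius"]))
               for s in block["inclusion_spheres"]]
    seed = block.get("contiguity_seed")
    return PocketSpec(spheres,
                      grid_spacing=float(block.get("grid_spacing", 1.0)),
                      exclusion_padding=float(block.get("exclusion_padding", 1.09)),
                      contiguity_seed=None if seed is None else np.asarray(seed, float))


def _log(msg: str) -> None:
    print(f"[pocketgate] {msg}", file=sys.stderr)


def _series_for(stage: dict, system: str, paths: list[str]) -> PocketVolumeSeries:
    spec = _pocket_spec(stage["pocket_spec"])
    res_a = _parse_residue(stage["distance_pair"][0])
    res_b = _parse_residue(stage["distance_pair"][1])
    n_frames = stage.get("n_frames")
    series = []
    for p in paths:
        traj = read_trajectory(p)
        series.append(volume_distance_series(traj, spec, res_a, res_b,
                                             n_frames=n_frames))
    return PocketVolumeSeries.concat(series)


def run_pipeline(config: dict | str | Path) -> dict:
    """Run every configured stage; returns (and writes) the manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    problems = _validate(config)
    if problems:
        raise ConfigError("; ".join(problems))

    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest: dict = {
        "package": "pocketgate", "version": __version__,
        "config_hash": config_hash, "seed": config.get("seed", 0),
        "stages": {},
    }
    stages = config["stages"]
    runners = {"rmsf": _run_rmsf, "pocket": _run_pocket, "fel": _run_fel,
               "kld": _run_kld, "hbonds": _run_hbonds, "binding": _run_binding}
    for name, stage in stages.items():
        if name not in runners:
            manifest["stages"][name] = {"status": "unknown-stage"}
            continue
        t0 = time.time()
        _log(f"stage {name} ...")
        try:
            outputs = runners[name](stage, out_dir, config)
            manifest["stages"][name] = {"status": "ok", "outputs": outputs,
                                        "seconds": round(time.time() - t0, 2)}
        except Exception as exc:  # stage independence: report, continue
            _log(f"stage {name} FAILED: {exc}")
            manifest["stages"][name] = {
                "status": "failed", "error": str(exc),
                "traceback": traceback.format_exc().splitlines()[-3:]}
        _log(f"stage {name} done in {time.time() - t0:.1f}s")
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_rmsf(stage: dict, out_dir: Path, config: dict) -> list[str]:
    outputs = []
    fit = stage.get("fit_selection")
    fit_sel = ResidueSelection.parse(fit, "fit") if fit else None
    for system, paths in stage["trajectories"].items():
        trajs = [read_trajectory(p) for p in paths]
        profile = rmsf_profile(trajs, fit_sel)
        path = out_dir / f"rmsf_{system}.csv"
        profile.to_frame().to_csv(path, index=False)
        outputs.append(str(path))
    return outputs


def _run_pocket(stage: dict, out_dir: Path, config: dict) -> list[str]:
    outputs = []
    pooled = {}
    for system, paths in stage["trajectories"].items():
        series = _series_for(stage, system, paths)
        pooled[system] = series
        path = out_dir / f"pocket_series_{system}.csv"
        series.to_frame().to_csv(path, index=False)
        outputs.append(str(path))
    systems = list(pooled)
    if len(systems) >= 2:
        comparisons = {}
        for i in range(len(systems)):
            for j in range(i + 1, len(systems)):
                r = ranksum_test(pooled[systems[i]].volume,
                                 pooled[systems[j]].volume)
                comparisons[f"{systems[i]}_vs_{systems[j]}"] = {
                    "z": r.statistic, "p_value": r.p_value,
                    "n_a": r.n_a, "n_b": r.n_b, "method": r.method}
        path = out_dir / "pocket_ranksum.json"
        path.write_text(json.dumps(comparisons, indent=2))
        outputs.append(str(path))
    return outputs


def _run_fel(stage: dict, out_dir: Path, config: dict) -> list[str]:
    outputs = []
    bins = tuple(stage.get("bins", (32, 32)))
    temperature = float(stage.get("temperature", 310.0))
    for system, paths in stage["trajectories"].items():
        series = _series_for(stage, system, paths)
        fel = build_fel(series, n_bins=bins, temperature=temperature)
        mean_v, mean_d = basin_summary(fel, series)
        payload = fel.to_dict()
        payload["basin_mean_volume_A3"] = mean_v
        payload["basin_mean_distance_A"] = mean_d
        path = out_dir / f"fel_{system}.json"
        path.write_text(json.dumps(payload, indent=2))
        outputs.append(str(path))
    return outputs


def _run_kld(stage: dict, out_dir: Path, config: dict) -> list[str]:
    fpb = int(stage.get("frames_per_block", 5000))
    nb = int(stage.get("n_blocks", 4))
    ens = []
    for side in ("ensemble_a", "ensemble_b"):
        trajs = [read_trajectory(p) for p in stage[side]]
        # concatenate replicate runs along the frame axis; each run is
        # blocked separately so blocks never straddle runs
        blocks = []
        offset = 0
        frames = []
        for t in trajs:
            edges = np.linspace(0, t.n_frames, nb + 1).astype(int)
            blocks.extend([(offset + edges[i], offset + edges[i + 1])
                           for i in range(nb)])
            frames.append(t.frames)
            offset += t.n_frames
        from .io import Trajectory
        merged = Trajectory(trajs[0].topology, np.concatenate(frames),
                            run_id="pooled")
        ens.append(extract_dihedrals(merged, fpb, block_bounds=blocks))
    profile = kl_profile(ens[0], ens[1],
                         n_bootstrap=int(stage.get("bootstrap", 100)),
                         seed=int(stage.get("seed", config.get("seed", 0))),
                         n_bins=int(stage.get("bins", 30)))
    path = out_dir / "kld.csv"
    profile.to_frame().to_csv(path, index=False)
    return [str(path)]


def _run_hbonds(stage: dict, out_dir: Path, config: dict) -> list[str]:
    outputs = []
    loop = ResidueSelection.parse(stage["loop"], "loop")
    criteria = HBondCriteria(
        da_distance_max=float(stage.get("distance_max", 3.5)),
        dha_angle_min=float(stage.get("angle_min", 120.0)))
    kw = {}
    if "min_frames" in stage:
        kw = {"min_frames": int(stage["min_frames"]), "min_fraction": None}
    else:
        kw = {"min_fraction": float(stage.get("min_fraction", 0.1))}
    for system, paths in stage["trajectories"].items():
        trajs = [read_trajectory(p) for p in paths]
        records = hbond_occupancy(trajs, loop, criteria, **kw)
        path = out_dir / f"hbonds_{system}.csv"
        occupancy_table(records).to_csv(path, index=False)
        outputs.append(str(path))
    return outputs


def _run_binding(stage: dict, out_dir: Path, config: dict) -> list[str]:
    outputs = []
    if stage.get("fp"):
        df = pd.read_csv(stage["fp"])
        data = [FPDataset(g["concentration_M"].to_numpy(),
                          g["mP"].to_numpy(), replicate_id=str(rep))
                for rep, g in df.groupby("replicate")]
        fit = fit_fp(data)
        path = out_dir / "fp_fit.json"
        path.write_text(json.dumps({
            "Kd_M": fit.Kd, "Bmax_mP": fit.Bmax, "ns_slope": fit.ns_slope,
            "background_mP": fit.background, "r_squared": fit.r_squared,
            "stderr": fit.stderr}, indent=2))
        outputs.append(str(path))
    if stage.get("bli"):
        df = pd.read_csv(stage["bli"])
        sgs = [Sensorgram(float(c), g["time_s"].to_numpy(),
                          g["response_nm"].to_numpy())
               for c, g in df.groupby("concentration_M")]
        assoc = df[df["phase"] == "association"]["time_s"]
        dissoc = df[df["phase"] == "dissociation"]["time_s"]
        data = BLIDataset(sgs, (float(assoc.min()), float(dissoc.min())),
                          (float(dissoc.min()), float(dissoc.max())))
        fit = fit_bli(data)
        path = out_dir / "bli_fit.json"
        path.write_text(json.dumps({
            "kon_per_M_s": fit.kon, "koff_per_s": fit.koff, "Rmax_nm": fit.Rmax,
            "Kd_M": fit.Kd, "chi_squared": fit.chi_squared,
            "r_squared": fit.r_squared,
            "kobs_per_s": {str(k): v for k, v in fit.kobs.items()},
            "stderr": fit.stderr}, indent=2))
        outputs.append(str(path))
    return outputs
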