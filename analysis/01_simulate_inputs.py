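"""Generate the synthetic study inputs with known ground truth.

Two gated-cavity systems mirror the biological contrast under study:
a *flexible-gate* system (high gate jitter, mostly closed — the CRY1-like
condition: mobile serine loop, smaller secondary pocket) and a
*rigid-gate* system (low jitter, mostly open — CRY2-like: ordered loop,
larger pocket).  Three replicate runs of 501 frames are produced per
system, plus FP and BLI binding datasets drawn from the exact model
equations.

Large multi-model PDB ensembles go to scratch/ (regenerable); small
summary tables go to results/.
"""

import json
import sys
from pathlib import Path

import pocketgate as pg

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "ensembles"
RESULTS = ROOT / "results"

SYSTEMS = {
    # label: (open_fraction, stiffness_open, stiffness_closed)
    "flexible_gate": (0.2, 1.2, 1.2),   # CRY1-like: mobile, mostly closed
    "rigid_gate": (0.8, 0.3, 0.3),      # CRY2-like: ordered, mostly open
}
N_FRAMES = 501
N_REPLICATES = 3
BASE_SEED = 1000


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    manifest = {"systems": {}, "n_frames": N_FRAMES,
                "n_replicates": N_REPLICATES}
    for si, (label, (open_frac, sd_open, sd_closed)) in enumerate(SYSTEMS.items()):
        paths = []
        for rep in range(N_REPLICATES):
            params = pg.GateModelParams(
                seed=BASE_SEED + 10 * si + rep, n_frames=N_FRAMES,
                open_fraction=open_frac, gate_stiffness_open=sd_open,
                gate_stiffness_closed=sd_closed)
            traj, truth = pg.generate_gate_trajectory(params)
            pdb = SCRATCH / f"{label}_run{rep + 1}.pdb"
            pg.write_trajectory(traj, pdb)
            truth.to_csv(SCRATCH / f"{label}_run{rep + 1}_truth.csv",
                         index=False)
            paths.append(str(pdb))
            print(f"{label} run{rep + 1}: {traj.n_frames} frames, "
                  f"{(truth.state == 'open').mean():.2f} open", file=sys.stderr)
        params = pg.GateModelParams(open_fraction=open_frac)
        manifest["systems"][label] = {
            "trajectories": paths,
            "open_fraction": open_frac,
            "distance_pair": [f"{c}:{r}" for c, r in params.distance_pair],
            "cavity_radius_A": params.cavity_radius,
            "gate_residues": [f"{c}:{r}" for c, r in params.gate_keys],
        }

    fp, fp_truth = pg.generate_fp_data(noise_sd=2.0, seed=BASE_SEED + 50)
    fp.to_frame().to_csv(SCRATCH / "fp.csv", index=False)
    bli, bli_truth = pg.generate_bli_data(noise_frac=0.01, seed=BASE_SEED + 51)
    bli.to_frame().to_csv(SCRATCH / "bli.csv", index=False)
    manifest["binding"] = {"fp": str(SCRATCH / "fp.csv"),
                           "fp_truth": fp_truth,
                           "bli": str(SCRATCH / "bli.csv"),
                           "bli_truth": bli_truth}
    (RESULTS / "simulation_manifest.json").write_text(
        json.dumps(manifest, indent=2))
    print(f"wrote {RESULTS / 'simulation_manifest.json'}")


if __name__ == "__main__":
    main()
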