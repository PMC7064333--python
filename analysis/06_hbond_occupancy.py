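"""Hydrogen-bond occupancy around the gate residues.

Detects donor-acceptor contacts frame by frame (3.5 A / 120 deg
criteria, heavy-atom fallback) and keeps bonds that touch the gate
selection with occupancy above 10% in any replicate — the loop-contact
filter used to characterise what stabilises an ordered versus a mobile
gate.
"""

import json
from pathlib import Path

import pocketgate as pg

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    manifest = json.loads((RESULTS / "simulation_manifest.json").read_text())
    for label, info in manifest["systems"].items():
        trajs = [pg.read_trajectory(p) for p in info["trajectories"]]
        gate = pg.ResidueSelection(
            "gate", [tuple([c, int(r)]) for c, r in
                     (g.split(":") for g in info["gate_residues"])])
        records = pg.hbond_occupancy(trajs, gate, min_fraction=0.1)
        out = RESULTS / f"hbonds_{label}.csv"
        pg.occupancy_table(records).to_csv(out, index=False)
        print(f"{label}: {len(records)} gate contacts above 10% occupancy "
              f"-> {out.name}")


if __name__ == "__main__":
    main()
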