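"""Crystal-structure comparisons of the CRY PHR domains.

Computes, from locally supplied PDB entries, the four structure-pair
quantities of interest:

* Calpha RMSD between the CRY1 PHR (5T5X) and CRY2 PHR (4I6E) domains
  over sequence-aligned, mutually resolved residues;
* Calpha RMSD of PER2 CBD residues 1136-1207 between the two
  CRY1 PHR:PER2 CBD complexes (6OF7 vs 4CT0);
* CRY1/CRY2 global-alignment sequence identity;
* serine-loop remodeling displacements between apo CRY2 (4I6E) and the
  PER2-bound complex (4U8H): S64 side-chain centroid and A61 Calpha,
  after superposing on all mutually resolved Calpha outside the loop
  (I54-I67).

The deposited entries are not redistributed here; download 5T5X, 4I6E,
4CT0, 4U8H and 6OF7 from a PDB mirror into data/reference/ first.
"""

import json
import sys
from pathlib import Path

import pocketgate as pg

ROOT = Path(__file__).resolve().parent.parent
REFERENCE = ROOT / "data" / "reference"
RESULTS = ROOT / "results"

ENTRIES = ["5T5X", "4I6E", "4CT0", "4U8H", "6OF7"]


def main() -> None:
    missing = [e for e in ENTRIES if not (REFERENCE / f"{e}.pdb").exists()]
    if missing:
        print(f"missing reference coordinates under {REFERENCE}: "
              f"{', '.join(missing)}.\nDownload the entries from a PDB "
              f"mirror (e.g. files.rcsb.org) and re-run.", file=sys.stderr)
        sys.exit(1)

    st = {e: pg.read_structure(REFERENCE / f"{e}.pdb") for e in ENTRIES}
    out = {}

    out["cry1_cry2_ca_rmsd_A"] = pg.ca_rmsd(st["5T5X"], st["4I6E"])

    per2_res = list(range(1136, 1208))
    chain = {}
    for e in ("6OF7", "4CT0"):
        for c, r, _ in st[e].residues():
            if r in per2_res:
                chain[e] = c
                break
    out["per2_cbd_ca_rmsd_A"] = pg.ca_rmsd(
        st["6OF7"], st["4CT0"], residues=per2_res,
        chain_a=chain["6OF7"], chain_b=chain["4CT0"])

    seq1, _ = st["5T5X"].chain_sequence(st["5T5X"].atoms[0].chain_id)
    seq2, _ = st["4I6E"].chain_sequence(st["4I6E"].atoms[0].chain_id)
    out["cry1_cry2_identity_pct"] = pg.align_sequences(seq1, seq2).percent_identity

    apo, bound = st["4I6E"], st["4U8H"]
    loop = pg.ResidueSelection.from_range("serine_loop",
                                          apo.atoms[0].chain_id, 54, 67)
    pairs = pg.ca_pairs_by_alignment(apo, bound, exclude_a=loop)
    c = apo.atoms[0].chain_id
    out["s64_displacement_A"] = pg.residue_displacement(
        apo, bound, pairs, (c, 64), rule="sidechain_centroid")
    out["a61_displacement_A"] = pg.residue_displacement(
        apo, bound, pairs, (c, 61), rule="ca")

    RESULTS.mkdir(parents=True, exist_ok=True)
    (RESULTS / "structure_comparisons.json").write_text(
        json.dumps(out, indent=2))
    for k, v in out.items():
        print(f"{k}: {v:.2f}")


if __name__ == "__main__":
    main()
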