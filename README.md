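# pocketgate

Conformational-ensemble comparison and binding analysis for loop-gated
protein pockets.

## The problem

Cryptochromes CRY1 and CRY2 repress the circadian transcription factor
CLOCK:BMAL1, and how tightly they bind its PAS-domain core is set by a
flexible, serine-rich loop that gates access to the *secondary pocket*
on the photolyase-homology (PHR) domain: a mobile loop correlates with a
smaller, more closable pocket and tighter CLOCK:BMAL1 binding, while an
ordered loop leaves a larger, open pocket and weaker binding.  Testing
that mechanism requires a chain of analyses over conformational
ensembles and binding data, and this package implements that chain as a
tested, reusable library:

* **Structure comparison** — Kabsch superposition, Cα RMSD with
  sequence-alignment pairing (BLOSUM62, affine gaps 11/1), per-residue
  displacement after core superposition;
* **Flexibility** — per-residue Cα RMSF per replicate trajectory,
  aggregated to a mean/min/max envelope,
  RMSF_i = √⟨|r_i(t) − ⟨r_i⟩|²⟩ after two-pass superposition on a
  time-average reference;
* **Pocket volumetrics** — grid-based pocket volume (inclusion spheres,
  van der Waals exclusion with 1.09 Å padding, optional 6-connected
  contiguity), the gate distance between two residue centers of mass,
  and the two-sided Wilcoxon rank-sum comparison of volume
  distributions;
* **Free-energy landscape** — F(V, d) = −ln(n/n_max) in k_BT over the
  (volume, distance) histogram, with minimum-basin frame extraction;
* **Torsion divergence** — per-residue Kullback-Leibler divergence
  D(P‖Q) = Σ p ln(p/q) of φ/ψ/χ1 distributions between two ensembles
  (30-bin circular histograms, add-½ pseudocounts), with block-bootstrap
  significance thresholds;
* **Hydrogen bonds** — geometric detection (donor–acceptor ≤ 3.5 Å,
  D–H⋯A ≥ 120° when hydrogens exist) and loop-contact occupancy
  filtering;
* **Binding fits** — equilibrium fluorescence polarization
  (mP = B_max·X/(K_d+X) + ns·X + bg) and global 1:1 bio-layer
  interferometry kinetics (R(t) = R_eq(1−e^(−k_obs t)),
  R_eq = R_max·C/(C+K_d), k_obs = k_on·C + k_off, K_d ≡ k_off/k_on).

Every stage is validated end-to-end on synthetic ensembles with known
ground truth from the built-in generators (a geometric gated-cavity
model, von Mises torsion ensembles, and forward-model binding data).

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
two-system data (a flexible, mostly-closed gate versus a rigid,
mostly-open gate — three replicates of 501 frames each):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_flexibility_profiles.py
python analysis/03_pocket_volumetrics.py
python analysis/04_free_energy_landscape.py
python analysis/05_torsion_divergence.py
python analysis/06_hbond_occupancy.py
python analysis/07_binding_fits.py
```

Output from this run (tables under `results/`):

```
flexible_gate: volume 1211 +/- 154 A^3, corr(V, d) = 0.88 over 753 frames
rigid_gate:    volume 1431 +/- 139 A^3, corr(V, d) = 0.99 over 753 frames
rank-sum flexible_gate vs rigid_gate: z = -22.1, p = 4.97e-108
flexible_gate: minimum basin at V = 1147 A^3, d = 13.1 A (17 frames)
rigid_gate:    minimum basin at V = 1504 A^3, d = 18.8 A (81 frames)
calibration: shifted residues [4, 5, 6, 7], flagged [4, 5, 6, 7]
FP:  Kd = 0.99 uM (truth 1.00 uM), Bmax = 149 mP, R^2 = 0.9996
BLI: kon = 1e+05 /M/s, koff = 0.00649 /s, Kd = 64.7 nM (truth 65.0 nM)
```

Reading the numbers: the rigid-gate system samples a significantly
larger pocket volume (rank-sum p ≪ 0.001), volume and gate distance
rise together, and the flexible system's free-energy minimum sits at
smaller volume and shorter distance — the statistical signature the
serine-loop mechanism predicts.  The divergence analysis flags exactly
the four residues whose χ1 distributions were shifted by construction,
and the binding fits recover the generating K_d within a few percent.

`analysis/08_structure_comparisons.py` additionally computes the
crystal-structure quantities (CRY1/CRY2 Cα RMSD and sequence identity,
PER2-CBD RMSD between complexes, serine-loop S64/A61 displacements)
when the PDB entries 5T5X, 4I6E, 4CT0, 4U8H and 6OF7 are placed under
`data/reference/` (they are not redistributed here).

A `pocketgate` console command exposes each stage
(`pocketgate rmsd`, `rmsf`, `pocket`, `fel`, `kld`, `hbonds`,
`fit-fp`, `fit-bli`, `simulate`, `run --config analysis.yaml`).

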