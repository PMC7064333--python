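# Methods

This note documents the models, estimators and defaults behind each
analysis stage, the design choices made where several reasonable options
existed, and what the synthetic generators do and do not emulate.

## Coordinates, structures, trajectories

All coordinates are in Ångström and residues are addressed by author
numbering (chain, residue_seq), because that is how pocket-lining and
loop residues are named in the structural literature.  PDB reading and
writing goes through gemmi; alternate locations collapse to the
highest-occupancy conformer (first listed on ties) and hydrogens are
optional everywhere — crystal structures rarely have them, so every
downstream stage must work heavy-atom-only.  Element masses and van der
Waals radii come from a fixed internal table (Bondi radii; see
`src/pocketgate/elements.py`) so that grid volumes are bit-reproducible
across library versions.

Frame subsampling takes `n` equally spaced frames including the first
(round-of-linspace indices: 251 frames from a 501-frame run are indices
0, 2, …, 500) or a fixed stride.  Because the saving interval of a
production run is generally not knowable from the stored frames, the
`frame_interval` field is optional metadata and occupancy-style
thresholds are exposed both as absolute frame counts and as fractions.

## Structure comparison

Superposition is the closed-form least-squares rigid transform (Kabsch,
via SVD with a determinant correction); degenerate (collinear or
coincident) point sets are rejected by a singular-value check.  The
implementation is verified in the test suite against a brute-force
oracle that scans rotations parameterized by quaternions.

Cross-protein Cα pairing uses a global sequence alignment
(BLOSUM62, gap open 11, extend 1 — the standard protein-alignment
parameterization) restricted to columns where both residues have a
resolved Cα.  Percent identity is computed over aligned non-gap
columns; sequence-similarity ("homology") percentages depend on an
arbitrary similarity threshold and are not computed.

Residue displacement between two conformations superposes on all
mutually resolved core Cα — excluding the mobile loop itself, so loop
motion is measured against the fixed domain core — and reports the
Euclidean distance between the probe residue's reference point.  The
default reference is the side-chain heavy-atom centroid (appropriate
for serine), with a Cα rule for glycine/alanine and a mass-weighted
center-of-mass rule also available; the choice matters at the ~1 Å
level and is always stated in output.

## RMSF

Each frame is superposed (Cα of a configurable fit selection; default
all Cα) onto a time-average reference obtained by one fit-to-frame-0
pass followed by re-averaging; RMSF is then the root-mean-square
deviation of each Cα about its mean position.  The two-pass reference
removes the arbitrariness of a single-frame reference at negligible
cost.  Replicate runs are aggregated element-wise to mean/min/max so a
profile carries its between-replicate envelope.

## Pocket volume and gate distance

The volume algorithm is the standard inclusion-sphere grid recipe: a
cubic lattice (default spacing 1.0 Å) anchored at the first
inclusion-sphere center covers the union of inclusion spheres; lattice
points within vdW radius + padding (default 1.09 Å, the hydrogen
radius) of any protein heavy atom are deleted; when a contiguity seed
is set, only points 6-connected to the seed's nearest surviving point
are kept, and a seed with no surviving point within one grid diagonal
signals a closed pocket (volume 0).  Volume is point count × spacing³.
Anchoring the grid to the sphere center makes the estimate exactly
invariant under joint translation of protein and spheres; rotational
invariance holds only to grid error, as for any axis-aligned lattice.
At 0.5 Å spacing the empty-sphere error against the analytic volume is
≈0.5%, comfortably within the 5% the pipeline assumes.

The gate distance is the Euclidean distance between mass-weighted
heavy-atom centers of mass of two residues on opposite sides of the
pocket mouth.  For real CRY structures, the inclusion region is a
deliberate configuration choice (a 10 Å sphere at the midpoint of the
serine loop and the F105/F123 Cα is a reasonable default); it is
surfaced in config rather than hard-coded because published
trajectory-mean volumes depend strongly on it.

Volume distributions are compared with the two-sided Wilcoxon rank-sum
(Mann-Whitney) test: exact enumeration for small untied samples
(n_a + n_b ≤ 12, via scipy), otherwise the normal approximation with
mid-rank ties, tie-corrected variance and the continuity correction.
The continuity correction is load-bearing: without it the asymptotic
two-sided p deviates from exhaustive enumeration by up to ~0.12 at
n = 8 per group; with it the deviation stays below ~0.01.

## Free-energy landscape

F_ij = −ln(n_ij / n_max) in k_BT units over a 2D histogram of
(volume, distance); the most populated bin defines F = 0 and the
minimum basin, whose member frames are collected for coordinate
averaging.  Only count *ratios* matter, so uniform count scaling leaves
F unchanged (additive count shifts do not — they change ratios).  Empty
bins are reported as unsampled (NaN plus a mask) rather than +∞ so that
summaries over the surface stay well-defined.  Defaults: 32×32 bins
over the observed data range; temperature 310 K is stored for optional
conversion to kJ/mol but cancels in k_BT units.  Ties in the modal bin
break toward the lexicographically lowest bin index, and this is
deterministic and documented.

A caution on basin localisation: with n = 10⁴ points on a 25×25 grid,
adjacent central bins of a smooth unimodal density differ in expected
count by far less than their Poisson noise, so the single modal bin
identifies the true mode only to within ±1–2 bins.  Basin summaries
should therefore be read at bin-width resolution, not as exact mode
coordinates.

## Torsion KL divergence

Dihedrals use the standard projected-vector formula with the IUPAC sign
convention; φ = C(i−1)–N–Cα–C, ψ = N–Cα–C–N(i+1), χ1 = N–Cα–Cβ–X with
the fourth atom from a per-residue-type table (Gly/Ala carry no χ1).
Residues missing backbone atoms are skipped.  Trajectories are divided
into blocks (default 4 per run; blocks never straddle replicate runs)
with a fixed number of equally spaced frames per block (default 5000,
configurable for desk-scale data).

The divergence estimator is a transparent histogram KL: 30 equal-width
bins over (−180°, 180°], add-½ pseudocounts in both histograms,
D = Σ p ln(p/q) in nats, summed over the torsion kinds a residue
possesses.  Against numerical quadrature of binned von Mises densities
the estimator is accurate to well under 5% at 10⁵ samples; its
self-divergence floor from the pseudocounts is below 2×10⁻³ nats.  The
reported direction is D(first ensemble ‖ second); the reverse direction
is included in output for symmetry diagnostics.

Significance uses a block bootstrap under the null of no difference:
blocks of the *first* ensemble are resampled with replacement, split
into two half-size pseudo-ensembles, and the per-residue divergence
recomputed; the threshold is the maximum over n_bootstrap (default 100)
replicates, giving a per-residue false-positive probability of about
1/(n_bootstrap+1) under exchangeability.  A residue is flagged when its
observed divergence exceeds its threshold.  At the default study scale
(60° χ1 shift, κ = 8, 4 blocks × 5000 frames) detection power is
effectively 1 and matched null comparisons flag nothing.

## Hydrogen bonds

Donors and acceptors come from a fixed per-residue-type table of polar
atoms (backbone N except proline as donor, backbone O/OXT as acceptor,
plus the usual side-chain N/O/S atoms).  A bond is counted when the
donor-heavy-atom–acceptor distance is ≤ 3.5 Å and, when an explicit
hydrogen is attached to the donor (≤ 1.25 Å), some D–H⋯A angle is
≥ 120°; without hydrogens the distance criterion alone applies
(heavy-atom fallback, on by default).  These are the conventional
geometric thresholds; tightening either criterion can only reduce
counts.  Occupancy filtering keeps bonds touching at least one residue
of the loop selection with a count above threshold in at least one
replicate; the threshold is an absolute frame count or a fraction
(default 0.1) because the saved-frame total of a run is not always
meaningful across datasets.

## Binding models

FP dose-response: mP(X) = B_max·X/(K_d+X) + ns·X + background (one-site
specific plus linear nonspecific and constant background), fitted by
nonlinear least squares with replicates averaged per concentration and
standard errors from the Jacobian at the optimum.

BLI kinetics: the 1:1 Langmuir model with association
R(t) = R_eq(1−e^(−k_obs t)), R_eq = R_max·C/(C+K_d),
k_obs = k_on·C+k_off, and dissociation decaying from the
association-end response with rate k_off.  One (k_on, k_off, R_max)
triple is fitted *globally* across all concentrations and both phases;
per-curve k_obs and R_eq are derived, and K_d = k_off/k_on holds as an
identity of the parameterization.  Bounds k_on ∈ [10², 10⁸] /M/s and
k_off ∈ [10⁻⁶, 1] /s are wide and prevent sign flips.  Sensorgram
alignment (subtract the mean of the last 5 s of baseline; offset the
dissociation start to the association end) is a documented stand-in for
instrument-specific interstep correction.  Goodness of fit is reported
as χ² (residual sum of squares) and R².

Under the study conditions (12-point 2-fold FP titration from 50×K_d
with 2 mP noise; 8 BLI concentrations 2-fold from 10×K_d, 300 s + 300 s
phases, 1% R_max noise) the median relative K_d error over 50 noise
realisations is a few percent for FP and well under 1% for BLI;
noiseless data are recovered to optimizer tolerance.

## Synthetic generators

The gate model is geometric, not physical: pseudo-residues (5 atoms
with standard names N/CA/C/O/CB, serine-like composition) form a
spherical cage (default 40 residues, cavity radius 8 Å, walls at
+2 Å) with a 45° mouth cone; gate residues (default 4) sit across the
mouth in closed frames and retract beyond the cage in open frames,
with per-frame i.i.d. open/closed states (default open fraction 0.5)
and Gaussian positional jitter (default 1.2 Å open / 0.4 Å closed
fluctuation scale; scaffold 0.15 Å).  This reproduces the statistical
structure the analyses assume — gate flexibility ↔ aperture distance ↔
pocket volume, with positive (V, d) coupling — in milliseconds per
trajectory.  It does *not* emulate bonded geometry, realistic
Ramachandran statistics, solvent, or autocorrelated dynamics, so
passing tests demonstrate correctness of the estimators and of the
statistical reasoning, not force-field realism; block structure in the
divergence analysis is honored by construction rather than by slow
decorrelation.

Torsion ensembles are von Mises mixtures sampled per residue and
torsion kind with a known shifted-residue set in the second ensemble
(default shift 60° on χ1 at κ = 8).  Binding data come from the exact
fitted-model equations plus Gaussian noise.  Every generator is
deterministic under its seed and emits its ground-truth table; tests
read truth only from those tables.

Default study sizes (3 replicates × 501 frames, 251 analysis frames per
run, 4 blocks × 5000 torsion frames, 50 recovery seeds) were chosen as
the smallest sizes at which the statistical claims under test are
comfortably resolved, and run in seconds to a few minutes on one core.

## Pipeline

`run_pipeline` validates its config fully (enumerating every problem)
before any computation, runs each configured stage independently — a
failing stage is recorded with its error and does not disturb the
others — and writes a manifest with the package version, seeds, config
hash and every output path, which is sufficient to reconstruct the run.
Logging goes to stderr; all numbers go to CSV/JSON files.

## Known limitations

* The grid-volume estimate is lattice-orientation dependent at the
  1–3% level; published pocket volumes additionally depend on the
  (rarely published) inclusion region, so cross-study volume
  comparisons should be made with the same PocketSpec.
* The KL estimator's histogram binning (12° bins) limits sensitivity
  to sub-bin distributional shifts; the bootstrap null assumes blocks
  are exchangeable, i.e. long-lived conformational drift within one
  ensemble inflates the null rather than the false-positive rate.
* The BLI model assumes a single 1:1 binding mode with no mass
  transport limitation, analyte depletion or baseline drift.
* Sequence-alignment Cα pairing can differ from a structure-based
  pairing in insertion/deletion regions; RMSD values on low-identity
  pairs inherit that pairing choice.
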