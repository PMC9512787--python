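# Methods

`augmintools` re-implements, as a reusable tested pipeline, the integrative
computational workflow used to establish the architecture of the augmin
(HAUS1–8) complex: comparative analysis of predicted model ensembles,
crosslinking-MS validation of atomic models, rigid-body fitting into
(simulated) EM densities, composite-model assembly, and quantification of the
hinge motion between the complex's two clamp conformations. This note
describes the models and conventions the package implements, the choices made
where the design was genuinely open, and what the synthetic test system does
and does not demonstrate.

## Coordinate model and selections

Structures are hierarchical atom lists (models → chains → residues → atoms)
addressed exclusively by **author residue numbering** with insertion codes —
the numbering used in deposition records and in all published selection
ranges. No renumbering happens on read. Alternate locations collapse to the
highest-occupancy conformer (first encountered on a tie). mmCIF is read-only;
output is PDB, which every downstream consumer accepts.

Selections are lists of inclusive residue ranges per *subunit name*
(HAUS2, S1, …); a **chain map** translates subunit names to chain ids,
many-to-one allowed. The fixed selections of the analysis (N-clamp, C-clamp,
H3/H5-arm anchor, rigid N-clamp body, hinge deletions, HAUS6 398–478
removal) ship as `data/reference_selections.yaml` together with the
validation constants.

## Superposition and flexibility

All superpositions are least-squares rigid fits (Kabsch, SVD with determinant
correction, so reflections are never returned) over **Cα atoms**. At the
resolutions involved (≥ 7 Å densities, coiled-coil models) the Cα trace
carries the entire signal; all-atom superposition is available through the
selection's atom filter.

Ensemble analysis aligns every member onto a reference model (default index
0, the highest-confidence prediction) over a core selection and then profiles
per-residue Cα deviation in two modes:

- `extreme_pair` — deviation between the two most distinct conformations,
  found exhaustively over all pairs by global Cα RMSD (deterministic
  lexicographic tie-break). This matches the convention of colouring a
  reference model against the maximally deviating one on a 0–10 Å scale.
- `ensemble_rmsd` — root-mean-square deviation from the per-residue ensemble
  mean.

Residues missing from any member are dropped from the profile and reported,
never silently.

## Hinge / domain-rotation measurement

`rotation_between` superposes two conformations on a reference selection,
then takes the Kabsch rotation over the mobile selection and reports its
axis–angle form: angle in [0, 180]°, right-handed unit axis. The returned
rotation maps the second structure's mobile domain onto the first's.
"Opening" versus "closing" is carried by the axis direction, not by a signed
angle. With an empty reference and `center_mode="centroid"`, the mobile
domains are compared about their centroids (translation discarded) — the
convention for measuring the ~180° relative rotation of the two
calponin-homology (CH) domains.

Axis and angle are extracted from the rotation matrix via quaternions
(`scipy.spatial.transform.Rotation`) rather than `arccos((tr−1)/2)`: the two
are mathematically identical, but the arccos form is ill-conditioned near
180° (an 1e-16 trace perturbation moves the angle by ~1e-6 degrees), and the
pipeline asserts micro-degree recovery at that boundary.

## Crosslink validation

The pipeline starts from an exported residue-pair table (TSV/CSV with
protein1/res1/protein2/res2/score columns; duplicates permitted). Processing
follows the published protocol exactly:

1. **Dedup** — one record per unordered residue pair, keeping the copy with
   the maximal aggregate score (sum of −ln(E) spectrum scores); ties keep the
   first occurrence in file order.
2. **Filter** — strictly greater than 250 aggregate score.
3. **Map** — Euclidean Cα–Cα distance on the target model; when a subunit
   maps to several chains the minimum over chain combinations is used; links
   with an unmodelled endpoint are flagged `unmapped`.
4. **Validate** — satisfied ⇔ distance ≤ 30 Å (inclusive; BS3 convention).
   Unmapped links are excluded from the percentage denominator and reported
   separately. Percentages are reported rounded to integers; full precision
   stays in the JSON. Exported scores are divided by 10 for downstream
   visualisation tools.

The per-subunit-pair count table puts each link once on its unordered pair
(intra links on the diagonal), so the sum over unordered pairs equals the
total link count; per-subunit endpoint counts are row sum + diagonal. (A
convention where the diagonal double-counts would instead make row sums equal
endpoint counts — the two properties cannot hold simultaneously.)

**Violation–flexibility association.** The published observation that
violated crosslinks concentrate in flexible segments is qualitative; the
package formalises it as: a residue is *flexible* when its profile value
exceeds the 0.8-quantile of the profile; the statistic is the fraction of
violated links touching ≥ 1 flexible residue; the null permutes
satisfied/violated labels over mapped links with fixed counts;
p = (1 + #{null ≥ observed}) / (1 + n_perm). Reports flag this as an
artifact-defined formalisation.

## Density simulation and rigid fitting

Simulated maps are sums of per-atom isotropic Gaussians with
σ = resolution × `sigma_factor`, amplitude ∝ atomic number (uniform carbon
for Cα-only models), truncated at 4.5 σ (< 0.1% mass loss). The default
`sigma_factor = 1/(π·√2) ≈ 0.225` matches the convention of the interactive
visualisation tool used for the published map simulations, so
cross-correlations are comparable. Defaults: voxel = resolution/3, padding =
2 × resolution. Grids are isotropic with a world-space origin; MRC/CCP4 I/O
goes through gemmi with axis order normalised to X, Y, Z on read, and an
explicit voxel-size override for recalibrated pixel sizes.

Cross-correlation is Pearson (about the mean, hence invariant to affine
intensity rescaling) over a masked voxel set: either the geometric overlap
region or voxels where the simulated map exceeds a contour (default 1% of
its maximum, avoiding empty-box dilution).

The published rigid docking was interactive and is not reproducible; the
package substitutes a deterministic search: an exhaustive axis-angle grid
(Fibonacci-sphere axes at the requested step, optionally bounded in rotation
magnitude) crossed with a translation grid around the density-centroid
alignment, scored by true CC, followed by greedy coordinate descent
(rotation steps halving 4° → 0.2°, translation steps 1 → 0.05 voxel). The
identity placement is always a candidate, so the reported CC never falls
below it. On self-simulated maps the search recovers identity within a
fraction of a voxel and a degree.

`coverage` reports the fraction of Cα atoms inside density at a contour plus
per-residue flags, for cross-referencing unexplained model segments with the
flexibility profile.

## Composite-model assembly

`splice_composite` merges complementary residue ranges from several source
models, each rigidly placed by an optional transform, enforcing pairwise
disjointness of spliced residues (violations are errors naming the
residues), then applies deletions (deleting a never-spliced residue only
warns). Atom count is conserved: |output| = Σ|splices| − |deletions applied|.
This reproduces the published recipe: the arm + TII model contributes
HAUS3 198–364 and HAUS5 275–419, the TIII model the remainder; the N-clamp
body is docked rigidly; hinge residues and the HAUS6 disordered tail are
deleted.

## Sequence identity

Global pairwise identity uses BLOSUM62 with affine gaps (open 10, extend 1,
biopython convention: a length-k gap costs open + (k−1)·extend). Terminal
gaps are free and excluded from the denominator, since the quantity of
interest is identity over the aligned domain cores. The published 10–20%
CH-domain identity range is a regime, not a reproduction target.

## Synthetic study system

The generators produce data with exactly the statistical structure the
analysis assumes, each alongside its ground truth:

- **Bundle** — ideal α-helical Cα traces (rise 1.5 Å/residue, twist
  100°/residue) on a circle with 12 Å axis spacing; default 8 chains × 150
  residues, the scale of the octameric complex. Deterministic.
- **Hinge pair** — residues past a split rotated as one rigid body by a known
  angle (default 23°, the published clamp opening) about a known axis.
- **Flex ensemble** — per-residue Gaussian displacements whose RMS magnitude
  follows a planted amplitude profile (default: sinusoid, up to ~3–4 Å,
  emulating rigid cores with mobile periphery); default 25 models, the size
  of the prediction ensembles.
- **Crosslink table** — planted satisfied (≤ 30 Å) and violated (> 30 Å)
  pairs with BS3-style K/KSTY end chemistry (relabelled in the table only),
  scores 250 + lognormal(3.0, 0.8) for genuine records, sub-threshold
  uniform(25, 250) decoys, and duplicate rows at strictly lower score.
  Defaults plant the study conditions: 173 satisfied + 17 violated = 190
  unique above-threshold pairs, intramolecular fraction 88/190, 40 decoys,
  20 duplicates — so the processing chain reproduces the published counts
  (190 / 88 / 102 / 91%) from first principles at run time.

All randomness flows through NumPy's PCG64 `default_rng`; a fixed seed gives
bit-identical output across platforms.

**What the synthetic system does not emulate:** real side chains and backbone
geometry (Cα-only), supercoiling, density noise/CTF, spectrum-level score
structure, unmappable crosslinks from unmodelled regions, or search FDR. A
green synthetic suite therefore demonstrates correctness of the computational
chain — not the biological conclusions, which require the deposited
experimental inputs (see `data/reference/`).

## Problem sizes and numerics

Tests and the acceptance script use bundles of 2–8 chains × 30–150 residues,
25-model ensembles, 8 Å maps at 2.67 Å voxels, and bounded rotation searches
(15° grid within 45°) — sizes chosen so the whole suite verifies every
pipeline stage, including exhaustive searches and permutation nulls, in well
under a minute. Degenerate inputs are errors, not silent results: < 3 points
for superposition, empty structures/selections, zero-variance correlation
masks, undersampled simulation grids, zero mapped links (percentage flagged
undefined, not a division error), zero violated links (association flagged
undefined).

## Known limitations

- Identity percentages depend on the gap convention; only the convention
  stated above is implemented.
- The rigid-fit coarse search is exhaustive, not FFT-accelerated; it is
  sized for single complexes, not density-wide exhaustive scans.
- Crosslink distances are Cα–Cα (the standard validation convention);
  lysine side-chain Nζ distances are not computed for Cα-only models.
- The published reproductions (deposited models, exported crosslink table)
  require downloading the public accessions; the repository ships only the
  procedure and the expected file layout.
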