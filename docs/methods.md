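# Methods

This note records the models, parameter choices and numerical conventions
behind `effimm`, and what the synthetic benchmarks do and do not show.

## Structure model

Coordinates are read from PDB/mmCIF (via gemmi) into a chain → residue →
heavy-atom hierarchy. Only the first model is kept; hydrogens and waters
are dropped; HETATM groups are excluded unless requested. Alternate
locations resolve to the highest-occupancy conformer, ties broken
alphabetically by altloc id — a deterministic, widely used convention.
Residue identity is the triple (chain, residue number, insertion code).
Van der Waals radii are element-based Bondi-style values (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 Å; unlisted elements fall back to 1.70 Å). When a
deposit contains several copies of a molecule in the asymmetric unit,
analyses operate on explicitly selected chains; copies are never averaged.

## SASA and solvation energetics

SASA uses the Shrake–Rupley method with a golden-spiral (Fibonacci) point
set — deterministic, so all downstream numbers are bit-reproducible. A
surface point is buried iff it lies strictly inside a neighbour's
probe-expanded sphere; boundary points count as exposed. Defaults: probe
1.4 Å, 960 points per atom. Convergence on a single sphere is ≤ 1% error
at 960 points and ≤ 0.25% at 3840 (verified against 4πR²); the two-sphere
case is verified against the spherical-cap closed form.

Solvation energy is the classic atomic-solvation-parameter sum
`Σ σ(element)·ASA(atom)`. The shipped σ set is Eisenberg-style
(kcal/mol/Å²): C +0.016, S +0.021, N −0.006, O −0.006, P +0.016 — burial
of apolar surface is favourable. The set is named and swappable. The
interface statistic is, per body X of a complex,

    gain_X    = E_solv(X isolated, bound conformation) − E_solv(X | partner present)
    percent_X = 100 · gain_X / |E_solv(X isolated)|

Because it is a ratio of energies computed with the same σ set, the
percentage is insensitive to the absolute σ scale; it is undefined
(reported as missing) when the monomer energy magnitude is below 1e-6.
Both terms use the bound conformation, so the statistic isolates surface
burial from conformational change.

## Interface statistics

Contacts: residue pairs with any heavy-atom pair within 4.5 Å (default),
or, in ΔASA mode, effector residues losing > 0.1 Å² of surface on
complexation. Core residues: rSASA = ASA / reference maximum < 0.25, with
Tien-style theoretical maxima per residue type; unknown residue types
fall back to the largest tabulated maximum (logged). None of these
thresholds is canonical; all are exposed in configuration. The
core-contact fraction pools counts over complexes before dividing (two
complexes contributing 10/20 and 7/23 give 17/43, not the mean of the two
fractions), and links complex residues to the free structure by global
sequence alignment (BLOSUM62, gap open 10 / extend 0.5) so numbering
offsets between deposits are tolerated; pairing by residue number is
available where numbering is shared. Active-site occlusion compares the
summed site-residue ASA with and without the partner as occluder, both in
the bound conformation.

## Superposition and hinge decomposition

Superposition is the closed-form Kabsch solution (SVD with reflection
correction); rotation angles come from the trace, axes from the
antisymmetric part (or the +1 eigenvector near 180°). For a two-subdomain
motion, both states are superposed on the fixed body; the Kabsch rotation
mapping the moving body free → bound gives the total angle and axis. The
hinge angle is defined as the angle subtended at the boundary Cα centroid
by the moving-body centroid before versus after the shift — one simple,
deterministic operationalization of a quantity often measured by eye in a
viewer; on constructed hinges it tracks the planted rotation to within a
few degrees, and comparisons against it should allow tolerances of
10–20°.

Split detection scans every contiguous single boundary (two bodies only;
multi-hinge decomposition is out of scope), fits each segment rigidly,
and declares a split when the pooled two-body RMSD improves on the
single-body RMSD by at least a factor of 2 with each body fitting within
2.0 Å (min body size 15 residues). A single-body RMSD below 1e-3 Å is
treated as "already rigid" so exact copies are never split. On planted
splits with 0.2 Å coordinate jitter the boundary is recovered within ±2
residues.

## Mechanism classification

The classifier is an ordered rule cascade on the features above:

1. **fold_disruption** if a rigid split with subdomain rotation ≥ 60° is
   detected (or supplied), or the free-vs-bound Cα RMSD is ≥ 5 Å;
2. otherwise, occlusion ≥ 0.5 → **plugging** if the immunity buries
   ≥ 15% of its own solvation energy, else **capping**;
3. occlusion < 0.5 → **exosite**; anything else is **indeterminate**.

The classes are qualitative in origin; the numeric boundaries were chosen
to separate the constructed fixtures sharply and are all configurable.
Labels on borderline real complexes should be read as descriptive, not as
ground truth. Without a free-state structure only rules 2–3 apply and the
call is flagged accordingly. Every comparison is recorded in a rule
trace, making calls reproducible and auditable.

## Metagenomic enrichment

Normalisation: `value = count / (read_total × Bacteroidales abundance) ×
10⁶` — hits per million Bacteroidales reads. Samples with zero or missing
abundance are dropped with a warning; abundance is an input column, not
estimated here. Hit counting from hmmsearch `--domtblout` files takes one
hit per target sequence per family at a full-sequence E-value ≤ 1e-5
(configurable). TssH is blacklisted from the structural aggregate by
default because AAA+ ATPase profiles attract off-target hits; the
aggregate is the per-sample sum over the structural family set (sums are
additive in the normalised units).

Group enrichment is per-family Kruskal–Wallis (mid-rank ties, chi-square
approximation) with Benjamini–Hochberg step-up over the family set. The
chi-square approximation is compared against the exact permutation null
on 5-per-group fixtures in the tests; at those sizes its absolute error
is on the 0.1 scale and shrinks with n. Slopes of toxin-family abundance
on a structural marker are per-group OLS with intercept (a
through-origin mode is exposed), with 95% CIs from the t-distribution of
the slope. The longitudinal analysis fits a per-subject OLS slope over
weeks (subjects with < 3 time points excluded) and tests the subject
slopes against zero per group with the Wilcoxon signed-rank test — a
deliberately simple stand-in for a full mixed-effects longitudinal model,
adequate for detecting a planted monotone drift but blind to covariates.

## Assay formulas

Competitive index: `(post_R/pre_R)/(post_D/pre_D)`; a zero recipient
count returns 0 flagged as at the limit of detection (an optional
pseudocount mode exists); a zero donor count is an error. One-site
binding is fitted in log-K_D parameterisation (K_D > 0 by construction)
with Levenberg–Marquardt from three starts at the dose-range log
quartiles; a matched nonspecific control is subtracted point-wise first.
Melt T_m is the temperature of maximum absolute first derivative of the
fluorescence after Savitzky–Golay smoothing (quadratic, window 5),
refined by parabolic interpolation between grid points; using |dF/dT|
makes the assignment invariant to affine transforms of the fluorescence.
A curve whose peak derivative does not exceed 3× the median derivative is
reported as having no transition.

## Synthetic data: what it emulates, and what it does not

Structural fixtures are idealised poly-alanine helices (rise 1.5 Å/res,
twist 100°/res, five heavy atoms per residue), atom cages/caps, and
planted rigid motions with Gaussian jitter (default 0.2 Å — large enough
to be nontrivial, small relative to the 2 Å rigid-fit tolerance). They
exercise the geometry exactly but have none of real proteins' packing,
side-chain diversity or crystallographic noise, so passing them
demonstrates correctness of the computations, not field performance on
arbitrary deposits. Hit tables are Poisson counts whose means are
(per-family lognormal baseline) × depth × abundance × planted fold ×
lognormal(σ = 0.5) biological noise, with depths 5e6–2e7 reads and
Bacteroidales abundances 0.05–0.6 — realistic scales for stool
metagenomes — under a three-group design of 30 samples/group and 150
families; real cohorts add compositionality, zero inflation and
covariates that the simulation omits. The longitudinal cohort plants a
+0.2/week drift (σ = 0.5, 10 weeks, 20 subjects/group) in one group.
Every generator takes an explicit seed, uses its own RNG, and emits its
ground truth.

## Problem sizes in the standard runs

The bundled verification runs use 200 simulated cohorts for the
planted-effect detection rate, 100 for the longitudinal trend rate, 20
random hinge instances for boundary recovery, 960-point SASA spheres, and
n = 200 per group for slope recovery — sizes at which the stochastic
rates are stable to a few percent while a full run stays within a couple
of minutes on one CPU.

## Known limitations

- SASA differences from PISA-class tools reflect different radii, point
  densities and σ sets; only the ratio-based percentage statistic should
  be compared across implementations.
- Split detection handles exactly one boundary; discontinuous bodies or
  multi-hinge motions need an explicit partition.
- The enrichment arm consumes hit tables; building or running profile
  HMMs, read QC and taxonomic profiling are out of scope.
- The deposited-structure analyses retrieve entries from the RCSB archive
  at run time and are therefore unavailable offline.
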