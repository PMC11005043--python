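# Methods

This note records the models, conventions and numerical choices behind
`enzymd`, in the spirit of a statistical-software methods appendix: what is
computed, under which assumptions, and where the genuinely open design
decisions were resolved.

## Response variable

The fold change in activities (FCA) is the difference between a variant's
fold activity (variant/template activity ratio) measured with and without a
pre-incubation heat shock: `FCA = fold_b − fold_a`. Only the difference is
physically defined, so the sign convention is configurable
(`RunConfig.fca_convention`); the default is with-pre-heat minus
without-pre-heat. FCA is invariant to rescaling all activities by a common
factor, which the tests assert.

## Sequence descriptors (80 columns)

The 66 scale descriptors are per-family, per-component means of per-residue
scale values — composition statistics, deliberately not position-encoded.
The ten families and dimensionalities are BLOSUM indices (10), Cruciani
properties (3), FASGAI (6), Kidera factors (10), MS-WHIM (3), ProtFP (8),
ST-scales (8), T-scales (5), VHSE (8), zScales (5); this is the unique
standard completion of the named five families that reaches 66 components.
The zScales, Kidera, VHSE, MS-WHIM, Cruciani and FASGAI tables are
transcribed from the literature. The ProtFP, ST-scale, T-scale and
BLOSUM-index tables are **synthetic reconstructions** (marked as such in
`scales.py`): seeded orthogonal rotations of the principal components of the
embedded property tables, matched to the published dimensionalities. They
preserve the physicochemical embedding structure these families provide but
are not the published numeric values; every downstream quantity is computed
from whichever table is present, and all features are min–max rescaled
before modelling, so no result in this package depends on digit-level
fidelity of an individual scale entry.

The 14 global properties are sequence length, average molecular weight
(residue-mass sum plus one water), isoelectric point, aromaticity,
instability index, GRAVY, net charge at pH 8.0 (the experimental assay pH),
reduced molar extinction coefficient, mean Vihinen flexibility,
helix/turn/sheet propensity fractions, aliphatic index, and Boman index.
Aromaticity, instability, GRAVY, the propensity fractions and the extinction
coefficient are delegated to Biopython's ProtParam; charge and pI use the
EMBOSS pKa set with the Henderson–Hasselbalch net-charge function, the pI
solved by root bracketing to |charge| < 1e-4 (cross-checked against a
10⁴-point pH grid in the tests). Flexibility is the composition mean of the
Vihinen scale rather than the sliding-window profile so that it, like every
other descriptor except the inherently dipeptide-based instability index,
is invariant to residue order.

## MD descriptors (32 columns)

Twelve geometry series — superposed RMSD against the reference structure and
mass-weighted radius of gyration, each for heavy-atom, backbone and Cα
selections on the whole protein and on the binding site — are summarized by
their per-trajectory mean and standard deviation (24 columns), joined by the
8 mean secondary-structure fractions (32 total). Replicate trajectories are
aggregated by averaging the per-replicate values ("average of the
averages"); the std-over-replicates of every per-replicate feature is also
available from `aggregate_replicates` for callers who want the dispersion.

Superposition is unweighted Kabsch (SVD with a determinant flip to enforce a
proper rotation), batched over frames; it fits and measures on the same atom
selection. RMSD is evaluated on the fitted coordinates rather than through
the closed-form singular-value identity, which cancels catastrophically for
near-identical conformations.

Secondary structure follows the Kabsch–Sander electrostatic model: the
hydrogen-bond energy E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332
kcal/mol with a bond below −0.5 kcal/mol; amide hydrogens are reconstructed
on the nitrogen along the preceding carbonyl O→C direction (standard
practice for inputs without hydrogens), prolines and chain starts donate no
bond, and inter-atom distances are floored at 0.5 Å. α-helices arise from
two consecutive i→i+4 turns, 3-10 helices from two consecutive i→i+3 turns,
parallel/antiparallel bridges from the classic two-bond patterns with a
minimum strand separation of three residues, turns from the interiors of
isolated 3/4/5-turns, and bends from Cα curvature over (i−2, i, i+2)
exceeding 70°. Priority is H > E > G > T > S > C; an eighth "other" class
absorbs anything unassigned (π-helices are not detected). Residue pairs
whose Cα atoms are more than 12 Å apart are skipped — at that separation the
electrostatic energy cannot reach the bonding threshold (verified against
the unfiltered computation in the tests); energies are evaluated in float32,
whose ~1e-4 Å distance error is negligible against the −0.5 kcal/mol
threshold.

## Pocket descriptors (80 columns)

The binding site is fixed from the template: residues with any heavy atom
within 3.5 Å (inclusive) of a ligand heavy atom. The descriptors are
deterministic proxies for grid-based pocket analysis: convex-hull volume of
the site atoms, maximum pairwise distance (length), mean distance of site
atoms to the hull surface (depth), Shrake–Rupley SASA of the site atoms
(960 golden-spiral points, 1.4 Å probe, all protein atoms as occluders),
Kyte–Doolittle hydrophobicity, residue-class counts with charges at pH 8
(His neutral, side-chain pKa ≈ 6), per-residue pocket occupancy (fraction of
frames within the residue's reference distance to the ligand centroid plus
2 Å slack, so an unperturbed trajectory scores 1), and the normalized
B-factor B = (8π²/3)·RMSF² on Cα, z-scored across site residues. Per-residue
quantities occupy 16 canonical slots ordered by residue id, zero-padded or
truncated (with a warning) when the site size differs; 10 + 32 + 32 + 6
columns make the 80-column block, and 32 + 80 = 112 MD-derived columns
overall. SASA within the block is evaluated every 5th frame (`sasa_stride`) with
240 sphere points per atom (`sasa_points`; the standalone routine defaults
to 960) — runtime/precision trade-offs that leave the frame-mean and -std
estimates essentially unchanged on the synthetic trajectories.

## Robustness statistics

Trajectories are chunked into contiguous 10 ns segments (trailing remainder
dropped). The chunk ANOVA compares each chunk's RMSD values against the
first chunk's, frames pooled across replicates (a per-replicate-means mode
is provided, since the pooling convention is a genuinely open choice); the
significance threshold is α = 0.05, uncorrected. Path-similarity analysis
uses the symmetric Hausdorff distance with pairwise-superposed RMSD as the
frame metric, classified as identical below 0.5 Å and highly different above
3.0 Å, with Ward clustering on the distance matrix. The shuffle retention
test draws, per fold, one random 80% frame subsample applied to every
replicate (a paired design: identical replicates give identical fold means
and F = 0) and runs a one-way ANOVA across replicates on the 20 fold means;
retention means p < 0.05, i.e. replicate differences survive averaging.

The minimum-informative-length rule declares a variant "agreeing" through
chunk c when no chunk 2..c differs significantly from chunk 1. If ≥ 80% of
variants agree through the whole horizon the first chunk length is
informative; if agreement never reaches 80% the longest length is returned
with a warning; otherwise the longest agreeing prefix length is chosen.

Calibration: on stationary white-noise trajectories (`ou_rho = 0`, so chunk
RMSD values are iid) the chunk ANOVA holds its nominal level (observed rate
0.045 over 5000 tests). Within a variant the chunk tests share the first
chunk and are positively correlated, so the seed-to-seed spread of the
observed rate is wider than the naive binomial SE; the calibration check in
the acceptance suite therefore uses the cluster-robust (per-variant) SE,
which is the correct yardstick for the 200-variant design.

## Modelling protocol

Features are min–max rescaled with extrema from the training rows only;
constant columns map to 0 and out-of-range values are not clipped. The
80/20 split is random and unstratified with train size ⌊0.8 n⌋ (312 → 249
train / 63 test). Screening fits a roster spanning the standard families
(linear, kernel, tree, ensemble, neighbors, neural, plus a mean-only dummy)
with default parameters, excludes models with negative test R² or a
response-domain mismatch (Poisson requires non-negative, Gamma strictly
positive responses), and ranks survivors by R², then RMSE, then fit time;
a model that raises is recorded as a failure, never fatal. Tuning is random
search over a compact LightGBM space with 5-fold CV and negative-MAE
scoring. The bootstrap comparison resamples the training set with
replacement, refits with the tuned (fixed) parameters and scores the fixed
test set — 500 iterations by default, followed by one-way ANOVA and Tukey
HSD across feature-block datasets. Under the null (identical datasets,
independent resampling streams) the Tukey procedure declares a difference in
≤ 5% of seeded runs, which the acceptance suite checks.

## Interpretation and diagnostics

Permutation importance is scikit-learn's (score drop under column
shuffling); gain and split-count rankings come from the LightGBM booster.
Shapley attributions use LightGBM's native TreeSHAP (`pred_contrib`); the
independent check is an exact 2^d coalition enumeration with the
interventional value function v(S) = mean over background rows of
f(x_S, b_∖S), which satisfies local accuracy to 1e-10. For additive
(depth-1) ensembles path-dependent TreeSHAP coincides with the exact
interventional values on the training background, which is the regime the
agreement test exercises. Importance rankings in the recovery experiment are
measured on the full data set with 20 permutation repeats: with few planted
drivers the tail of both rankings is estimator noise, and measuring on 60
test rows with 5 repeats leaves the top-20 concordance unstable for reasons
that have nothing to do with either method.

Poor predictions are residuals (ŷ − y) outside the empirical 5%/95%
quantiles (linear-interpolation convention). The enrichment diagnostic is a
one-sided (over-enrichment) hypergeometric test of a case flag — by default
"≥ 5 co-occurring mutations" — among the poor predictions: p = P(X ≥ k)
under Hypergeometric(N, K, s), fold = (k/s)/(K/N).

## Synthetic data generator

The generator defines the study conditions the pipeline is validated under;
it emulates the statistical structure of the real library, not its physics.

* **Template**: 235 residues (the scale of an enterokinase light chain)
  built from ideal backbone internal coordinates (NeRF chain construction;
  helices at φ/ψ = −57°/−47°, sheets at −119°/113°, loops drawn from an
  extended-coil range), six helix and six strand segments, and a 6-atom
  peptide-like ligand anchored 2.5 Å off the mid-chain Cα atoms so a
  non-empty 3.5 Å binding site exists. Backbone-only (N, Cα, C, O); isolated
  strands do not pair, so the template's sheet content reads as coil — the
  planted response targets helix and turn content, which the assignment
  resolves well.
* **Library**: 312 variants; variant 0 is the template; substitution counts
  are Poisson(4.2) clipped to 0..9, positions drawn from 70 hot-spot
  positions in three regions (70/235 = 29.8% of positions, so the library
  reproduces the ~30% mutated-position coverage and ~25% prevalence of
  variants with more than five mutations characteristic of the emulated
  epPCR data; pairwise identity stays above 90% by construction).
* **Trajectories**: per-atom mean-reverting Gaussian (Ornstein–Uhlenbeck)
  displacements around the template, x_{t+1} = ρ·x_t + η with ρ = 0.9 and η
  scaled so the stationary per-coordinate sd equals the per-atom amplitude —
  the simplest process with temporal autocorrelation within a replicate and
  variability between replicates, the two properties the robustness
  statistics probe. The amplitude is 0.25 Å at structured residues, doubled
  in loops and scaled by 2.5× within ±2 residues of a mutation, so mutations
  fray local helices and move the secondary-structure fractions — giving
  realistic RMSD (~0.8 Å) and RMSF magnitudes and cross-variant descriptor
  variance. Replicates differ only in their seed stream; everything is
  deterministic given the spec seed.
* **Response**: FCA_i = Σ_j coef_j·z(feature_ij) + ε with per-column
  standardization and ε ~ N(0, 0.5²); the default coefficients are +1 on the
  mean α-helix fraction and −1 on the mean turn fraction, mirroring the
  direction of the structure–activity relationship the workflow is meant to
  recover. The planted ground truth is returned for recovery tests.

What passing on this generator does **not** show: physical realism of the
dynamics (no force field, solvent or thermostat), realistic feature
correlation structure beyond what the OU fluctuations induce, epistasis
(the planted response is linear and additive by default), or anything about
the real data set's noise distribution, which is unstated.

## Problem sizes of the validation experiments

Chosen for single-core desk-scale runs: schema conformance on a 20-variant
full-block library; oracle comparisons at 50–100 random instances each;
type-I calibration with 200 variants × 2 replicates × 300 frames; Tukey null
calibration over 20 seeds with 50 bootstrap iterations of a ridge regressor
(the property under test is the resampling/Tukey machinery, not the
learner); recovery on one 300-variant, 5-replicate, 101-frame library with
ten seeded repetitions of the planted noise, split, tuning and fit
(featurization dominates the cost; the planted-noise/split/model seeds are
what the recovery statement quantifies over).

## Known limitations

* Backbone-only structures: "heavy" and "backbone" atom selections coincide
  on generator output (they differ on real PDB inputs with side chains).
* The DSSP-style assignment omits π-helices, chain-break handling and the
  full ladder/sheet bookkeeping of the original dictionary.
* Pocket descriptors are documented geometric proxies, not an alpha-sphere
  cavity model; convex-hull volume rank-correlates with cavity size on toy
  systems but is not an absolute cavity volume.
* The four reconstructed scale families are embeddings, not the published
  tables (see above).
* `StructureModel` carries a single conformational chain; multi-chain
  support is limited to what the PDB reader preserves.
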