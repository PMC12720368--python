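# Methods

## Similarity model

A region's morphometry is modelled as the distribution of its vertices in
the 5-dimensional feature space (volume, area, thickness, sulcal depth,
curvature), after z-scoring each feature channel within subject across all
vertices.  Similarity is `s = 1/(1 + KLsym)`, which maps divergences in
[0, ∞) onto (0, 1] without any data-dependent rescaling — a min–max
normalization per subject would destroy cross-subject comparability of the
resulting matrices.

Two divergence estimators are provided:

- **gaussian** — the closed form on per-region sample moments, with a ridge
  of `1e-6 · trace/d` added before inversion.  Exact for Gaussian clouds;
  used as the fast default in simulation studies because the synthetic
  generator draws Gaussian vertices.
- **knn** (default k = 5) — the Wang–Kulkarni–Verdú estimator,
  `D ≈ (d/n) Σ log(ν_k/ρ_k) + log(m/(n−1))` per direction, clipped at zero
  and averaged.  Coincident points are separated by a seeded 1e-9 jitter.
  Known limitation: at d = 5 and n ≈ 2000 vertices the estimate saturates
  for strongly divergent pairs (measured 20–35 % underestimation at
  KLsym ≥ 2 for every k between 1 and 40), so the two estimators agree
  closely (mean |Δs| ≈ 0.02) only up to moderate divergences
  (KLsym ≲ 0.5).  Rankings are preserved well beyond that point.

Regional strength is the row mean of off-diagonal similarities
(no thresholding); network strength is the unweighted mean over member
regions of a 7-level partition.

## Synthetic cohort

The generator is the package's study bench; its defaults emulate the
cohort structure of a two-subtype Parkinson's case-control study
(101 controls, 67 + 60 patients; age ≈ 58 ± 7; male fractions, MoCA,
UPDRS-III, H&Y, LEDD and duration drawn per group from the reference cohort
summaries built into the generator; TIV log-normal; sex 0/1).

Geometry: mirrored unit-sphere centroids (left x < 0), seven azimuthal
network sectors per hemisphere.  Region moments vary smoothly over the
sphere (linear basis in the centroid for means; an SPD field
`A(c)A(c)ᵀ + 0.5·I` for covariances), so similarity matrices and the maps
derived from them are spatially smooth.

Planted effects act on the full distribution, not on feature means:

- **Subtype 1** (lowered similarity): anisotropic covariance distortion
  `Σ → DΣD`, `D = diag(exp(±effect/2))` with alternating signs.  A scalar
  inflation `(1+e)Σ` was rejected: when inter-regional mean separation
  dominates the divergence, the added trace term cancels almost exactly
  against the shrunken Mahalanobis term and the net strength change is
  ≈ 0; the anisotropic form raises divergence to every other region
  regardless of the mean field.
- **Subtype 2** (raised similarity): moments blended toward the cortical
  average with weight `w = e/(1+e)`, which lowers divergence to everything.

The two planted region sets are disjoint (`affected_frac` each, default
0.2; construction rejects overlap).  Covariate effects enter as smooth
region-patterned mean shifts proportional to standardized age/sex/TIV
(defaults 0.1 each in z-units).  A strength perturbation in planted
regions also moves unplanted regions' strengths (each strength averages
similarity to all regions), so case-control significance spreads beyond
the planted sets at large effects — intended behaviour of the similarity
construct, and the reason the null-soundness check uses zero-effect
cohorts.

Expression: planted gene columns are built as
`coupling·standardized(map) + √(1−coupling²)·noise` with the noise
orthogonalized against the map, so each planted column's sample
correlation with the target equals the coupling exactly; remaining columns
are standard noise.  What the generator does **not** emulate: non-Gaussian
vertex distributions, scanner/site effects, spatially autocorrelated
expression noise, donor structure, or any coupling between covariates and
subtype membership.  Passing tests therefore demonstrate correctness of
the estimators and decision procedures under the stated model, not
robustness to those real-data complications.

## Subtyping

`fit_polytope` alternates (a) hard assignment of each patient to the
hyperplane with the largest geometric margin `(wᵀx + b)/‖w‖` and (b)
refitting each hyperplane as a linear soft-margin classifier (L2, squared
hinge, C = 0.25 by default) between all controls and the assigned
patients, for up to 50 iterations or until assignments stabilize.
Features are z-scored per region across subjects first (margin objectives
are scale-sensitive).  Initialization matters: a uniform random partition
starts every hyperplane at the same average deviation direction and stalls
in a degenerate optimum, so each run instead anchors its K hyperplanes at
randomly chosen patients' deviations from the control centroid and assigns
patients to the best-aligned anchor.  Empty hyperplanes are reseeded from
the worst-margin patients.  Consensus: co-assignment frequencies over
`n_consensus = 20` runs, cut by average-linkage clustering at K; the
hyperplanes are refit once against the consensus partition.

Model selection (`select_k`): for each K, a consensus fit on each of 10
folds' training patients (plus all controls) assigns *all* patients by the
nearest-face rule; the criterion is the mean pairwise ARI over the 45 fold
pairs.  Under planted two-subtype structure the profile peaks sharply at
K = 2; under pure noise it stays low — though not at zero, since fold
models share 90 % of their training data and inherit the same spurious
direction.  Strength inputs are *not* covariate-adjusted before subtyping
(adjustment happens in the case-control stage); a caller can pass
residualized strengths if desired.

## Statistics

Covariate adjustment is per-region OLS on centred sex/age/TIV; the
adjusted value is residual + intercept, which keeps group means on the
original strength scale (centring makes the intercept the grand mean and
changes neither residuals nor t statistics).  Contrasts are pooled-variance
Student t (Welch by flag), Bonferroni at α/m with m = number of regions
(7 for network-level maps).  The χ² test is Pearson's without continuity
correction — with Yates' correction the reference sex statistics
(0.176, 0.345) are not reproduced.  Mann–Whitney U counts x > y pairs plus
half-ties; p exact for small tie-free samples, else tie-corrected normal.
BH-FDR is the standard step-up, used for clinical correlation maps, gene
p-values (within gene family) and enrichment (across sets).

## PLS and bootstrap gene scores

For a single response the first PLS weight vector is the normalized
cross-covariance `Xᵀy` of the column-standardized expression with the
centred map; `variance_explained` is the squared correlation of the region
scores with the map.  Orientation is canonical (scores correlate
positively with the map).  Component significance uses 5000 permutations
of the map across regions.

Bootstrap Z: regions resampled with replacement, the replicate
cross-covariance scaled by the **original** norm, SE over replicates,
`Z = w/SE`, two-sided normal p, BH-FDR; PLS1± classes at |Z| > 3 and
p_FDR < 0.005.  Scaling each replicate by its own norm (the common
implementation) understates the SE whenever genes outnumber regions —
the replicate norm co-fluctuates with every gene's weight and dividing
cancels shared variance that is genuinely present across datasets;
measured null Z dispersion was ~1.5 instead of 1.0, which would make the
significance classes anticonservative.  With fixed-norm scaling the null
Z is calibrated (sd ≈ 1.0) and planted genes at coupling 0.8 score
Z ≈ 8–11.

## Spin permutations

Nulls are uniform random 3-D rotations (QR of a Gaussian matrix,
determinant +1) of the region centroids; rotated positions are matched
back to the originals by minimum-cost assignment, so every null is an
exact permutation (value multisets preserved).  `p = (1 + #{|r_null| ≥
|r_obs|})/(n_spins + 1)`, two-sided; minimum 100 spins.  Left-hemisphere
maps only, matching the expression matrix.  Caveat: for pure low-order
(dipole-like) coordinate maps the spin null has intrinsically low power,
because any rotated dipole correlates substantially with any other dipole;
tests and examples use higher-order smooth fields where power exists.

## Expression preprocessing

The five probe-to-region steps run in fixed order: gene mapping; removal
of probes below background in strictly more than 50 % of samples (exactly
half is kept); per-gene probe selection by differential stability (mean
inter-donor Spearman correlation of regional profiles; single-donor
fallback: highest variance); sample-to-region assignment with regions
modelled as centroid balls and a 2 mm tolerance beyond the boundary;
scaled robust sigmoid `1/(1+exp(−(x−median)/IQR))` per gene within donor,
min–max rescaled, then within-region and across-donor averaging.
Donor-wise normalization precedes averaging because donor batch effects
are the dominant nuisance in this kind of resource.

## Enrichment

The permutation null draws size-matched gene lists uniformly from the
scored-gene universe (not genome-wide — lists are selected from scored
genes, so that is the exchangeable reference), 5000 draws by default,
plus-one p, BH-FDR across the seven sets.  Under uniform sampling this
null equals the hypergeometric distribution, which is computed exactly
alongside as a cross-check.

## Problem sizes and determinism

Simulation studies in tests and the acceptance script use 40-region /
60–120-vertex cohorts, 152-region geometry (76 left) with 200 genes for
transcriptomics, 199 spins for calibration loops and 1000 bootstrap
replicates — sizes chosen so the full suite runs on a laptop in minutes;
the full 308-region scale is supported throughout.  Every stochastic
routine takes an explicit seed; the pipeline fans one global seed into
per-stage seeds (SHA-256 of seed:stage, recorded in `manifest.json`), and
equal seeds reproduce byte-identical artifacts.

## Known limitations

- The k-NN divergence saturates at strong divergences (above); absolute
  similarity values at weakly similar region pairs are conservative.
- Bootstrap gene Z assumes exchangeable regions; spatial autocorrelation
  of expression (present in real atlases, absent in the generator) would
  make the SE optimistic — the spin test, not the gene Z, carries the
  spatial inference.
- The subtyping CV-ARI criterion is a stability measure, not a test; under
  the null it is low but positively biased, so it ranks K rather than
  certifying cluster existence.
- No subcortical structures; the similarity construct is cortical.
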