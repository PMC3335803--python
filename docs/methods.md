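# Methods

## Data model and assumptions

All volumes (FA maps, density maps, probability maps, statistic maps)
are 3-D scalar grids with a NIfTI affine, assumed co-registered to one
common grid. Cross-volume operations are index-aligned; every pipeline
entry point calls a grid check (equal shapes, affines equal within 1e-4
per entry) and aborts on mismatch. There is no resampling anywhere —
spatial normalisation is an upstream concern, and the package treats its
outputs as given. FA is dimensionless in [0, 1]; volumes are written as
float32 NIfTI-1 single files, with scaling slope/intercept honoured on
read.

## Probabilistic atlas

Per-subject tract density maps are binarised (any positive density →
membership) and averaged voxelwise per portion, giving membership
probabilities that are multiples of 1/n for n atlas subjects. The
retention threshold τ (default 0.90) zeroes probabilities below τ and
keeps values at or above τ **unchanged** — the surviving probability is
later used as the weight, so collapsing it to 1 would discard exactly
the information the weighting needs.

Boundary convention: a probability exactly equal to τ is retained
(≥ rule). With n = 25 the attainable probabilities are multiples of
0.04, so 0.90 itself cannot occur and the convention is moot; for other
n it makes thresholding predictable. Raising τ can only remove voxels
(monotonicity) and thresholding is idempotent; both are enforced by
property tests.

Portions are built independently; after thresholding a voxel may in
principle belong to several portions (nothing forbids overlap on real,
warped data), and downstream statistics treat portions independently.
A portion whose thresholded map is empty is a construction error naming
the portion, never a silent empty region.

## Probability-weighted regional FA

For each analysis subject and portion, the regional value is
`Σ p(v)·FA(v) / Σ p(v)` over voxels with positive atlas probability and
`FA ≥ fa_min` (default 0.2, the conventional white-matter floor; FA
exactly 0.2 is included, since only values *below* the floor are
rejected). Rejected sub-threshold voxels are counted and logged per
subject — useful as an atrophy indicator — but contribute to neither
numerator nor denominator. An empty accepted set raises an error naming
subject and portion. The weighted mean is invariant to rescaling all
weights of a portion by a positive constant and always lies within the
range of contributing FA values (tested against a brute-force per-voxel
loop at 1e-12).

Group "(SD)" values reported by `group_summary` are the plain
across-subject sample SD of per-subject regional means — a
between-subject spread, not a voxelwise one.

## Skeleton arm (TBSS-style)

The comparison arm reduces a template (the voxelwise mean FA across
analysis subjects) to its ridge and projects each subject's FA onto it:

1. The template is smoothed with a Gaussian of sigma 1 voxel (the only
   smoothing anywhere; chosen for Hessian stability on thin tubes).
2. A local tract-perpendicular is estimated per voxel: the direction of
   steepest smoothed-FA ascent where the gradient magnitude exceeds 5%
   of its volume maximum (off the ridge, this points at the tract
   centre), and the eigenvector of the local Hessian with the most
   negative eigenvalue where the gradient vanishes (on the ridge, where
   the gradient carries no direction). A pure principal-curvature rule
   was rejected: for a radially symmetric tube the most negative
   curvature off the axis is azimuthal, along which every flank voxel is
   a local maximum, so the detector would keep the whole suprathreshold
   disc instead of the axis. Both branches and the relative switch are
   invariant under monotone affine rescaling of the template.
3. A voxel joins the skeleton iff its template FA is ≥ the threshold
   (default 0.2) and ≥ both linearly interpolated template values one
   voxel away along ± the perpendicular. Ties keep the voxel, biasing
   toward connected skeletons.
4. Projection: at each skeleton voxel, the subject's value is the
   maximum FA at integer steps 0..max_search (default 4, bounded by the
   phantom tract half-width) along ± the perpendicular, nearest-voxel
   sampling, out-of-grid steps ignored.
5. Regional skeleton FA is the **unweighted** mean of projected values
   over skeleton voxels with positive portion probability (the atlas
   provides localisation only); a portion without skeleton voxels is an
   error.

This is a declared simplification of the packaged TBSS machinery (no
distance maps, no 1 mm standard-space resampling) — enough fidelity for
the qualitative comparison: max-projection can only raise values, so
skeleton regional means dominate tract-volume means, reproducing the
systematic ordering between the two measurement tables.

## Group statistics

**ANOVA.** Per portion, one-way fixed-effects ANOVA across the groups
present. Pairwise post-hoc t tests use the pooled within-group mean
square with N − k degrees of freedom (the convention of mainstream
statistical packages' post-hoc procedures), and Bonferroni correction
multiplies by the number of pairwise contrasts *within the portion*
(3 for the three study groups). The family was chosen as per-portion ×3
rather than ×8 portions or ×24 tests because per-portion pairwise
corrected p-values are the quantity the measurement tables report. F
from raw data is cross-checked against a closed-form reconstruction from
(n, mean, SD) summaries and against an independent library one-way ANOVA
at 1e-8.

**Classification.** Binary logistic regression on all 8 portion means
plus intercept (no feature selection), with a mild ridge penalty
(λ = 1e-6) so complete separation degrades gracefully — separation is
surfaced as a warning, and the penalty is recorded in the result.
Apparent (resubstitution) accuracy, sensitivity and specificity are
computed at the 0.5 cutoff with "positive" = the more-affected group;
generalisability is assessed by a stratified, seeded 80/20 split (one by
default, with a repeat-count option), reporting correct-classification
rates on the selected (80%) and unselected (20%) cases. Classification
accuracy on phantoms is *not* comparable to real-cohort values: the
generator draws portions independently (no between-region covariance is
published), which changes the multivariate separability; the machinery
is therefore validated with separable and null oracles instead. Under
the null, the ≈ chance expectation holds for held-out cases only — the
resubstitution rate of an 8-feature model is optimistically biased at
small n.

**Voxelwise permutation + TFCE.** The raw statistic is the pooled
two-sample t per voxel. TFCE integrates suprathreshold component extent
and height, `TFCE(v) = Σ_{h = dh, 2dh, … ≤ max stat} e(h,v)^E h^H dh`
with E = 0.5, H = 2, dh = 0.1 and 26-connected components (canonical
parameter defaults; nothing else is published). Corrected p-values come
from the permutation distribution of the maximum TFCE statistic over
random label shuffles: `p(v) = (1 + #{max ≥ TFCE(v)}) / (n_perm + 1)`,
so p is bounded below by 1/(n_perm+1). Fewer than 100 permutations are
rejected as meaningless FWE resolution. Negative statistic values
enhance to zero (one-sided contrast; the caller chooses orientation).
Computation is restricted to the mask bounding box. Significant-voxel
counts per atlas portion are reported by masking the corrected p map
with each portion's support.

## Phantom generator

The generator emulates the post-registration data situation, not MRI
physics. On a default 32×32×16 grid, eight disjoint axis-aligned blocks
(≥ 27 voxels each) stand in for the CC portions: six midline slabs
anterior→posterior (CC1, CC2, CC3, CC4, CC5, CC7) and two lateral
temporal blocks (CC6L/CC6R).

*Density maps*: the portion geometry with boundary voxels (those with a
6-neighbour outside the geometry) independently dropped with jitter
probability 0.1 — the residual inter-subject variability that survives
registration. Interior voxels are always present.

*FA volumes*: each subject draws a regional mean per portion from
Normal(group mean, between-subject SD) — defaults are the published
per-portion group values for AD (n 37), aMCI (n 19) and HC (n 20) —
then adds Normal(0, 0.01) voxel noise, clipped to [0.01, 0.99] on
tracts. No within-subject voxelwise FA dispersion is published; 0.01 is
a free choice kept configurable, small enough that regional averaging
leaves the between-subject SD essentially unchanged. Background voxels
sit at FA 0.1 plus the same noise, clipped to [0.01, 0.199], strictly
below the 0.2 rejection floor — so regional estimators see only tract
voxels, up to atlas jitter.

What the phantom does **not** model: realistic CC anatomy and curvature,
between-portion covariance, atrophy/partial-volume gradients,
registration error beyond boundary jitter, and any diffusion-signal
physics. Passing tests therefore demonstrate correctness of the
measurement and statistics machinery under the published group
parameters, not performance on real images.

The tract-volume FA parameters (not the higher skeleton-arm values) are
the generator's defaults; the skeleton arm's higher means are treated as
a consequence of max-projection, which the phantom reproduces
qualitatively, rather than as a second parameter set.

Everything is driven by `numpy` Generator seeds: identical
(config, seed) gives bitwise-identical cohorts, and the orchestrated run
writes byte-identical result bundles.

## Problem sizes and numerical choices

Validation runs use the 32×32×16 phantom grid, 25 atlas subjects, and
the published group sizes (37/19/20); the simulated group-comparison
check uses 200 replicate cohorts, and permutation tests in validation
use 150–1000 permutations (the analysis default remains 5000). Grid
checks use 1e-4 on affine entries; NIfTI round-trips are exact to 1e-6
(float32); oracle comparisons use 1e-8 (ANOVA) and 1e-12 (weighted
means). Ties: probability ≥ τ retained, FA = fa_min retained, skeleton
ridge ties retained.

## Known limitations

- The skeleton arm is a simplified ridge/projection scheme, not
  bit-compatible with the packaged TBSS implementation.
- Phantom portions are axis-aligned blocks; geometric realism is out of
  scope.
- Classification percentages on phantoms do not reproduce real-cohort
  values (no published between-region covariance); only separable/null
  behaviour is validated.
- Covariate adjustment (age, sex), nonparametric alternatives and
  multiclass classification are not implemented.
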