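# Methods

## Model

A reconstructed cortical surface is a set of vertices, each carrying *d*
morphometric features. A parcellation partitions the vertices into *R*
regions; region *r*'s vertices are treated as i.i.d. draws from an
unknown continuous distribution *P_r* over ℝ^d. Structural similarity
between regions *a* and *b* is defined through the symmetric (Jeffreys)
KL divergence D(P_a, P_b) = D_KL(P_a‖P_b) + D_KL(P_b‖P_a), mapped to

    MIND(a, b) = 1 / (1 + D(P_a, P_b)) ∈ (0, 1].

Each directed divergence is estimated with the k-nearest-neighbor
estimator

    D̂_KL(P_a‖P_b) = -(d/n) Σ_i log( r_k(x_i) / s_k(x_i) ) + log( m / (n-1) ),

where n, m are the two sample sizes, r_k is the within-sample k-NN
distance (self excluded) and s_k the cross-sample k-NN distance. The
estimator is consistent for continuous densities; it requires no
bandwidth or other tuning and extends to moderate d where explicit
density estimation fails. Because a near-zero true divergence can be
estimated slightly negative, each direction is clamped at 0 before
summing, so D̂ ≥ 0 and weights stay in (0, 1].

Preprocessing before estimation: vertices with non-positive thickness,
volume, or area (biologically unfeasible surface locations) are
discarded; each feature is then z-scored across all retained vertices of
both hemispheres of the one subject (not per region, not per cohort),
using the sample standard deviation (ddof = 1 — immaterial at realistic
vertex counts, stated for exactness). Filtering precedes standardization
so zeros cannot distort the moments. Unlabeled/medial-wall vertices are
excluded with a logged count.

The comparison method, MSN, reduces each region to five summary
statistics (mean sulcal depth, mean thickness, total volume, total area,
and integrated rectified mean curvature Σ_v |MC_v|·SA_v), z-scores each
summary across regions within the subject, and correlates the regional
vectors (Pearson). Appended noise features are region-averaged and enter
the vector after the same z-scoring — which is precisely why MSN is
fragile to uninformative features (the z-score forces them to unit
between-region variance) while MIND, driven by whole distributions, is
not.

## Key parameters

| parameter | default | notes |
| --- | --- | --- |
| k (neighbor order) | 1 | nearest-neighbor variant of the estimator; exposed for sensitivity checks. The additive constant log(m/(n−1)) is used verbatim for every k. |
| distance floor | 1e-12 | duplicate points give zero neighbor distances; distances below the floor are clamped to it with a warning rather than dropping data — inert for continuous features. |
| MIND diagonal | stored as 1, excluded from statistics | the estimator is undefined for a region against itself; 1 matches the "most similar" reading. |
| density grid | 1%–100% in 1% steps | for edge-fraction sweeps; configurable. |
| density ties | weight desc, then region indices asc | deterministic retained sets across runs and orderings. |
| spin permutations | 1,000 | generated from uniform random 3-D rotations; the left-hemisphere rotation is x-mirrored onto the right so bilateral symmetry is preserved; reassignment is one-to-one within hemisphere by Hungarian matching on Euclidean cost between unit-sphere-projected centroids. |
| spin p-values | plain fraction | no +1 smoothing; minimum attainable p is 0. Two-sided tests use the r² statistic. |
| bootstrap | ≥ 100 resamples, one-sided by default | the one-sided null (the first network does not outcorrelate the second) matches the test's purpose; a two-sided option doubles the smaller tail. Degenerate (constant) resamples are redrawn with a logged count. |
| tract matrices | NaN = unmeasured | true-zero connections are log-undefined and treated as absent by default; both directed measurements of a pair are separate observations against the one undirected similarity edge. |
| PLS explained fraction | covariance definition | fraction of total squared X–y covariance captured by component 1; an X-variance definition is exposed as an alternative since "variance explained" is ambiguous for PLS. |
| gene ranks | descending PLS1 loading, ties by gene id | rank 1 = most positively associated with the map; the component sign is fixed so scores correlate positively with the (possibly permuted) map. |
| FDR | Benjamini–Hochberg | across gene sets. |

## Synthetic generator

Regions are multivariate Gaussians — the one family with closed-form
symmetric KL, hence an exact oracle for the entire pipeline (estimator →
standardization → network). Defaults: 10 regions per hemisphere, d = 3,
200 vertices per region, between-region mean spread of 1 feature-SD,
mirrored hemispheres, Fibonacci-sphere centroids, cyclically assigned
cytoarchitectonic class labels. The morphometric variant produces the
five standard T1w features on plausible raw unit scales (CT ≈ 2.5 mm,
per-vertex SA ≈ 0.45 mm², Vol ≈ 1.1 mm³, signed MC, SD) so the vertex
filter and MSN summaries apply. Standardization is a global diagonal
affine map, under which KL divergence is invariant, so the closed-form
truth is unaffected by the pipeline's z-scoring.

Cohorts jitter regional means per subject (homotopic pairs jointly when
mirrored, preserving the spec invariant), leaving each subject's ground
truth computable. Expression matrices plant `n_coupled` genes equal to
`effect` × standardized degree plus unit noise (defaults G = 500,
25 genes, effect = 1). The effect default is deliberately moderate: the
spin-refit enrichment null inherits the planted genes' mutual
correlation, so a very large effect inflates the null spread as much as
the observed statistic — per-gene signal comparable to noise is both the
realistic regime and the one in which the test has power.

Not emulated: within-region spatial autocorrelation, mesh topology,
distance-dependent edge structure, scanner noise. Passing tests
demonstrate correctness of the estimators under the stated regional
model, not robustness to real acquisition artifacts.

## Problem sizes in tests and the acceptance script

Estimator-level checks use n up to 5,000 points (20 seeds) against the
univariate Gaussian closed form; the oracle-equivalence sweep covers 200
random instances with n, m ≤ 500, d ≤ 6, k ≤ 3. End-to-end recovery uses
a 20-region, d = 3 cortex at 500 vertices per region; noise-resilience
uses 10 subjects at 150 vertices per region with 5 appended noise
features; calibration uses 200 replicates × 200 spins (spin test) and 40
replicates × 50 permutations (enrichment null). These sizes keep the full
suite and the acceptance script at roughly twenty seconds each while
leaving comfortable statistical margins.

## Numerical and degenerate-input choices

- Nearest-neighbor ties are broken arbitrarily: only distances enter the
  estimator, so ties cannot change the value.
- The kd-tree path is contractually identical to exhaustive search
  (tested to 1e-10); the spatial index is purely an acceleration.
- Zero-variance feature columns, constant maps, empty regions, zero-norm
  expression profiles, and |r| = 1 Fisher inputs raise (or clamp with a
  warning, where a deterministic policy is safer than failure); each
  error names the offending column/region.
- Angular similarity uses the arctan2 form of the angle
  (2·atan2(‖û−v̂‖, ‖û+v̂‖)), which is exact at the parallel/antiparallel
  extremes where arccos of a clipped cosine loses all precision.
- Regions with ≤ k vertices make the within-sample distance undefined;
  the default is a hard error listing them, with an opt-in reduced
  network that records the dropped regions in metadata.

## Known limitations

- Subcortical structures are out of scope (no surface representation).
- The spin test assumes roughly spherical hemisphere geometry; centroids
  are projected to the unit sphere per hemisphere before rotation.
- The k > 1 estimator keeps the k = 1 additive constant; for large k
  this biases the estimate (documented, default k = 1).
- MSN z-scoring is per subject; cohort-level standardization variants
  are not implemented.
- Gene-expression preprocessing (probe selection, donor aggregation) is
  upstream of this package; the transcriptomics module consumes a ready
  genes × regions table.
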