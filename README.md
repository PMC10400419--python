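# mindnet

Cortical similarity networks from vertex-wise structural MRI morphometry.

Structural connectomics needs a way to quantify, within a single subject,
how anatomically similar every pair of cortical regions is. `mindnet`
implements **MIND** (Morphometric INverse Divergence): each region *r* is
treated as an empirical multivariate distribution *P<sub>r</sub>* of its
surface vertices' features (cortical thickness CT, surface area SA, gray
matter volume Vol, mean curvature MC, sulcal depth SD), and the edge
weight between regions *a* and *b* is

```
MIND(a, b) = 1 / (1 + D̂(P_a, P_b)),        D̂ = max(D̂_KL(P_a‖P_b), 0) + max(D̂_KL(P_b‖P_a), 0)
```

where each directed Kullback–Leibler divergence is estimated directly
from the samples by the k-nearest-neighbor estimator (no density
estimation step):

```
D̂_KL(P_a‖P_b) = -(d/n) Σ_i log( r_k(x_i) / s_k(x_i) ) + log( m / (n-1) )
```

with *r<sub>k</sub>(x<sub>i</sub>)* the distance from vertex
*x<sub>i</sub>* to its k-th nearest neighbor within region *a* (self
excluded), *s<sub>k</sub>(x<sub>i</sub>)* its k-th nearest neighbor in
region *b*, and *k* = 1 by default. Weights lie in (0, 1]; higher means
more similar.

The package also provides, for comparison and validation:

- **MSN** construction (the prior summary-statistic approach: Pearson
  correlation between regions' z-scored vectors of per-region summaries);
- network statistics: weighted degree, density thresholding,
  inter-hemispheric / within-cytoarchitectonic-class edge fractions over
  a density sweep, between-subject consistency, coarse-graining onto a
  parent parcellation, vertex-projected degree correlations;
- spatial-permutation ("spin") inference with mirrored rotations and
  Hungarian reassignment, for maps and for whole networks;
- tract-tracing comparison statistics (Fisher-averaged afferent/efferent
  profile correlations, edgewise bootstrap contrasts, log(FLNe) edge
  correlations with density sweeps);
- imaging transcriptomics: angular-similarity co-expression networks,
  structural–transcriptional coupling, PLS1 gene loadings, and
  median-rank cell-type enrichment with a spin-refit null;
- a synthetic-cortex generator whose Gaussian regional distributions give
  the exact similarity network in closed form — an end-to-end oracle.

Inputs are FreeSurfer per-vertex scalar ("curv") files with `.annot`
parcellations, or plain TSVs (`vertex_id`, `hemisphere`, `region`,
feature columns).

## Worked example

Simulate a small mirrored cortex (4 regions per hemisphere, 3 features,
300 vertices per region), estimate its MIND network, and compare with the
closed-form truth:

```python
import numpy as np
from scipy import stats
import mindnet as mn

spec = mn.SyntheticCortexSpec.create(R_per_hemisphere=4, d=3, n_r=300,
                                     mirror=True, seed=0)
table, parc = mn.generate_subject(spec)
net = mn.compute_mind(mn.split_regions(mn.standardize_features(table), parc))
truth = mn.ground_truth_mind(spec)

print("estimated L000-R000 (homotopic):",
      round(net.weights[0, 4], 3), " truth:", round(truth.weights[0, 4], 3))
print("Spearman(est, truth):",
      round(stats.spearmanr(net.upper_triangle(), truth.upper_triangle())[0], 3))
print("weighted degree:", np.round(mn.weighted_degree(net), 3))
```

```
estimated L000-R000 (homotopic): 0.839  truth: 1.0
Spearman(est, truth): 0.953
weighted degree: [0.551 0.562 0.29  0.372 0.475 0.492 0.29  0.384]
```

The homotopic edge (identical generating distributions in the two
hemispheres, true divergence 0) is estimated near the top of the weight
range — the finite-sample k-NN estimate of a zero divergence is positive,
so the estimated edge sits below the theoretical 1.0 — and the estimated
network ranks region pairs almost exactly as the closed form does.

The same pipeline is available from the shell:

```
mindnet simulate --regions-per-hemisphere 4 --n-vertices 300 --out sim/
mindnet mind --features sim/vertices.tsv --parcellation sim/parcellation.tsv --out net/
mindnet analyze --networks net/mind.tsv --parcellation sim/parcellation.tsv \
    --labels hemisphere --out stats/
```

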