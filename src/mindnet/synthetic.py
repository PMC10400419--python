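"""Synthetic cortices with closed-form ground truth.

Each synthetic region is a multivariate Gaussian over its vertices'
features, which is the one regional model whose symmetric KL divergence —
and hence whose true inverse-divergence similarity network — is available
in closed form, giving an exact oracle for the full estimation pipeline.
Hemispheres can be mirrored (homotopic regions share distribution
parameters), region centroids are laid out on per-hemisphere spheres by a
Fibonacci lattice for spin-test realism, and cytoarchitectonic class
labels are attached for edge-group analyses.  Generators for cohorts
(between-subject mean jitter) and gene-expression matrices with a planted
degree-coupled gene set complete the test bed.

What this emulates — and what it does not: vertices are i.i.d. within a
region, so there is no within-region spatial autocorrelation, no mesh
geometry, and no measurement artifacts; passing recovery tests shows
estimator correctness under the stated regional model, not robustness to
real acquisition noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import ParcellationScheme, VertexFeatureTable
from .divergence import gaussian_symmetric_kl
from .networks import SimilarityNetwork, mind_from_divergence
from .transcriptomics import GeneExpressionMatrix

MORPHOMETRIC_FEATURES = ["CT", "SA", "Vol", "MC", "SD"]
#: Plausible raw-unit baselines: thickness mm, per-vertex area mm²,
#: per-vertex volume mm³, curvature 1/mm, sulcal depth (dimensionless).
_MORPH_MEANS = np.array([2.5, 0.45, 1.1, 0.0, 0.0])
_MORPH_SCALES = np.array([0.35, 0.08, 0.22, 0.12, 0.5])

CYTO_CLASSES = ["primary_sensory", "secondary_sensory", "motor", "association", "limbic"]


def fibonacci_sphere(n: int, radius: float = 30.0) -> np.ndarray:
    """n roughly equidistant points on a sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return radius * pts


@dataclass
class SyntheticCortexSpec:
    """Ground-truth parameters of a synthetic two-hemisphere cortex."""

    region_ids: list
    hemispheres: list
    means: np.ndarray  # R × d
    covs: np.ndarray  # R × d × d
    n_r: np.ndarray  # vertices per region
    feature_names: list
    cyto_classes: list
    centroids: np.ndarray  # R × 3 (mm)
    mirror: bool
    seed: int

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)
        self.n_r = np.asarray(self.n_r, dtype=int)
        R, d = self.means.shape
        if self.covs.shape != (R, d, d):
            raise ValueError("covs must be R × d × d")
        for r in range(R):
            if not np.allclose(self.covs[r], self.covs[r].T):
                raise ValueError(f"covariance of region {self.region_ids[r]} not symmetric")
        if self.mirror:
            for i, j in self.homotopic_pairs():
                if not (np.allclose(self.means[i], self.means[j]) and np.allclose(self.covs[i], self.covs[j])):
                    raise ValueError("mirror=True requires identical homotopic parameters")

    @property
    def R(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (left region, its right-hemisphere counterpart)."""
        base = {}
        for i, rid in enumerate(self.region_ids):
            base.setdefault(str(rid)[1:], {})[self.hemispheres[i]] = i
        return [
            (d_["left"], d_["right"])
            for d_ in base.values()
            if "left" in d_ and "right" in d_
        ]

    def parcellation(self) -> ParcellationScheme:
        return ParcellationScheme(
            pd.DataFrame(
                {
                    "region_id": self.region_ids,
                    "name": self.region_ids,
                    "hemisphere": self.hemispheres,
                    "cyto_class": self.cyto_classes,
                    "x": self.centroids[:, 0],
                    "y": self.centroids[:, 1],
                    "z": self.centroids[:, 2],
                }
            )
        )

    @classmethod
    def create(
        cls,
        R_per_hemisphere: int = 10,
        d: int = 3,
        n_r: int = 200,
        separation: float = 1.0,
        mirror: bool = True,
        seed: int = 0,
        feature_names: list | None = None,
        morphometric: bool = False,
    ) -> "SyntheticCortexSpec":
        """Random spec: per-region Gaussians with mean spread ``separation``.

        With ``morphometric=True`` the five standard T1w features are
        produced on raw unit scales (so the vertex filter and regional
        summary statistics apply); otherwise features are generic with
        unit-scale covariances.
        """
        rng = np.random.default_rng(seed)
        if morphometric:
            d = 5
            feature_names = list(MORPHOMETRIC_FEATURES)
        elif feature_names is None:
            feature_names = [f"f{i + 1}" for i in range(d)]
        scales = _MORPH_SCALES if morphometric else np.ones(d)
        base = _MORPH_MEANS if morphometric else np.zeros(d)

        def one_hemisphere() -> tuple[np.ndarray, np.ndarray]:
            means = base + separation * scales * rng.normal(size=(R_per_hemisphere, d))
            covs = np.empty((R_per_hemisphere, d, d))
            for r in range(R_per_hemisphere):
                A = rng.normal(scale=0.25, size=(d, d))
                corr_jitter = A @ A.T
                covs[r] = np.diag(scales) @ (np.eye(d) + corr_jitter) @ np.diag(scales)
            return means, covs

        means_l, covs_l = one_hemisphere()
        if mirror:
            means_r, covs_r = means_l.copy(), covs_l.copy()
        else:
            means_r, covs_r = one_hemisphere()

        classes = [CYTO_CLASSES[i % len(CYTO_CLASSES)] for i in range(R_per_hemisphere)]
        pts = fibonacci_sphere(R_per_hemisphere)
        left_c = pts + np.array([-45.0, 0.0, 0.0])
        right_c = pts * np.array([-1.0, 1.0, 1.0]) + np.array([45.0, 0.0, 0.0])
        return cls(
            region_ids=[f"L{i:03d}" for i in range(R_per_hemisphere)]
            + [f"R{i:03d}" for i in range(R_per_hemisphere)],
            hemispheres=["left"] * R_per_hemisphere + ["right"] * R_per_hemisphere,
            means=np.vstack([means_l, means_r]),
            covs=np.concatenate([covs_l, covs_r]),
            n_r=np.full(2 * R_per_hemisphere, n_r),
            feature_names=feature_names,
            cyto_classes=classes + classes,
            centroids=np.vstack([left_c, right_c]),
            mirror=mirror,
            seed=seed,
        )


def generate_subject(
    spec: SyntheticCortexSpec, seed: int | None = None
) -> tuple[VertexFeatureTable, ParcellationScheme]:
    """Draw one subject: i.i.d. Gaussian vertices per region.

    Deterministic under a seed (``spec.seed`` unless overridden).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    counters = {"left": 0, "right": 0}
    for r in range(spec.R):
        try:
            chol = np.linalg.cholesky(spec.covs[r])
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"covariance of region {spec.region_ids[r]} is not positive definite"
            ) from err
        n = int(spec.n_r[r])
        X = spec.means[r] + rng.standard_normal((n, spec.d)) @ chol.T
        hemi = spec.hemispheres[r]
        df = pd.DataFrame(X, columns=spec.feature_names)
        df.insert(0, "region", spec.region_ids[r])
        df.insert(0, "hemisphere", hemi)
        df.insert(0, "vertex_id", np.arange(counters[hemi], counters[hemi] + n))
        counters[hemi] += n
        frames.append(df)
    table = VertexFeatureTable(pd.concat(frames, ignore_index=True), list(spec.feature_names))
    return table, spec.parcellation()


def ground_truth_mind(spec: SyntheticCortexSpec) -> SimilarityNetwork:
    """Exact similarity network via the Gaussian closed form for symmetric KL."""
    R = spec.R
    W = np.eye(R)
    for a in range(R):
        for b in range(a + 1, R):
            D = gaussian_symmetric_kl(spec.means[a], spec.covs[a], spec.means[b], spec.covs[b])
            W[a, b] = W[b, a] = mind_from_divergence(D)
    return SimilarityNetwork(W, list(spec.region_ids), method="MIND")


@dataclass
class SyntheticSubject:
    """One cohort member: its realized spec (jittered means) and data."""

    spec: SyntheticCortexSpec
    table: VertexFeatureTable
    parcellation: ParcellationScheme


def generate_cohort(
    spec: SyntheticCortexSpec,
    n_subjects: int,
    between_subject_jitter: float = 0.0,
    seed: int = 0,
) -> list[SyntheticSubject]:
    """Cohort of subjects sharing a spec up to per-subject mean jitter.

    With jitter 0 subjects differ only by vertex sampling noise; larger
    jitter perturbs regional means per subject (homotopic pairs jointly
    when the spec is mirrored, preserving its symmetry) and lowers
    expected between-subject edge consistency.  Each subject's own ground
    truth stays computable from its perturbed spec.
    """
    if between_subject_jitter < 0:
        raise ValueError("jitter must be nonnegative")
    rng = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        means = spec.means.copy()
        if between_subject_jitter > 0:
            shift = rng.normal(scale=between_subject_jitter, size=means.shape)
            if spec.mirror:
                for i, j in spec.homotopic_pairs():
                    shift[j] = shift[i]
            means = means + shift
        sub_spec = replace(spec, means=means)
        table, parc = generate_subject(sub_spec, seed=int(rng.integers(2**31)))
        subjects.append(SyntheticSubject(sub_spec, table, parc))
    return subjects


def generate_expression(
    degrees,
    G: int = 500,
    n_coupled: int = 25,
    effect: float = 1.0,
    seed: int = 0,
    region_ids: list | None = None,
) -> tuple[GeneExpressionMatrix, list]:
    """Expression matrix with ``n_coupled`` genes tracking network degree.

    Coupled genes are ``effect`` × standardized degree plus unit noise;
    the rest are pure unit noise.  Returns the matrix and the planted
    gene-set identifiers.
    """
    degrees = np.asarray(degrees, dtype=float)
    if not 0 <= n_coupled <= G:
        raise ValueError("need 0 <= n_coupled <= G")
    R = degrees.size
    rng = np.random.default_rng(seed)
    z = (degrees - degrees.mean()) / degrees.std(ddof=1) if np.ptp(degrees) else np.zeros(R)
    genes = [f"gene{i:05d}" for i in range(G)]
    values = rng.standard_normal((G, R))
    planted_idx = rng.choice(G, size=n_coupled, replace=False) if n_coupled else np.array([], dtype=int)
    values[planted_idx] += effect * z
    if region_ids is None:
        region_ids = [f"region{i:03d}" for i in range(R)]
    expr = GeneExpressionMatrix(pd.DataFrame(values, index=genes, columns=region_ids))
    return expr, [genes[i] for i in planted_idx]
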