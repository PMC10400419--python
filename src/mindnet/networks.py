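"""Construction of MIND and MSN similarity networks.

MIND (Morphometric INverse Divergence) treats each cortical region as a
multivariate distribution of its vertices' standardized features and sets
the edge weight between regions a and b to 1 / (1 + D̂(P_a, P_b)), where D̂
is the clamped symmetric k-NN KL divergence estimate.  Weights lie in
(0, 1]; higher means more similar.

MSN (Morphometric Similarity Network) is the prior summary-statistic
approach: each region is reduced to a vector of per-region summaries
(mean sulcal depth, mean thickness, total volume, total area, integrated
rectified mean curvature), each summary is z-scored across regions, and
the edge weight is the Pearson correlation of the two regional vectors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import RegionSample, VertexFeatureTable, ParcellationScheme, UNLABELED
from .divergence import symmetric_kl

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-12


@dataclass
class SimilarityNetwork:
    """Symmetric R × R similarity matrix with node identities.

    ``method`` is ``"MIND"`` (weights in (0, 1], diagonal stored as 1 and
    excluded from all statistics) or ``"MSN"`` (weights in [-1, 1],
    diagonal 1).
    """

    weights: np.ndarray
    node_ids: list
    method: str = "MIND"
    diagonal_convention: str = "one"
    dropped_regions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        R = len(self.node_ids)
        if self.weights.shape != (R, R):
            raise ValueError("weights shape must match node_ids length")
        if not np.allclose(self.weights, self.weights.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValueError("weights must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal edge weights, upper triangle, row-major.

        This fixed vectorization order makes edge vectors comparable
        across subjects sharing a node order.
        """
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_nodes, k=1)

    def reorder(self, node_ids: list) -> "SimilarityNetwork":
        idx = [self.node_ids.index(r) for r in node_ids]
        return SimilarityNetwork(
            self.weights[np.ix_(idx, idx)], list(node_ids), self.method,
            self.diagonal_convention, list(self.dropped_regions),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_ids, columns=self.node_ids)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "region_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, method: str = "MIND") -> "SimilarityNetwork":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns), method)

    def to_edge_list(self) -> pd.DataFrame:
        i, j = self.edge_index()
        return pd.DataFrame(
            {
                "region_a": [self.node_ids[a] for a in i],
                "region_b": [self.node_ids[b] for b in j],
                "weight": self.weights[i, j],
            }
        )


def mind_from_divergence(D: float) -> float:
    """Map a nonnegative divergence to similarity 1/(1+D) ∈ (0, 1]."""
    if D < 0:
        raise ValueError(f"divergence must be nonnegative, got {D}")
    return 1.0 / (1.0 + D)


def compute_mind(
    samples: list[RegionSample],
    k: int = 1,
    drop_undersized: bool = False,
) -> SimilarityNetwork:
    """MIND network over all unordered pairs of region samples.

    Every region needs more than ``k`` vertices for the within-sample
    neighbor distances to exist.  By default an undersized region is a
    hard error; with ``drop_undersized`` the offending regions are
    removed and recorded on the returned network.
    """
    undersized = [s.region_id for s in samples if s.n <= k]
    if undersized:
        if not drop_undersized:
            raise ValueError(
                f"regions with too few vertices (n <= k={k}): {undersized}; "
                "a complete MIND network cannot be computed "
                "(pass drop_undersized=True for a reduced network)"
            )
        logger.warning("compute_mind: dropping undersized regions %s", undersized)
        samples = [s for s in samples if s.n > k]
    R = len(samples)
    if R < 2:
        raise ValueError("need at least two usable regions")
    W = np.eye(R)
    for i, j in itertools.combinations(range(R), 2):
        est = symmetric_kl(samples[i].data, samples[j].data, k=k)
        W[i, j] = W[j, i] = mind_from_divergence(est.symmetric)
    return SimilarityNetwork(
        W, [s.region_id for s in samples], method="MIND",
        dropped_regions=list(undersized),
    )


#: Canonical morphometric summary roles and how each is aggregated.
MSN_FEATURES = ("SD", "CT", "Vol", "SA", "MC")


def regional_summaries(
    table: VertexFeatureTable,
    parc: ParcellationScheme,
    variant: str = "manual",
    precomputed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-region summary statistics on raw (unstandardized) features.

    ``manual`` reproduces the standard anatomical-stats outputs from the
    vertex table: mean SD, mean CT, total Vol, total SA, and integrated
    rectified mean curvature Σ_v |MC_v|·SA_v.  Any additional feature
    columns (e.g. appended noise features) are averaged within each
    region.  ``freesurfer_stats`` accepts a precomputed regions × features
    table instead.
    """
    if variant == "freesurfer_stats":
        if precomputed is None:
            raise ValueError("freesurfer_stats variant requires a precomputed table")
        missing = [r for r in parc.region_ids if r not in precomputed.index]
        if missing:
            raise ValueError(f"precomputed summaries missing regions: {missing}")
        return precomputed.loc[parc.region_ids]
    if variant != "manual":
        raise ValueError(f"unknown variant {variant!r}")

    core = [f for f in MSN_FEATURES if f in table.feature_names]
    extras = [f for f in table.feature_names if f not in MSN_FEATURES]
    rows = {}
    labeled = table.df[table.df["region"] != UNLABELED]
    grouped = dict(tuple(labeled.groupby("region", sort=False)))
    for rid in parc.region_ids:
        if rid not in grouped or len(grouped[rid]) == 0:
            raise ValueError(f"region {rid} has no vertices; cannot summarize")
        sub = grouped[rid]
        row = {}
        for feat in core:
            if feat in ("SD", "CT"):
                row[feat] = sub[feat].mean()
            elif feat in ("Vol", "SA"):
                row[feat] = sub[feat].sum()
            elif feat == "MC":
                if "SA" not in sub.columns:
                    raise ValueError("integrated rectified MC requires an SA column")
                row[feat] = float((sub["MC"].abs() * sub["SA"]).sum())
        for feat in extras:
            row[feat] = sub[feat].mean()
        rows[rid] = row
    return pd.DataFrame.from_dict(rows, orient="index").loc[parc.region_ids]


def compute_msn(
    summaries: pd.DataFrame | np.ndarray,
    node_ids: list | None = None,
    standardize: bool = True,
) -> SimilarityNetwork:
    """MSN from an R × F table of per-region summaries.

    Each feature column is z-scored across regions (within subject), then
    the edge weight between two regions is the Pearson correlation of
    their F-vectors.  ``standardize=False`` accepts rows that are already
    standardized.
    """
    if isinstance(summaries, pd.DataFrame):
        node_ids = list(summaries.index)
        X = summaries.to_numpy(dtype=float)
        names = list(summaries.columns)
    else:
        X = np.asarray(summaries, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
        if node_ids is None:
            node_ids = list(range(X.shape[0]))
    if X.shape[1] < 2:
        raise ValueError("MSN needs at least two features")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        bad = np.where(sd == 0)[0]
        if bad.size:
            raise ValueError(
                f"zero-variance features across regions: {[names[i] for i in bad]}"
            )
        Z = (X - X.mean(axis=0)) / sd
    else:
        Z = X
    W = np.corrcoef(Z)
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 1.0)
    return SimilarityNetwork(W, node_ids, method="MSN")


def add_noise_features(
    table: VertexFeatureTable, q: int, seed: int | np.random.Generator
) -> VertexFeatureTable:
    """Append ``q`` i.i.d. standard-normal feature columns per vertex.

    Used to probe resilience to uninformative features: for MIND the noise
    columns enter whole-brain standardization like any measured feature;
    for MSN they are region-averaged by :func:`regional_summaries` and
    z-scored across regions by :func:`compute_msn`.
    """
    if q < 0:
        raise ValueError("q must be nonnegative")
    if q == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    names = []
    for i in range(q):
        name = f"noise{i + 1}"
        df[name] = rng.standard_normal(len(df))
        names.append(name)
    return VertexFeatureTable(df, list(table.feature_names) + names)
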