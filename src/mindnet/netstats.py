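"""Network-level statistics for similarity connectomes.

Weighted degree, density thresholding, edge-group fractions across a
density sweep (e.g. inter-hemispheric or within-cytoarchitectonic-class
edges), between-subject consistency, and parcellation-consistency
analyses (coarse-graining a fine network onto parent regions and
projecting regional degree back to vertices).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ParcellationScheme, UNLABELED
from .networks import SimilarityNetwork

logger = logging.getLogger(__name__)

#: Default density sweep: 1% to 100% in 1% steps.
DEFAULT_DENSITIES = np.round(np.arange(0.01, 1.005, 0.01), 2)


@dataclass(frozen=True)
class DensityCurve:
    """A statistic traced over an increasing grid of network densities."""

    densities: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.shape != v.shape:
            raise ValueError("densities and values must have equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("densities must be strictly increasing")
        if np.any((d <= 0) | (d > 1)):
            raise ValueError("densities must lie in (0, 1]")
        object.__setattr__(self, "densities", d)
        object.__setattr__(self, "values", v)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"density": self.densities, "value": self.values})


def weighted_degree(net: SimilarityNetwork) -> np.ndarray:
    """Mean off-diagonal edge weight per node ("hubness")."""
    R = net.n_nodes
    if R < 2:
        raise ValueError("need at least two nodes")
    W = net.weights.copy()
    np.fill_diagonal(W, 0.0)
    return W.sum(axis=1) / (R - 1)


def threshold_top_density(net: SimilarityNetwork, density: float) -> np.ndarray:
    """Boolean R × R mask retaining the top-``density`` fraction of edges.

    Keeps the ⌈density·E⌉ largest upper-triangle off-diagonal edges
    (E = R(R-1)/2).  Ties at the boundary are broken deterministically by
    (weight desc, row asc, col asc) so the retained set is stable.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    R = net.n_nodes
    iu, ju = np.triu_indices(R, k=1)
    w = net.weights[iu, ju]
    E = w.size
    n_keep = int(np.ceil(density * E))
    if n_keep < 1:
        raise ValueError("density too small: no edges retained")
    order = np.lexsort((ju, iu, -w))  # weight desc, then (i, j) asc
    keep = order[:n_keep]
    mask = np.zeros((R, R), dtype=bool)
    mask[iu[keep], ju[keep]] = True
    return mask | mask.T


def grouped_edge_fraction(
    net: SimilarityNetwork,
    node_labels,
    predicate: str = "different_label",
    densities=DEFAULT_DENSITIES,
) -> DensityCurve:
    """Fraction of retained edges whose endpoints satisfy a label predicate.

    With hemisphere labels and ``different_label`` this is the
    inter-hemispheric edge fraction across densities; with
    cytoarchitectonic class labels and ``same_label`` it is the
    within-class fraction.
    """
    labels = np.asarray(pd.Series(node_labels), dtype=object)
    if labels.size != net.n_nodes:
        raise ValueError("one label per node required")
    if pd.isna(labels).any():
        raise ValueError("missing node labels")
    if predicate not in ("different_label", "same_label"):
        raise ValueError(f"unknown predicate {predicate!r}")
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    same = labels[iu] == labels[ju]
    qualifies = ~same if predicate == "different_label" else same
    densities = np.asarray(densities, dtype=float)
    values = []
    for dens in densities:
        mask = threshold_top_density(net, dens)
        kept = mask[iu, ju]
        values.append(float(qualifies[kept].sum() / kept.sum()))
    return DensityCurve(densities, np.asarray(values))


def between_subject_consistency(
    nets: list[SimilarityNetwork], level: str = "edge"
) -> tuple[np.ndarray, float]:
    """Pairwise Pearson correlations of networks across subjects.

    ``edge`` correlates vectorized upper triangles; ``degree`` correlates
    weighted-degree vectors.  Returns (pairwise correlations, mean).
    """
    if len(nets) < 2:
        raise ValueError("need at least two subjects")
    node_ids = nets[0].node_ids
    for net in nets[1:]:
        if net.node_ids != node_ids:
            raise ValueError("all networks must share the same node set and order")
    if level == "edge":
        vecs = [net.upper_triangle() for net in nets]
    elif level == "degree":
        vecs = [weighted_degree(net) for net in nets]
    else:
        raise ValueError(f"unknown level {level!r}")
    rs = np.array(
        [stats.pearsonr(vecs[i], vecs[j])[0] for i, j in itertools.combinations(range(len(nets)), 2)]
    )
    return rs, float(rs.mean())


def interpolate_to_parent(
    net_fine: SimilarityNetwork, parc_fine: ParcellationScheme
) -> SimilarityNetwork:
    """Coarse-grain a fine network onto parent regions.

    The parent edge (A, B), A ≠ B, is the mean over all fine edges with
    one endpoint in A and the other in B; fine edges within a single
    parent are ignored.  Exact on block-constant fine networks.
    """
    parents = parc_fine.parent_map()
    fine_parent = np.array([parents[r] for r in net_fine.node_ids], dtype=object)
    parent_ids = list(pd.unique(pd.Series(fine_parent)))
    P = len(parent_ids)
    idx_of = {p: np.where(fine_parent == p)[0] for p in parent_ids}
    W = np.eye(P)
    for a, b in itertools.combinations(range(P), 2):
        ia, ib = idx_of[parent_ids[a]], idx_of[parent_ids[b]]
        block = net_fine.weights[np.ix_(ia, ib)]
        if block.size == 0:
            raise ValueError(
                f"no fine edges between parents {parent_ids[a]} and {parent_ids[b]}"
            )
        W[a, b] = W[b, a] = float(block.mean())
    return SimilarityNetwork(W, parent_ids, method=net_fine.method)


def vertex_projected_degree_correlation(
    degrees_1,
    node_ids_1: list,
    degrees_2,
    node_ids_2: list,
    vertex_labels_1,
    vertex_labels_2,
    method: str = "pearson",
) -> float:
    """Correlate two parcellations' degree maps projected to vertices.

    Each vertex is assigned the weighted degree of the region containing
    it under each parcellation; the two vertex-length vectors are then
    correlated.  Vertices unlabeled under either scheme are excluded with
    a logged count.
    """
    lab1 = np.asarray(pd.Series(vertex_labels_1), dtype=object)
    lab2 = np.asarray(pd.Series(vertex_labels_2), dtype=object)
    if lab1.size != lab2.size:
        raise ValueError("vertex label maps must cover the same vertex set")
    deg1 = dict(zip(node_ids_1, np.asarray(degrees_1, dtype=float)))
    deg2 = dict(zip(node_ids_2, np.asarray(degrees_2, dtype=float)))
    ok = np.array(
        [(l1 in deg1) and (l2 in deg2) and UNLABELED not in (l1, l2) for l1, l2 in zip(lab1, lab2)]
    )
    excluded = int((~ok).sum())
    if excluded:
        logger.info(
            "vertex_projected_degree_correlation: excluding %d vertices covered by "
            "only one parcellation", excluded,
        )
    if ok.sum() < 3:
        raise ValueError("too few vertices covered by both parcellations")
    v1 = np.array([deg1[l] for l in lab1[ok]])
    v2 = np.array([deg2[l] for l in lab2[ok]])
    if method == "pearson":
        return float(stats.pearsonr(v1, v2)[0])
    if method == "spearman":
        return float(stats.spearmanr(v1, v2)[0])
    raise ValueError(f"unknown method {method!r}")
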