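"""Transcriptional similarity networks and imaging-transcriptomic coupling.

Regional gene-expression profiles (genes × regions) are compared with an
angular similarity metric τ = 1 - arccos(cos_sim)/π, which resolves
differences between high-dimensional, highly similar vectors better than
raw cosine or Pearson similarity.  The resulting co-expression network is
coupled to structural similarity networks at edge and degree level with
spin-permutation nulls; a PLS regression relates the expression matrix to
regional network degree, and cell-type gene sets are tested for
enrichment by their median rank in the PLS1 gene loading list, against a
null of PLS refits on spun degree maps.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .inference import SpinPermutationSet, spin_network, spin_pvalue
from .netstats import weighted_degree
from .networks import SimilarityNetwork


@dataclass
class GeneExpressionMatrix:
    """Normalized expression values, genes × regions, with no missing data."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def regions(self) -> list:
        return list(self.values.columns)

    @property
    def G(self) -> int:
        return len(self.values.index)

    @classmethod
    def from_tsv(cls, path) -> "GeneExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def angular_similarity(x, y) -> float:
    """τ(x, y) = 1 - arccos(x·y / (‖x‖‖y‖)) / π, in [0, 1].

    1 for positively proportional vectors, 0.5 for orthogonal, 0 for
    antiparallel; invariant to positive rescaling of either argument.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("angular similarity undefined for zero-norm vectors")
    u, v = x / nx, y / ny
    # Kahan's formula: well-conditioned near parallel/antiparallel, where
    # arccos of the clipped cosine loses all precision.
    angle = 2.0 * np.arctan2(np.linalg.norm(u - v), np.linalg.norm(u + v))
    return float(1.0 - angle / np.pi)


def coexpression_network(expr: GeneExpressionMatrix) -> SimilarityNetwork:
    """Transcriptional similarity network: τ between regional profiles."""
    if expr.G < 2:
        raise ValueError("need at least two genes")
    X = expr.values.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=0)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero expression for regions: {[expr.regions[i] for i in zero]}")
    R = X.shape[1]
    W = np.eye(R)
    for a, b in itertools.combinations(range(R), 2):
        W[a, b] = W[b, a] = angular_similarity(X[:, a], X[:, b])
    return SimilarityNetwork(W, expr.regions, method="coexpression")


def coupling(
    net_struct: SimilarityNetwork,
    net_gene: SimilarityNetwork,
    level: str = "edge",
    method: str = "pearson",
    spins: SpinPermutationSet | None = None,
) -> tuple[float, float | None]:
    """Structural-transcriptional coupling at edge or degree level.

    Returns (correlation, spin p) — the p-value uses a two-sided r² null
    built by rotating the whole structural network (edge level) or the
    structural degree map (degree level); None when no spins are given.
    """
    if net_struct.node_ids != net_gene.node_ids:
        raise ValueError("networks must share the same region set and order")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if level == "edge":
        x, y = net_struct.upper_triangle(), net_gene.upper_triangle()
    elif level == "degree":
        x, y = weighted_degree(net_struct), weighted_degree(net_gene)
    else:
        raise ValueError(f"unknown level {level!r}")
    r = float(corr(x, y)[0])
    if spins is None:
        return r, None
    if level == "degree":
        stat = "r2_pearson" if method == "pearson" else "r2_spearman"
        return r, spin_pvalue(x, y, spins, statistic=stat)
    observed = r**2
    null = np.empty(spins.n_perm)
    for i, perm in enumerate(spins.permutations):
        spun = spin_network(net_struct, perm).upper_triangle()
        null[i] = corr(spun, y)[0] ** 2
    return r, float(np.mean(null >= observed))


@dataclass
class PLSResult:
    """First-component summary of a PLS fit of expression onto degree."""

    loadings: pd.Series  # per-gene PLS1 weight, sign-fixed
    ranks: pd.Series  # 1..G, rank 1 = most positively degree-associated
    covariance_explained: float | None
    scores: np.ndarray  # regional PLS1 scores


def _rank_loadings(loadings: pd.Series) -> pd.Series:
    """Ranks 1..G, descending loading, ties broken by gene identifier."""
    order = sorted(loadings.index, key=lambda g: (-loadings[g], str(g)))
    return pd.Series(np.arange(1, len(order) + 1), index=order).loc[loadings.index]


def pls1(
    expr: GeneExpressionMatrix,
    y,
    explained: str | None = "covariance",
) -> PLSResult:
    """PLS regression of regional expression onto a regional map.

    X is the regions × genes matrix, y the regional map (e.g. weighted
    degree); both are centered internally.  The first component's sign is
    fixed so its regional scores correlate positively with y — lower gene
    rank then means stronger positive association with the map.

    ``explained`` selects how the explained fraction is defined:
    ``"covariance"`` (squared X-y covariance captured by component 1 over
    the total across all components), ``"x_variance"`` (fraction of X
    variance carried by component 1), or None to skip (cheapest; only the
    first component is fitted).
    """
    y = np.asarray(y, dtype=float)
    X = expr.values.to_numpy(dtype=float).T  # regions × genes
    R, G = X.shape
    if R < 3:
        raise ValueError("need at least three regions")
    if y.size != R:
        raise ValueError("map length must equal region count")
    if np.ptp(y) == 0:
        raise ValueError("constant map: PLS undefined")

    n_comp_total = min(R - 1, G)
    n_fit = 1 if explained is None else n_comp_total
    pls = PLSRegression(n_components=n_fit, scale=False)
    with warnings.catch_warnings():
        # with a single response the y residual vanishes once the fit is
        # complete; later components carry ~zero covariance by design
        warnings.filterwarnings("ignore", message=".*residual is constant.*")
        pls.fit(X, y)
    w1 = pls.x_weights_[:, 0].copy()
    t = pls.x_scores_
    t1 = t[:, 0].copy()
    if np.ptp(t1) != 0 and stats.pearsonr(t1, y)[0] < 0:
        w1, t1 = -w1, -t1

    cov_explained: float | None
    if explained is None:
        cov_explained = None
    elif explained == "covariance":
        yc = y - y.mean()
        covs = np.array([abs(np.cov(t[:, i], yc, ddof=1)[0, 1]) for i in range(n_fit)])
        cov_explained = float(covs[0] ** 2 / np.sum(covs**2))
    elif explained == "x_variance":
        Xc = X - X.mean(axis=0)
        total = float((Xc**2).sum())
        p1 = pls.x_loadings_[:, 0]
        cov_explained = float((np.outer(t[:, 0], p1) ** 2).sum() / total)
    else:
        raise ValueError(f"unknown explained definition {explained!r}")

    loadings = pd.Series(w1, index=expr.genes)
    return PLSResult(loadings, _rank_loadings(loadings), cov_explained, t1)


@dataclass
class EnrichmentResult:
    """Median-rank enrichment of one gene set in the PLS1 gene list."""

    gene_set: str
    observed_median_rank: float
    null_median_ranks: np.ndarray
    p_value: float
    p_fdr: float = float("nan")


def median_rank_enrichment(
    ranks: pd.Series,
    gene_sets: dict,
    y,
    expr: GeneExpressionMatrix,
    spins: SpinPermutationSet,
    fdr: bool = True,
) -> list[EnrichmentResult]:
    """Two-sided spin-refit test of gene-set median rank in PLS1 loadings.

    For each spatial permutation of the regional map, a fresh PLS model is
    fitted (sign convention re-applied against the permuted map) and each
    set's median rank recomputed.  p is the fraction of permutations whose
    median rank is at least as far from the global median position
    (G+1)/2 as the observed one; Benjamini–Hochberg correction across
    sets.
    """
    y = np.asarray(y, dtype=float)
    universe = set(ranks.index)
    for name, genes in gene_sets.items():
        if len(genes) == 0:
            raise ValueError(f"gene set {name!r} is empty")
        missing = set(genes) - universe
        if missing:
            raise ValueError(f"gene set {name!r} has genes outside the universe: {sorted(missing)[:5]}")
    G = len(ranks)
    global_median = (G + 1) / 2.0

    null = {name: np.empty(spins.n_perm) for name in gene_sets}
    for i, perm in enumerate(spins.permutations):
        res = pls1(expr, y[perm], explained=None)
        for name, genes in gene_sets.items():
            null[name][i] = float(res.ranks.loc[list(genes)].median())

    results = []
    for name, genes in gene_sets.items():
        observed = float(ranks.loc[list(genes)].median())
        dev = abs(observed - global_median)
        p = float(np.mean(np.abs(null[name] - global_median) >= dev))
        results.append(EnrichmentResult(name, observed, null[name], p))
    if fdr and results:
        rejected, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for res, padj in zip(results, p_adj):
            res.p_fdr = float(padj)
    return results
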