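"""Spatial-permutation ("spin") nulls and tract-tracing comparison statistics.

Cortical maps are spatially autocorrelated, so naive permutation nulls are
anticonservative.  The spin test instead rotates parcel centroids on the
sphere and reassigns regions one-to-one by minimum-total-distance
(Hungarian) matching, producing permutations that respect the spatial
embedding.  The same rotation, x-mirrored, is applied to the right
hemisphere so bilateral symmetry is maintained, and within-hemisphere
indices map within hemisphere.  Networks are "spun" by applying one such
permutation to both rows and columns.

Also provided: the Fisher-averaged afferent/efferent profile correlation
and the edgewise bootstrap used to compare two similarity networks
against tract-tracing connectivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .netstats import DensityCurve, weighted_degree
from .networks import SimilarityNetwork

logger = logging.getLogger(__name__)


@dataclass
class SpinPermutationSet:
    """P × R matrix of region-index bijections, reproducible from a seed."""

    permutations: np.ndarray
    seed: int | None = None
    n_perm: int = 0

    def __post_init__(self) -> None:
        self.permutations = np.asarray(self.permutations, dtype=int)
        if self.permutations.ndim != 2:
            raise ValueError("permutations must be P × R")
        self.n_perm = self.permutations.shape[0]
        R = self.permutations.shape[1]
        ref = np.arange(R)
        for row in self.permutations:
            if not np.array_equal(np.sort(row), ref):
                raise ValueError("each spin row must be a bijection of region indices")

    @property
    def n_regions(self) -> int:
        return self.permutations.shape[1]


def _unit_sphere(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate centroid at the hemisphere center")
    return centered / norms


def generate_spins(
    centroids: np.ndarray,
    hemispheres,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    rotations: list | None = None,
) -> SpinPermutationSet:
    """Spin permutations from parcel centroids with mirrored rotations.

    Per permutation a uniform random 3-D rotation is applied to the
    left-hemisphere centroids (projected to the unit sphere per
    hemisphere) and its x-mirrored counterpart to the right; regions are
    then reassigned one-to-one within hemisphere by Hungarian matching on
    Euclidean cost.  ``rotations`` overrides the random rotations (test
    hook; e.g. identity matrices yield identity permutations).
    """
    centroids = np.asarray(centroids, dtype=float)
    if not np.isfinite(centroids).all():
        raise ValueError("centroids must be finite")
    hemi = np.asarray(pd.Series(hemispheres), dtype=object)
    R = centroids.shape[0]
    mirror = np.diag([-1.0, 1.0, 1.0])
    groups = {}
    for h in ("left", "right"):
        idx = np.where(hemi == h)[0]
        if idx.size and idx.size < 2:
            raise ValueError(f"hemisphere {h!r} needs at least 2 regions")
        if idx.size:
            groups[h] = (idx, _unit_sphere(centroids[idx]))
    if not groups:
        raise ValueError("no left/right hemisphere labels found")
    rng = np.random.default_rng(seed)
    if rotations is None:
        rotations = [Rotation.random(rng=rng).as_matrix() for _ in range(n_perm)]
    perms = np.empty((len(rotations), R), dtype=int)
    for p, rot in enumerate(rotations):
        perm = np.arange(R)
        for h, (idx, unit) in groups.items():
            rot_h = rot if h == "left" else mirror @ rot @ mirror
            rotated = unit @ rot_h.T
            # cost[i, j]: rotated region i vs original site j; the region
            # assigned to site j supplies site j's permuted value.
            cost = cdist(rotated, unit)
            row_ind, col_ind = linear_sum_assignment(cost)
            perm[idx[col_ind]] = idx[row_ind]
        perms[p] = perm
    return SpinPermutationSet(
        perms, seed=seed if isinstance(seed, int) else None, n_perm=len(rotations)
    )


def _r2_rows(spun: np.ndarray, y: np.ndarray, spearman: bool) -> np.ndarray:
    """Squared correlation of each row of ``spun`` with ``y``, vectorized."""
    if spearman:
        y = stats.rankdata(y)
        spun = np.apply_along_axis(stats.rankdata, 1, spun)
    yc = y - y.mean()
    sc = spun - spun.mean(axis=1, keepdims=True)
    denom = np.sqrt((sc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sc @ yc / denom
    return r**2


def spin_pvalue(
    map_a,
    map_b,
    spins: SpinPermutationSet,
    statistic: str = "r2_pearson",
) -> float:
    """Two-sided spin p for the association between two regional maps.

    p is the plain fraction of permutations whose r² between the spun
    ``map_a`` and ``map_b`` reaches the observed r² (minimum attainable
    p is 0; no +1 smoothing).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.size != spins.n_regions or b.size != spins.n_regions:
        raise ValueError("maps must live on the spin set's region set")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    spearman = statistic == "r2_spearman"
    if statistic not in ("r2_pearson", "r2_spearman"):
        raise ValueError(f"unknown statistic {statistic!r}")
    observed = _r2_rows(a[None, :], b, spearman)[0]
    null = _r2_rows(a[spins.permutations], b, spearman)
    return float(np.mean(null >= observed))


def spin_network(net: SimilarityNetwork, permutation) -> SimilarityNetwork:
    """Rotate an entire network: permute rows and columns by one bijection."""
    perm = np.asarray(permutation, dtype=int)
    if perm.size != net.n_nodes:
        raise ValueError("permutation length must equal node count")
    W = net.weights[np.ix_(perm, perm)]
    return SimilarityNetwork(W, list(net.node_ids), net.method, net.diagonal_convention)


def fisher_mean(r1: float, r2: float) -> float:
    """Average two correlations on the Fisher-z scale: tanh((z1+z2)/2)."""
    rs = []
    for r in (r1, r2):
        if abs(r) >= 1:
            warnings.warn("|r| = 1 clamped for Fisher transform", RuntimeWarning, stacklevel=2)
            r = np.sign(r) * (1 - 1e-12)
        rs.append(r)
    return float(np.tanh((np.arctanh(rs[0]) + np.arctanh(rs[1])) / 2.0))


def profile_correlation(similarity_profile, afferent, efferent) -> float:
    """Fisher-averaged correlation of a similarity profile with a region's
    afferent and efferent tract-tracing profiles.

    Missing tract entries (NaN) are excluded pairwise before each Pearson
    correlation; the two correlations are then combined on the Fisher-z
    scale.
    """
    sim = np.asarray(similarity_profile, dtype=float)
    rs = []
    for tract in (afferent, efferent):
        t = np.asarray(tract, dtype=float)
        if t.size != sim.size:
            raise ValueError("profiles must share an index set")
        ok = np.isfinite(t) & np.isfinite(sim)
        if ok.sum() < 3:
            raise ValueError("too few measured entries in tract profile")
        rs.append(stats.pearsonr(sim[ok], t[ok])[0])
    return fisher_mean(rs[0], rs[1])


@dataclass
class BootstrapResult:
    p_value: float
    deltas: np.ndarray
    observed_delta: float
    degenerate: bool = False
    n_redrawn: int = 0


def edge_bootstrap_compare(
    tract,
    sim_1,
    sim_2,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    alternative: str = "one_sided",
) -> BootstrapResult:
    """Edgewise bootstrap test that ``sim_1`` outcorrelates ``sim_2``.

    Per resample of edges (with replacement):
    delta = corr(tract, sim_1) - corr(tract, sim_2).  The one-sided p
    (null: sim_1 does not correlate more strongly) is the fraction of
    deltas below 0; ``two_sided`` doubles the smaller tail.  Resamples in
    which any vector is constant are redrawn with a logged count.
    """
    t = np.asarray(tract, dtype=float)
    s1 = np.asarray(sim_1, dtype=float)
    s2 = np.asarray(sim_2, dtype=float)
    if not (t.size == s1.size == s2.size):
        raise ValueError("edge vectors must be aligned")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    E = t.size
    observed = stats.pearsonr(t, s1)[0] - stats.pearsonr(t, s2)[0]
    deltas = np.empty(n_boot)
    n_redrawn = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, E, size=E)
            tb, s1b, s2b = t[idx], s1[idx], s2[idx]
            if np.ptp(tb) == 0 or np.ptp(s1b) == 0 or np.ptp(s2b) == 0:
                n_redrawn += 1
                continue
            break
        deltas[i] = stats.pearsonr(tb, s1b)[0] - stats.pearsonr(tb, s2b)[0]
    if n_redrawn:
        logger.info("edge_bootstrap_compare: redrew %d degenerate resamples", n_redrawn)
    degenerate = bool(np.all(deltas == 0))
    if degenerate:
        logger.warning("edge_bootstrap_compare: all bootstrap deltas are exactly 0")
    frac_below = float(np.mean(deltas < 0))
    if alternative == "one_sided":
        p = frac_below
    elif alternative == "two_sided":
        p = min(1.0, 2.0 * min(frac_below, float(np.mean(deltas > 0))))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return BootstrapResult(p, deltas, observed, degenerate, n_redrawn)


def tract_edge_correlation(
    tract: pd.DataFrame,
    sim: SimilarityNetwork,
    densities=None,
    method: str = "pearson",
):
    """Correlate tract-tracing weights with similarity edge weights.

    ``tract`` is a (possibly rectangular) targets × sources frame of
    log-transformed connection weights; NaN marks unmeasured pairs, which
    are excluded (distinct from measured-zero, which the caller encodes
    as a finite weight or NaN by policy).  Each measured directed entry
    (i → j), i ≠ j, is paired with the single undirected similarity edge.
    With ``densities`` the tract network is thresholded to its top-weight
    fraction at each density and the correlation recomputed.
    """
    node_pos = {r: i for i, r in enumerate(sim.node_ids)}
    t_vals, s_vals = [], []
    for target in tract.index:
        for source in tract.columns:
            if target == source:
                continue
            w = tract.loc[target, source]
            if pd.isna(w) or target not in node_pos or source not in node_pos:
                continue
            t_vals.append(float(w))
            s_vals.append(sim.weights[node_pos[target], node_pos[source]])
    if len(t_vals) < 3:
        raise ValueError("no (or too few) overlapping measured edges")
    t_arr = np.asarray(t_vals)
    s_arr = np.asarray(s_vals)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    if densities is None:
        return float(corr(t_arr, s_arr)[0])
    densities = np.asarray(densities, dtype=float)
    order = np.argsort(-t_arr, kind="stable")
    values = []
    for dens in densities:
        if not (0 < dens <= 1):
            raise ValueError("densities must lie in (0, 1]")
        keep = order[: int(np.ceil(dens * t_arr.size))]
        if keep.size < 3:
            raise ValueError(f"density {dens} leaves too few edges")
        values.append(float(corr(t_arr[keep], s_arr[keep])[0]))
    return DensityCurve(densities, np.asarray(values))
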