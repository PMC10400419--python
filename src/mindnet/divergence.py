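"""k-nearest-neighbor estimation of symmetric Kullback-Leibler divergence.

Given two empirical samples ``a`` (n × d) and ``b`` (m × d) regarded as
draws from continuous distributions P_a and P_b, the divergence
D_KL(P_a ‖ P_b) is estimated without any density estimation step, directly
from nearest-neighbor distances (Perez-Cruz estimator):

    D̂ = -(d/n) Σ_i log( r_k(x_i) / s_k(x_i) ) + log( m / (n-1) )

where r_k(x_i) is the Euclidean distance from x_i to its k-th nearest
neighbor within ``a`` (excluding x_i itself) and s_k(x_i) to its k-th
nearest neighbor within ``b``.  The bias-correction constant log(m/(n-1))
is used verbatim for every k; natural logarithms throughout (nats).

Because the estimate of a true divergence near zero can come out slightly
negative, each direction is clamped at zero before forming the symmetric
(Jeffreys) divergence d_ab + d_ba.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

#: Distances below this floor (exact duplicates up to rounding) are clamped
#: to it so the log stays finite; inert for continuous MRI features.
EPS_DISTANCE = 1e-12


@dataclass(frozen=True)
class KLEstimate:
    """Clamped directed estimates and their symmetric sum."""

    d_ab: float
    d_ba: float
    symmetric: float
    k: int
    n: int
    m: int


def _validate(a: np.ndarray, b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("samples must be 2-D (n × d)")
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if k < 1:
        raise ValueError("k must be a positive integer")
    n, m = a.shape[0], b.shape[0]
    if n <= k:
        raise ValueError(f"need n > k for within-sample neighbors (n={n}, k={k})")
    if m < k:
        raise ValueError(f"need m >= k for cross-sample neighbors (m={m}, k={k})")
    return a, b


def _clamp_distances(dist: np.ndarray) -> np.ndarray:
    small = dist < EPS_DISTANCE
    if small.any():
        warnings.warn(
            f"{int(small.sum())} near-zero neighbor distances clamped to {EPS_DISTANCE} "
            "(duplicate points)",
            RuntimeWarning,
            stacklevel=3,
        )
        dist = np.maximum(dist, EPS_DISTANCE)
    return dist


def knn_kl(sample_a: np.ndarray, sample_b: np.ndarray, k: int = 1) -> float:
    """Raw (unclamped) k-NN estimate of D_KL(P_a ‖ P_b), kd-tree accelerated."""
    a, b, = _validate(sample_a, sample_b, k)
    n, m = a.shape[0], b.shape[0]
    d = a.shape[1]
    # k+1 within a: the nearest hit is the query point itself (distance 0).
    r = cKDTree(a).query(a, k=k + 1)[0][:, k]
    s = cKDTree(b).query(a, k=k)[0]
    if k > 1:
        s = s[:, k - 1]
    s = np.ravel(s)
    r = _clamp_distances(r)
    s = _clamp_distances(s)
    return float(-(d / n) * np.sum(np.log(r / s)) + np.log(m / (n - 1)))


def knn_kl_bruteforce(sample_a: np.ndarray, sample_b: np.ndarray, k: int = 1) -> float:
    """Oracle estimator via exhaustive pairwise distances (no spatial index).

    Intended for small inputs; contractually identical to :func:`knn_kl`.
    """
    a, b = _validate(sample_a, sample_b, k)
    n, m = a.shape[0], b.shape[0]
    d = a.shape[1]
    daa = cdist(a, a)
    np.fill_diagonal(daa, np.inf)  # exclude self
    r = np.sort(daa, axis=1)[:, k - 1]
    s = np.sort(cdist(a, b), axis=1)[:, k - 1]
    r = _clamp_distances(r)
    s = _clamp_distances(s)
    return float(-(d / n) * np.sum(np.log(r / s)) + np.log(m / (n - 1)))


def symmetric_kl(sample_a: np.ndarray, sample_b: np.ndarray, k: int = 1) -> KLEstimate:
    """Clamped symmetric (Jeffreys) divergence estimate between two samples.

    Each direction is floored at zero, so the result is invariant under
    swapping the samples and always nonnegative.
    """
    a, b = _validate(sample_a, sample_b, k)
    # both directions need their own preconditions
    _validate(b, a, k)
    d_ab = max(knn_kl(a, b, k), 0.0)
    d_ba = max(knn_kl(b, a, k), 0.0)
    return KLEstimate(
        d_ab=d_ab,
        d_ba=d_ba,
        symmetric=d_ab + d_ba,
        k=k,
        n=a.shape[0],
        m=b.shape[0],
    )


def gaussian_kl(mu_a, cov_a, mu_b, cov_b) -> float:
    """Closed-form D_KL(N_a ‖ N_b) between multivariate Gaussians (nats).

    ½ [ tr(Σ_b⁻¹Σ_a) + (μ_b-μ_a)ᵀ Σ_b⁻¹ (μ_b-μ_a) - d + ln(det Σ_b / det Σ_a) ]
    """
    mu_a = np.atleast_1d(np.asarray(mu_a, dtype=float))
    mu_b = np.atleast_1d(np.asarray(mu_b, dtype=float))
    cov_a = np.atleast_2d(np.asarray(cov_a, dtype=float))
    cov_b = np.atleast_2d(np.asarray(cov_b, dtype=float))
    d = mu_a.size
    sign_b, logdet_b = np.linalg.slogdet(cov_b)
    sign_a, logdet_a = np.linalg.slogdet(cov_a)
    if sign_a <= 0 or sign_b <= 0:
        raise np.linalg.LinAlgError("covariance matrices must be positive definite")
    solve_b = np.linalg.solve(cov_b, cov_a)
    diff = mu_b - mu_a
    maha = diff @ np.linalg.solve(cov_b, diff)
    return float(0.5 * (np.trace(solve_b) + maha - d + logdet_b - logdet_a))


def gaussian_symmetric_kl(mu_a, cov_a, mu_b, cov_b) -> float:
    """Closed-form symmetric KL divergence between two Gaussians."""
    return gaussian_kl(mu_a, cov_a, mu_b, cov_b) + gaussian_kl(mu_b, cov_b, mu_a, cov_a)
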