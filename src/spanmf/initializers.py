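"""Baseline NMF initializers: repetitive random, NNDSVD and fuzzy c-means.

These are the comparison points for SPA initialization.  Random and FCM are
non-deterministic and are meant to be used under restart orchestration
(:func:`spanmf.solvers.run_with_restarts`); NNDSVD is deterministic up to the
SVD sign convention, which is fixed here so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy.linalg import svd

from .matrix import InitFactors, as_feature_matrix

__all__ = [
    "random_init",
    "nndsvd_init",
    "fcm_cluster",
    "fcm_init",
    "FcmResult",
    "NndsvdDecomposition",
]


def random_init(m: int, n: int, r: int, seed: int) -> InitFactors:
    """Uniform(0, 1) random initialization of both factors, reproducible per seed."""
    rng = np.random.default_rng(seed)
    W0 = rng.uniform(0.0, 1.0, size=(m, r))
    H0 = rng.uniform(0.0, 1.0, size=(r, n))
    return InitFactors(W0=W0, H0=H0, method="random", seed=seed)


@dataclass
class NndsvdDecomposition:
    """Bookkeeping for the truncated-SVD construction behind NNDSVD.

    ``triplet_factors[i]`` holds the non-negative unit directions
    ``(u_hat, v_hat)`` chosen from the positive-part split of singular
    component ``i``, together with the combined weight ``mu`` such that the
    rank-1 term is ``sqrt(sigma_i * mu) u_hat`` times ``sqrt(sigma_i * mu) v_hat^T``.
    """

    singular_values: npt.NDArray[np.floating]
    triplet_factors: list[tuple[npt.NDArray[np.floating], npt.NDArray[np.floating], float]]


def _fix_sign(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # orient so the largest-magnitude entry of u is positive (determinism)
    k = int(np.argmax(np.abs(u)))
    if u[k] < 0:
        return -u, -v
    return u, v


def nndsvd_init(X, r: int, *, zero_fix: bool = True) -> InitFactors:
    """Non-negative double SVD initialization with a 1%-of-mean zero fix.

    The leading singular triplet of a non-negative matrix is non-negative up
    to sign and is used directly.  For components ``i >= 2`` the singular
    vectors are split into positive and negative parts; of the two candidate
    non-negative rank-1 terms, the one with the larger product of factor
    norms (the dominant triplet of the positive part ``C_i+``) is kept and
    rescaled to carry the component's energy.  Because several NMF updates
    (multiplicative rules, the squared-variable gradient solver) leave zero
    entries at zero forever, every remaining zero of ``W0`` (resp. ``H0``)
    is then replaced by 1% of the mean of its positive entries.
    """
    fm = as_feature_matrix(X)
    A = fm.data
    m, n = A.shape
    if r < 1 or r > min(m, n):
        raise ValueError(f"r={r} out of range for a {m}x{n} matrix")
    U, s, Vt = svd(A, full_matrices=False)
    W0 = np.zeros((m, r))
    H0 = np.zeros((r, n))
    triplets = []
    for i in range(r):
        u, v = _fix_sign(U[:, i], Vt[i])
        if i == 0:
            # leading triplet of a non-negative matrix is non-negative (Perron-Frobenius)
            u_hat, v_hat = np.abs(u), np.abs(v)
            mu = 1.0
        else:
            up, un = np.maximum(u, 0.0), np.maximum(-u, 0.0)
            vp, vn = np.maximum(v, 0.0), np.maximum(-v, 0.0)
            norm_p = np.linalg.norm(up) * np.linalg.norm(vp)
            norm_n = np.linalg.norm(un) * np.linalg.norm(vn)
            if norm_p >= norm_n:
                uu, vv, mu = up, vp, norm_p
            else:
                uu, vv, mu = un, vn, norm_n
            if mu == 0.0:
                triplets.append((np.zeros(m), np.zeros(n), 0.0))
                continue  # degenerate component stays zero until zero-fix
            u_hat, v_hat = uu / np.linalg.norm(uu), vv / np.linalg.norm(vv)
        triplets.append((u_hat, v_hat, mu))
        W0[:, i] = np.sqrt(s[i] * mu) * u_hat
        H0[i] = np.sqrt(s[i] * mu) * v_hat
    if zero_fix:
        for M in (W0, H0):
            pos = M[M > 0]
            if pos.size:
                M[M == 0] = 0.01 * pos.mean()
    return InitFactors(W0=W0, H0=H0, method="nndsvd", seed=None)


@dataclass
class FcmResult:
    """Fuzzy c-means output: centroids (c x m), memberships (c x n) with
    columns summing to one, the non-increasing objective trace and the
    iteration count."""

    centroids: npt.NDArray[np.floating]
    memberships: npt.NDArray[np.floating]
    objective_trace: list[float]
    n_iter: int


def fcm_cluster(
    points,
    c: int,
    *,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FcmResult:
    """Fuzzy c-means with Euclidean distance and random initial memberships.

    Each point belongs to every cluster with a membership in [0, 1];
    memberships follow the classical inverse-distance rule with exponent
    ``2 / (fuzzifier - 1)`` and centroids are membership^fuzzifier-weighted
    means.  Iterates until the largest membership change drops below ``tol``
    or ``max_iter`` is reached.  A point coincident with a centroid gets an
    indicator membership on its nearest coincident centroid (standard
    singularity handling).
    """
    P = np.asarray(points, dtype=float)  # n x m
    if P.ndim != 2:
        raise ValueError("points must be 2-D (n_points x n_features)")
    n = P.shape[0]
    if c < 1 or c > n:
        raise ValueError(f"c={c} out of range for {n} points")
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier must be > 1")
    rng = np.random.default_rng(seed)
    U = rng.uniform(size=(c, n))
    U /= U.sum(axis=0, keepdims=True)
    expo = 2.0 / (fuzzifier - 1.0)
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        Um = U**fuzzifier
        centroids = (Um @ P) / Um.sum(axis=1, keepdims=True)
        # squared distances point j -> centroid k
        d2 = (
            np.sum(centroids**2, axis=1)[:, None]
            - 2.0 * centroids @ P.T
            + np.sum(P**2, axis=1)[None, :]
        )
        d2 = np.maximum(d2, 0.0)
        trace.append(float(np.sum(Um * d2)))
        coincident = d2 < 1e-30
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo / 2.0)
            U_new = inv / inv.sum(axis=0, keepdims=True)
        sing = coincident.any(axis=0)
        if sing.any():
            U_new[:, sing] = 0.0
            U_new[np.argmax(coincident[:, sing], axis=0), np.flatnonzero(sing)] = 1.0
        shift = float(np.max(np.abs(U_new - U)))
        U = U_new
        if shift < tol:
            break
    Um = U**fuzzifier
    centroids = (Um @ P) / Um.sum(axis=1, keepdims=True)
    return FcmResult(centroids=centroids, memberships=U, objective_trace=trace, n_iter=it)


def fcm_init(
    X,
    r: int,
    seed: int,
    *,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> InitFactors:
    """FCM initialization: cluster the voxels, centroids -> ``W0`` columns,
    membership rows -> ``H0``."""
    fm = as_feature_matrix(X)
    res = fcm_cluster(
        fm.data.T, r, fuzzifier=fuzzifier, tol=tol, max_iter=max_iter, seed=seed
    )
    W0 = np.maximum(res.centroids.T, 0.0)  # guard FP round-off on non-negative data
    return InitFactors(W0=W0, H0=res.memberships, method="fcm", seed=seed)
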