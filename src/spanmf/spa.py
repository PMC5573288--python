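"""Successive projection algorithm (SPA) and the initializations derived from it.

SPA is a greedy column-selection method rooted in convex geometry: under the
near-separable assumption (every source appears pure in at least one voxel
and abundances sum to at most one), the data columns span a convex hull whose
vertices are the pure voxels.  SPA finds them by repeatedly taking the column
of largest l2 norm and projecting all columns onto the orthogonal complement
of the selected one.  The selected original columns become ``W0``; ``H0`` is
obtained by per-voxel non-negative least squares, and for Convex NMF an
auxiliary weight matrix ``A0`` is derived from ``H0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy.optimize import nnls as _nnls

from .matrix import FeatureMatrix, InitFactors, as_feature_matrix

__all__ = [
    "SpaSelection",
    "spa_select_columns",
    "nnls_abundances",
    "init_from_spa",
    "convex_weights_init",
]


class RankDeficiencyError(ValueError):
    """Raised when SPA runs out of linearly independent directions."""


@dataclass
class SpaSelection:
    """Result of SPA column selection.

    ``indices[j]`` is the 0-based column picked at step ``j``; ``vectors[j]``
    is the *original* (unprojected) column of ``X`` at that index, and
    ``projected_norms[j]`` the squared l2 norm that was maximal in the
    projected subspace at step ``j``.
    """

    indices: list[int]
    vectors: npt.NDArray[np.floating]  # m x r, selection order
    projected_norms: list[float]


def spa_select_columns(X, r: int, *, norm_floor_rel: float = 1e-12) -> SpaSelection:
    """Select ``r`` near-separable vertex columns of ``X`` by SPA.

    At each step the column with the largest squared l2 norm of the working
    (projected) matrix ``S`` is selected — ties broken by smallest column
    index — and ``S`` is projected onto the orthogonal complement of the
    selected direction.  The total cost is O(mnr).

    Parameters
    ----------
    X
        Non-negative feature matrix (``FeatureMatrix`` or array, m x n).
    r
        Number of columns (sources) to select; must be <= min(m, n).
    norm_floor_rel
        Relative numerical floor: if the maximal projected squared norm at
        some step drops below ``norm_floor_rel * ||X||_F^2``, the data has
        no ``r`` independent directions and a rank-deficiency error names
        the failing step.
    """
    fm = as_feature_matrix(X)
    A = fm.data
    m, n = A.shape
    if r < 1:
        raise ValueError("r must be a positive integer")
    if r > min(m, n):
        raise ValueError(f"r={r} exceeds min(m, n) = {min(m, n)}")

    floor = norm_floor_rel * float(np.sum(A * A))
    S = A.copy()
    indices: list[int] = []
    norms: list[float] = []
    vectors = np.empty((m, r), dtype=float)
    for j in range(r):
        col_norms = np.einsum("ij,ij->j", S, S)
        i_star = int(np.argmax(col_norms))  # argmax returns first (smallest) index on ties
        best = float(col_norms[i_star])
        if best <= floor:
            raise RankDeficiencyError(
                f"SPA step {j}: maximal projected squared norm {best:.3e} is below "
                f"the numerical floor {floor:.3e}; X has fewer than {r} independent "
                "directions"
            )
        s = S[:, i_star]
        indices.append(i_star)
        norms.append(best)
        vectors[:, j] = A[:, i_star]
        # project out the selected direction: S <- (I - s s^T / ||s||^2) S
        S -= np.outer(s / best, s @ S)
    return SpaSelection(indices=indices, vectors=vectors, projected_norms=norms)


def nnls_abundances(X, W) -> npt.NDArray[np.floating]:
    """Per-voxel non-negative least squares abundances.

    Column ``j`` of the result minimizes ``||X[:, j] - W h||_2`` subject to
    ``h >= 0``, solved independently per column with the Lawson-Hanson
    active-set method (exact KKT point per column).
    """
    Xd = X.data if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != Xd.shape[0]:
        raise ValueError(f"W {W.shape} incompatible with X {Xd.shape}")
    zero_cols = np.where(~W.any(axis=0))[0]
    if zero_cols.size:
        raise ValueError(f"degenerate basis: W columns {zero_cols.tolist()} are zero")
    r, n = W.shape[1], Xd.shape[1]
    H = np.empty((r, n), dtype=float)
    for j in range(n):
        H[:, j], _ = _nnls(W, Xd[:, j])
    return H


def init_from_spa(X, r: int) -> InitFactors:
    """Deterministic SPA initialization: ``W0`` = selected columns, ``H0`` by NNLS."""
    fm = as_feature_matrix(X)
    sel = spa_select_columns(fm, r)
    W0 = sel.vectors.copy()
    H0 = nnls_abundances(fm, W0)
    return InitFactors(W0=W0, H0=H0, method="spa", seed=None)


def convex_weights_init(H0, mode: str = "from_H") -> npt.NDArray[np.floating]:
    """Initial data-space weights ``A0`` (n x r) for Convex NMF from ``H0``.

    Solves ``X ~ X A H`` for ``A`` at ``H = H0`` in least squares,
    ``A = H0^T (H0 H0^T)^{-1}``, then restores non-negativity by keeping the
    positive part ``A+`` and adding a uniform offset of 0.2 times the mean
    absolute value of the nonzero entries of ``A+``::

        A0 = A+ + 0.2 * <A+> * E

    with ``E`` the all-ones matrix.  The same construction is applied to the
    ``H0`` of every initialization method.
    """
    H0 = np.asarray(H0, dtype=float)
    if H0.ndim != 2:
        raise ValueError("H0 must be 2-D (r x n)")
    r = H0.shape[0]
    G = H0 @ H0.T
    # A^T solves G A^T = H0; fall back to a tiny ridge only if G is singular
    try:
        cond = np.linalg.cond(G)
    except np.linalg.LinAlgError:
        cond = np.inf
    if mode == "from_H" and cond > 1e14:
        raise np.linalg.LinAlgError(
            "H0 H0^T is numerically singular; regularize H0 or use "
            "mode='zero_fallback'"
        )
    if cond > 1e14:
        G = G + (1e-10 * np.trace(G) / r) * np.eye(r)
    A = np.linalg.solve(G, H0).T  # n x r
    A_pos = np.maximum(A, 0.0)
    nnz = np.count_nonzero(A_pos)
    if nnz == 0:
        raise ValueError("positive part of A is identically zero")
    offset = 0.2 * (np.abs(A_pos).sum() / nnz)
    return A_pos + offset
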