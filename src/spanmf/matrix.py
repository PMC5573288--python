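"""Core containers for the factorization pipeline.

The data model follows the standard unmixing convention: a non-negative
feature matrix ``X`` of shape ``(m, n)`` holds one column per voxel and one
row per MRI-derived feature.  A rank-``r`` factorization ``X ~ W H`` has
source signatures in the columns of ``W`` (m x r) and per-voxel abundances
in the rows of ``H`` (r x n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "FeatureMatrix",
    "InitFactors",
    "Factorization",
    "residual",
]


@dataclass
class FeatureMatrix:
    """Non-negative feature matrix with optional voxel-grid geometry.

    Parameters
    ----------
    data
        Array of shape ``(m, n)``, every entry >= 0.  Rows are features,
        columns are voxels.
    grid_shape
        Optional ``(rows, cols)`` pair mapping column index ``j`` to 2-D
        position ``(j // cols, j % cols)``; ``rows * cols`` must be >= n.
    feature_names
        Optional list of ``m`` row labels.
    dropped_columns
        Indices of all-zero columns removed at load time (see
        :func:`spanmf.io.read_feature_matrix`).
    """

    data: npt.NDArray[np.floating]
    grid_shape: tuple[int, int] | None = None
    feature_names: list[str] | None = None
    dropped_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("feature matrix must be 2-D (features x voxels)")
        m, n = self.data.shape
        if m < 1 or n < 1:
            raise ValueError("feature matrix must be non-empty")
        if np.any(self.data < 0):
            bad = np.argwhere(self.data < 0)
            raise ValueError(
                f"feature matrix has {len(bad)} negative entries, "
                f"first at (row, col) = {tuple(bad[0])}"
            )
        if self.grid_shape is not None:
            gr, gc = self.grid_shape
            if gr < 1 or gc < 1 or gr * gc < n:
                raise ValueError(
                    f"grid_shape {self.grid_shape} cannot host {n} voxels"
                )
        if self.feature_names is not None and len(self.feature_names) != m:
            raise ValueError("feature_names length must equal number of rows")

    @property
    def m(self) -> int:
        """Number of features (rows)."""
        return self.data.shape[0]

    @property
    def n(self) -> int:
        """Number of voxels (columns)."""
        return self.data.shape[1]


def as_feature_matrix(X) -> FeatureMatrix:
    """Coerce an array or FeatureMatrix to a FeatureMatrix."""
    if isinstance(X, FeatureMatrix):
        return X
    return FeatureMatrix(np.asarray(X, dtype=float))


@dataclass
class InitFactors:
    """An initialization pair ``(W0, H0)`` for an NMF solver.

    ``A0`` is only populated for Convex NMF, where the sources are
    constrained to the column space of the data (``W = X A``).
    """

    W0: npt.NDArray[np.floating]
    H0: npt.NDArray[np.floating]
    A0: npt.NDArray[np.floating] | None = None
    method: str = "unknown"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.W0 = np.asarray(self.W0, dtype=float)
        self.H0 = np.asarray(self.H0, dtype=float)
        if self.W0.ndim != 2 or self.H0.ndim != 2:
            raise ValueError("W0 and H0 must be 2-D")
        if self.W0.shape[1] != self.H0.shape[0]:
            raise ValueError(
                f"rank mismatch: W0 is {self.W0.shape}, H0 is {self.H0.shape}"
            )
        if np.any(self.W0 < 0) or np.any(self.H0 < 0):
            raise ValueError("initial factors must be non-negative")
        if self.A0 is not None:
            self.A0 = np.asarray(self.A0, dtype=float)
            if np.any(self.A0 < 0):
                raise ValueError("A0 must be non-negative")

    @property
    def rank(self) -> int:
        return self.W0.shape[1]


@dataclass
class Factorization:
    """Solver output: factors, residual trace and convergence metadata.

    ``residual_trace[t]`` is ``||X - W H||_F`` after outer iteration ``t``,
    with ``residual_trace[0]`` evaluated at the initialization so that
    head-start comparisons between initializers are possible.
    """

    W: npt.NDArray[np.floating]
    H: npt.NDArray[np.floating]
    residual_trace: list[float]
    n_iter: int
    converged: bool
    init_method: str = "unknown"
    seed: int | None = None
    A: npt.NDArray[np.floating] | None = None

    @property
    def final_residual(self) -> float:
        return self.residual_trace[-1]

    @property
    def rank(self) -> int:
        return self.W.shape[1]


def residual(X, W, H) -> float:
    """Frobenius residual ``||X - W H||_F``.

    This unsquared norm is the quantity traced per iteration and used for
    restart selection; the optimization objective ``0.5 ||X - WH||_F^2``
    induces the same ordering.
    """
    X = X.data if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.shape[0] != X.shape[0] or H.shape[1] != X.shape[1] or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, W {W.shape}, H {H.shape}"
        )
    return float(np.linalg.norm(X - W @ H, "fro"))
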