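"""Two-level hierarchical NMF (hNMF).

A rank-2 factorization first splits the voxels into two coarse tissue groups
(in tumor imaging, roughly pathologic vs normal-appearing tissue).  Each
group is then factorized separately at a smaller rank, the branch sources
are pooled, and the final abundances over all voxels are recomputed by
non-negative least squares against the pooled sources.  aHALS is used at
both levels, and the chosen initialization method is applied at both stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .matrix import Factorization, as_feature_matrix
from .solvers import SolverConfig, solve as _solve, run_with_restarts
from .spa import nnls_abundances

__all__ = ["HnmfResult", "hnmf_solve"]


@dataclass
class HnmfResult:
    """Output of the 2-level factorization.

    ``branch_assignment[j]`` is 1 or 2 depending on which level-1 source
    dominates voxel ``j``; ``W_pooled`` concatenates the branch sources
    (branch 1 first) and ``H_final`` is the NNLS fit of the full data on
    ``W_pooled``.
    """

    level1: Factorization
    branch_assignment: npt.NDArray[np.integer]
    branch_factorizations: tuple[Factorization, Factorization]
    W_pooled: npt.NDArray[np.floating]
    H_final: npt.NDArray[np.floating]
    final_residual: float


def _branch_solve(Xsub: np.ndarray, rank: int, init_method: str,
                  cfg: SolverConfig, base_seed: int) -> Factorization:
    if init_method in ("random", "fcm"):
        return run_with_restarts(Xsub, rank, "ahals", init_method, cfg, base_seed)
    return _solve(Xsub, rank, "ahals", init_method, cfg)


def hnmf_solve(X, r: int, r1: int | None = None, init_method: str = "spa",
               cfg: SolverConfig | None = None, base_seed: int = 0) -> HnmfResult:
    """Run the 2-level hierarchical factorization.

    Parameters
    ----------
    X
        Non-negative feature matrix (m x n).
    r
        Total number of sources (>= 2).
    r1
        Rank given to branch 1; branch 2 gets ``r - r1``.  Defaults to
        ``ceil(r / 2)``.
    init_method
        One of ``{"spa", "nndsvd", "random", "fcm"}``, applied at both
        levels (restart orchestration is used for the non-deterministic
        ones, with ``cfg.n_restarts`` repetitions).
    """
    cfg = cfg or SolverConfig()
    fm = as_feature_matrix(X)
    Xd = fm.data
    n = fm.n
    if r < 2:
        raise ValueError("hNMF needs r >= 2")
    if r1 is None:
        r1 = -(-r // 2)  # ceil(r/2)
    if not (1 <= r1 < r):
        raise ValueError(f"rank split r1={r1} must satisfy 1 <= r1 < r={r}")
    r2 = r - r1

    # level 1: rank-2 split
    if init_method in ("random", "fcm"):
        level1 = run_with_restarts(fm, 2, "ahals", init_method, cfg, base_seed)
    else:
        level1 = _solve(fm, 2, "ahals", init_method, cfg)
    # each voxel follows its dominant level-1 abundance; ties -> branch 1
    assignment = np.where(level1.H[1] > level1.H[0], 2, 1)

    idx1 = np.flatnonzero(assignment == 1)
    idx2 = np.flatnonzero(assignment == 2)
    for name, idx, rank in (("branch 1", idx1, r1), ("branch 2", idx2, r2)):
        if idx.size < rank:
            raise ValueError(
                f"{name} received {idx.size} voxels, fewer than its rank {rank}"
            )
    fac1 = _branch_solve(Xd[:, idx1], r1, init_method, cfg, base_seed + 1000)
    fac2 = _branch_solve(Xd[:, idx2], r2, init_method, cfg, base_seed + 2000)

    W_pooled = np.hstack([fac1.W, fac2.W])
    H_final = nnls_abundances(Xd, W_pooled)
    return HnmfResult(
        level1=level1,
        branch_assignment=assignment,
        branch_factorizations=(fac1, fac2),
        W_pooled=W_pooled,
        H_final=H_final,
        final_residual=float(np.linalg.norm(Xd - W_pooled @ H_final, "fro")),
    )
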