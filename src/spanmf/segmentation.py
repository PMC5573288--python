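"""Abundance-based tissue segmentation and its validation.

Abundance matrices are turned into hard tissue label maps by k-means with
one-hot centroid initialization (so cluster ``k`` inherits the identity of
source ``k``), segmentations are scored with the Dice overlap over the three
nested BraTS tumor classes (active tumor; tumor core = active + necrosis;
whole tumor = core + edema), and paired per-subject scores are compared with
a one-tailed Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm
from sklearn.cluster import KMeans

__all__ = [
    "LabelMap",
    "DiceReport",
    "segment_abundances",
    "match_sources",
    "dice",
    "tissue_class_masks",
    "dice_report",
    "wilcoxon_one_tailed",
]

logger = logging.getLogger(__name__)

TISSUE_NAMES = ("normal", "edema", "active", "necrosis")


@dataclass
class LabelMap:
    """Hard segmentation: one tissue index per voxel.

    ``labels[j]`` is in ``1..r`` (0 marks an unassigned voxel, e.g. an
    all-zero abundance column).  ``class_of_source`` maps each source index
    to a tissue name in ``{"normal", "edema", "active", "necrosis",
    "other"}`` so BraTS class masks can be formed.
    """

    labels: npt.NDArray[np.integer]
    grid_shape: tuple[int, int] | None = None
    class_of_source: dict[int, str] = field(default_factory=dict)

    def as_grid(self) -> npt.NDArray[np.integer]:
        if self.grid_shape is None:
            raise ValueError("label map has no grid geometry")
        out = np.zeros(self.grid_shape, dtype=int).ravel()
        out[: self.labels.size] = self.labels
        return out.reshape(self.grid_shape)


def segment_abundances(H, *, normalize: bool = True,
                       grid_shape: tuple[int, int] | None = None,
                       class_of_source: dict[int, str] | None = None) -> LabelMap:
    """Cluster abundance columns into ``r`` tissue labels by k-means.

    Centroids are initialized at the one-hot vectors ``e_1 .. e_r`` so that
    cluster ``k`` starts at "pure source k" and keeps that identity; Lloyd
    iterations then refine the partition.  Columns are optionally normalized
    to unit sum first, which puts mixed voxels on the same simplex as the
    one-hot centroids.  All-zero columns cannot be normalized and are
    labeled 0 (unassigned, logged).
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise ValueError("H must be 2-D (r x n)")
    r, n = H.shape
    if r < 2:
        raise ValueError("segmentation needs at least 2 sources")
    colsum = H.sum(axis=0)
    ok = colsum > 0
    if not ok.all():
        logger.warning("segment_abundances: %d all-zero columns left unassigned",
                       int((~ok).sum()))
    P = H[:, ok]
    if normalize:
        P = P / P.sum(axis=0, keepdims=True)
    km = KMeans(n_clusters=r, init=np.eye(r), n_init=1, max_iter=300,
                tol=1e-6, algorithm="lloyd")
    fit_labels = km.fit_predict(P.T)
    labels = np.zeros(n, dtype=int)
    labels[ok] = fit_labels + 1
    return LabelMap(labels=labels, grid_shape=grid_shape,
                    class_of_source=dict(class_of_source or {}))


def match_sources(W_est, W_ref) -> npt.NDArray[np.integer]:
    """Optimal source-to-reference matching by cosine similarity.

    NMF output ordering is arbitrary; this finds the one-to-one assignment
    maximizing the summed cosine similarity between matched columns (exact,
    via the Hungarian algorithm).  Returns ``perm`` with ``perm[k]`` = index
    of the reference column matched to estimated column ``k``.
    """
    A = np.asarray(W_est, dtype=float)
    B = np.asarray(W_ref, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero column in source matrix")
    C = (A / na).T @ (B / nb)  # cosine similarity matrix
    row, col = linear_sum_assignment(-C)
    perm = np.empty(A.shape[1], dtype=int)
    perm[row] = col
    return perm


def relabel(labels: npt.NDArray[np.integer],
            perm: npt.NDArray[np.integer]) -> npt.NDArray[np.integer]:
    """Apply a source permutation to a 1-based label vector (0 stays 0)."""
    out = np.zeros_like(labels)
    for k, p in enumerate(perm):
        out[labels == k + 1] = p + 1
    return out


def dice(mask_a, mask_b) -> float:
    """Dice overlap ``2 |A & B| / (|A| + |B|)`` of two boolean voxel masks.

    Two empty masks agree perfectly on absence and score 1 (logged);
    empty vs non-empty scores 0.
    """
    a = np.asarray(mask_a, dtype=bool).ravel()
    b = np.asarray(mask_b, dtype=bool).ravel()
    if a.shape != b.shape:
        raise ValueError("masks must cover the same voxel index set")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        logger.info("dice: both masks empty, scoring 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def tissue_class_masks(label_map: LabelMap) -> dict[str, npt.NDArray[np.bool_]]:
    """Boolean masks for the three nested BraTS classes.

    active = active tumor; core = active + necrosis; whole = core + edema.
    """
    labels = label_map.labels
    present = set(np.unique(labels[labels > 0]).tolist())
    missing = present - set(label_map.class_of_source)
    if missing:
        raise ValueError(f"labels {sorted(missing)} have no tissue-class mapping")
    by_tissue = {t: np.zeros(labels.shape, dtype=bool)
                 for t in ("active", "necrosis", "edema")}
    for src, tissue in label_map.class_of_source.items():
        if tissue in by_tissue:
            by_tissue[tissue] |= labels == src
    active = by_tissue["active"]
    core = active | by_tissue["necrosis"]
    whole = core | by_tissue["edema"]
    return {"active": active, "core": core, "whole": whole}


@dataclass
class DiceReport:
    """Per-class Dice scores of an estimated vs a reference segmentation."""

    dice_active: float
    dice_core: float
    dice_whole: float
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {"active": self.dice_active, "core": self.dice_core,
                "whole": self.dice_whole}


def dice_report(estimated: LabelMap, reference: LabelMap) -> DiceReport:
    """Score an estimated label map against a reference over the BraTS classes."""
    est = tissue_class_masks(estimated)
    ref = tissue_class_masks(reference)
    scores = {}
    counts = {}
    for cls in ("active", "core", "whole"):
        scores[cls] = dice(est[cls], ref[cls])
        counts[cls] = {
            "estimated": int(est[cls].sum()),
            "reference": int(ref[cls].sum()),
            "intersection": int((est[cls] & ref[cls]).sum()),
        }
    return DiceReport(dice_active=scores["active"], dice_core=scores["core"],
                      dice_whole=scores["whole"], counts=counts)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """P(W+ >= w_plus) under the signed-rank null, exactly.

    Dynamic programming over the distribution of the positive rank sum: each
    rank joins the positive set independently with probability 1/2.  Ranks
    are midranks (possibly half-integers), so everything is scaled by 2 to
    work on an integer lattice.
    """
    scaled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(scaled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for s in scaled:
        shifted = np.zeros_like(dist)
        shifted[s:] = dist[: total + 1 - s]
        dist = 0.5 * (dist + shifted)
    threshold = int(np.ceil(2.0 * w_plus - 1e-9))
    return float(dist[threshold:].sum())


def wilcoxon_one_tailed(dice_a, dice_b) -> tuple[float, float]:
    """One-tailed paired Wilcoxon signed-rank test of ``a > b``.

    Zero differences are dropped (the common signed-rank convention); ties
    among the |differences| get midranks.  The null distribution of the
    positive rank sum ``W+`` is enumerated exactly for up to 25 nonzero
    pairs (the enumeration handles midranks exactly), and approximated by a
    tie-corrected normal with continuity correction beyond that.

    Returns ``(W+, p_value)``.
    """
    a = np.asarray(dice_a, dtype=float)
    b = np.asarray(dice_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D sequences of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        logger.warning("wilcoxon_one_tailed: all differences zero, p = 1")
        return 0.0, 1.0
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))  # midranks under ties
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= 25:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        # tie correction: Var(W+) = sum(ranks^2)/4
        sigma = np.sqrt(float(np.sum(ranks**2)) / 4.0)
        z = (w_plus - mu - 0.5) / sigma
        p = float(norm.sf(z))
    return w_plus, p
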