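"""Synthetic multi-parametric phantoms for end-to-end testing.

The generator emulates the statistical structure the factorization pipeline
assumes in brain-tumor MRI: a non-negative feature matrix whose columns are
voxels, each voxel a near-separable mixture of a few tissue signatures
(normal tissue, edema, active tumor, necrosis) with sum-to-one abundances,
spatially coherent concentric tumor geometry (necrotic center inside an
active rim inside an edema halo inside normal background), pure voxels for
most tissues, and additive noise.  It makes no attempt to simulate MR
physics; only the matrix shape and mixing geometry of such data are
reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from .matrix import FeatureMatrix
from .segmentation import LabelMap, TISSUE_NAMES

__all__ = ["PhantomConfig", "Phantom", "make_phantom", "snr_of"]


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic phantom.

    Parameters
    ----------
    grid_shape
        Voxel grid; n = rows * cols.
    m
        Number of non-negative features per voxel (rows of X).
    r
        Number of tissue sources; source k is named ``tissue_names[k]``.
    purity_fraction
        Fraction of each tissue's interior voxels that are pure (one-hot
        abundance).
    snr_db
        Target signal-to-noise ratio in dB; ``inf`` for noiseless.
    mixing_sharpness
        Dirichlet concentration placed on a voxel's own tissue for mixed
        interior voxels; larger values concentrate abundance on the true
        tissue.
    pure_pixel_per_source
        Per-source flags; setting one to False replaces that tissue's pure
        voxels with 0.9/0.1 mixtures, emulating the partial-volume violation
        of the pure-pixel assumption seen in low-resolution modalities.
    """

    grid_shape: tuple[int, int] = (64, 64)
    m: int = 24
    r: int = 4
    purity_fraction: float = 0.5
    snr_db: float = np.inf
    mixing_sharpness: float = 10.0
    pure_pixel_per_source: tuple[bool, ...] | None = None
    seed: int = 0
    tissue_names: tuple[str, ...] = TISSUE_NAMES

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity_fraction <= 1.0):
            raise ValueError("purity_fraction must be in [0, 1]")
        if self.r > self.m:
            raise ValueError("need r <= m")
        if self.pure_pixel_per_source is None:
            self.pure_pixel_per_source = (True,) * self.r
        if len(self.pure_pixel_per_source) != self.r:
            raise ValueError("pure_pixel_per_source must have r entries")
        if len(self.tissue_names) < self.r:
            raise ValueError("need a tissue name per source")


@dataclass
class Phantom:
    """Ground truth bundle: data, generating factors, labels and pure voxels."""

    X: FeatureMatrix
    W_true: npt.NDArray[np.floating]
    H_true: npt.NDArray[np.floating]
    label_map_true: LabelMap
    pure_indices: dict[int, list[int]]
    X_clean: npt.NDArray[np.floating]
    config: PhantomConfig = field(repr=False, default=None)

    @property
    def class_of_source(self) -> dict[int, str]:
        return dict(self.label_map_true.class_of_source)


def _draw_sources(rng: np.random.Generator, m: int, r: int,
                  max_cosine: float = 0.97) -> np.ndarray:
    """Log-uniform non-negative signatures with pairwise cosine <= max_cosine."""
    for _ in range(200):
        W = 10.0 ** rng.uniform(-1.0, 1.0, size=(m, r))
        Wn = W / np.linalg.norm(W, axis=0)
        G = Wn.T @ Wn
        np.fill_diagonal(G, 0.0)
        if G.max() <= max_cosine:
            return W
    raise RuntimeError("could not draw sufficiently distinct source signatures")


def _region_layout(grid_shape: tuple[int, int], r: int) -> np.ndarray:
    """Concentric tissue regions: necrosis core, active rim, edema halo,
    normal background (labels r-1, r-2, ... down to 0 from the center out
    for r = 4; smaller r drops the innermost rings)."""
    gr, gc = grid_shape
    yy, xx = np.mgrid[0:gr, 0:gc]
    cy, cx = (gr - 1) / 2.0, (gc - 1) / 2.0
    dist = np.sqrt(((yy - cy) / gr) ** 2 + ((xx - cx) / gc) ** 2)  # 0 .. ~0.71
    # radii as a fraction of the half-diagonal; sized so every ring is populated
    radii = {4: (0.10, 0.20, 0.32), 3: (0.16, 0.30), 2: (0.25,)}
    if r not in radii:
        raise ValueError("concentric layout supports r in {2, 3, 4}")
    region = np.zeros((gr, gc), dtype=int)  # 0 = normal background
    # innermost region gets the highest source index (necrosis for r=4)
    for depth, radius in enumerate(reversed(radii[r]), start=1):
        region[dist <= radius] = depth
    # map ring depth -> source index: background 0, halo 1, rim 2, core 3
    return region


def make_phantom(cfg: PhantomConfig) -> Phantom:
    """Generate one phantom under the given study conditions.

    Interior voxels of each region are pure with probability
    ``purity_fraction`` and otherwise Dirichlet mixtures concentrated on the
    region's tissue; voxels on a region boundary are two-tissue mixtures
    with the neighboring region.  Columns always sum to one.  Additive
    Gaussian noise is scaled to the target SNR and truncated at zero to
    keep X non-negative.
    """
    rng = np.random.default_rng(cfg.seed)
    gr, gc = cfg.grid_shape
    n = gr * gc
    r = cfg.r
    W = _draw_sources(rng, cfg.m, r)
    region = _region_layout(cfg.grid_shape, r)
    for k in range(r):
        if not np.any(region == k):
            raise ValueError(f"grid too small: region for source {k} is empty")

    # boundary voxels: 4-neighborhood touches a different region
    boundary = np.zeros_like(region, dtype=bool)
    boundary[:-1] |= region[:-1] != region[1:]
    boundary[1:] |= region[1:] != region[:-1]
    boundary[:, :-1] |= region[:, :-1] != region[:, 1:]
    boundary[:, 1:] |= region[:, 1:] != region[:, :-1]
    # the neighboring tissue a boundary voxel mixes with (first differing neighbor)
    neighbor = region.copy()
    for shift in (
        lambda a: np.pad(a[1:], ((0, 1), (0, 0)), mode="edge"),
        lambda a: np.pad(a[:-1], ((1, 0), (0, 0)), mode="edge"),
        lambda a: np.pad(a[:, 1:], ((0, 0), (0, 1)), mode="edge"),
        lambda a: np.pad(a[:, :-1], ((0, 0), (1, 0)), mode="edge"),
    ):
        sh = shift(region)
        take = boundary & (neighbor == region) & (sh != region)
        neighbor[take] = sh[take]

    region_f = region.ravel()
    boundary_f = boundary.ravel()
    neighbor_f = neighbor.ravel()
    H = np.zeros((r, n))
    pure = np.zeros(n, dtype=bool)
    is_pure_draw = rng.uniform(size=n) < cfg.purity_fraction
    diric = rng.gamma  # Dirichlet via normalized gammas, drawn per voxel group
    for j in range(n):
        k = region_f[j]
        if boundary_f[j]:
            # two-tissue mixture favoring the voxel's own region
            g_own = diric(2.0)
            g_nb = diric(1.0)
            tot = g_own + g_nb
            H[k, j] = g_own / tot
            H[neighbor_f[j], j] = g_nb / tot
        elif is_pure_draw[j]:
            H[k, j] = 1.0
            pure[j] = True
        else:
            alpha = np.full(r, 0.3)
            alpha[k] = cfg.mixing_sharpness
            g = diric(alpha)
            H[:, j] = g / g.sum()

    # pure-pixel violation: demote a tissue's pure voxels to 0.9/0.1 mixtures
    for k in range(r):
        if not cfg.pure_pixel_per_source[k]:
            cols = np.flatnonzero(pure & (region_f == k))
            for j in cols:
                other = neighbor_f[j] if neighbor_f[j] != k else (k - 1) % r
                H[:, j] = 0.0
                H[k, j] = 0.9
                H[other, j] = 0.1
                pure[j] = False

    X_clean = W @ H
    if np.isinf(cfg.snr_db):
        X = X_clean.copy()
    else:
        signal_power = float(np.mean(X_clean**2))
        noise_sigma = np.sqrt(signal_power * 10.0 ** (-cfg.snr_db / 10.0))
        X = np.maximum(X_clean + rng.normal(0.0, noise_sigma, size=X_clean.shape), 0.0)

    class_of_source = {k + 1: cfg.tissue_names[k] for k in range(r)}
    label_map = LabelMap(labels=region_f + 1, grid_shape=cfg.grid_shape,
                         class_of_source=class_of_source)
    pure_indices = {k: np.flatnonzero(pure & (region_f == k)).tolist()
                    for k in range(r)}
    return Phantom(
        X=FeatureMatrix(X, grid_shape=cfg.grid_shape),
        W_true=W,
        H_true=H,
        label_map_true=label_map,
        pure_indices=pure_indices,
        X_clean=X_clean,
        config=cfg,
    )


def snr_of(X_clean, X_noisy) -> float:
    """Realized SNR in dB: ``10 log10(||clean||_F^2 / ||noisy - clean||_F^2)``."""
    A = np.asarray(X_clean, dtype=float)
    B = np.asarray(X_noisy, dtype=float)
    if A.shape != B.shape:
        raise ValueError("shape mismatch")
    noise = float(np.sum((B - A) ** 2))
    if noise == 0.0:
        return np.inf
    return 10.0 * np.log10(float(np.sum(A * A)) / noise)
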