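"""Delimited-text I/O for feature matrices, label grids and reports.

The primary exchange format is plain delimited text (comma or tab): feature
matrices are stored with one row per feature and one column per voxel,
optionally with a header row of feature names and a JSON sidecar carrying
the voxel-grid shape; label maps are integer grids.  An optional NIfTI
adapter converts a 4-D feature volume plus mask into the feature-matrix
layout.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .matrix import FeatureMatrix
from .segmentation import LabelMap

__all__ = [
    "read_feature_matrix",
    "write_feature_matrix",
    "read_label_grid",
    "write_label_grid",
    "nifti_to_feature_matrix",
]

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_feature_matrix(path: str | Path, *, header: bool | None = None) -> FeatureMatrix:
    """Read a delimited feature matrix (rows = features, columns = voxels).

    The delimiter (comma or tab) is sniffed from the first line, and a
    header row of feature names is detected automatically unless ``header``
    is forced.  A sidecar ``<path>.json`` with a ``grid_shape`` entry is
    honored when present.  Entries must be non-negative; all-zero columns
    are dropped and their indices recorded on the returned object.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = "\t" if "\t" in lines[0] else ","
    first = lines[0].split(delim)
    if header is None:
        try:
            [float(tok) for tok in first]
            header = False
        except ValueError:
            header = True
    names = [tok.strip() for tok in first] if header else None
    rows = []
    width = None
    for lineno, ln in enumerate(lines[1 if header else 0:], start=2 if header else 1):
        toks = ln.split(delim)
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(toks)} fields, expected {width})"
            )
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable value at line {lineno}: {exc}") from exc
    data = np.asarray(rows, dtype=float)
    neg = np.argwhere(data < 0)
    if neg.size:
        cells = ", ".join(f"(row {i}, col {j})" for i, j in neg[:5])
        raise ValueError(f"{path}: negative entries at {cells}"
                         + ("..." if len(neg) > 5 else ""))
    grid_shape = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "grid_shape" in meta:
            grid_shape = tuple(meta["grid_shape"])
    zero_cols = np.flatnonzero(~data.any(axis=0)).tolist()
    if zero_cols:
        logger.warning("%s: dropping %d all-zero columns %s",
                       path, len(zero_cols), zero_cols[:10])
        data = data[:, data.any(axis=0)]
        grid_shape = None  # geometry no longer contiguous
    return FeatureMatrix(data, grid_shape=grid_shape, feature_names=names,
                         dropped_columns=zero_cols)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path,
                         *, delim: str = ",") -> None:
    """Write a feature matrix as delimited text (+ JSON sidecar for geometry).

    Values are written with ``repr`` precision so a read-back is
    bit-identical for exactly representable values.
    """
    path = Path(path)
    with path.open("w") as fh:
        if fm.feature_names:
            fh.write(delim.join(fm.feature_names) + "\n")
        for row in fm.data:
            fh.write(delim.join(repr(float(v)) for v in row) + "\n")
    if fm.grid_shape is not None:
        _sidecar_path(path).write_text(
            json.dumps({"grid_shape": list(fm.grid_shape)}) + "\n"
        )


def read_label_grid(path: str | Path,
                    class_of_source: dict[int, str] | None = None) -> LabelMap:
    """Read an integer label grid (rows of the image as lines)."""
    path = Path(path)
    grid = np.loadtxt(path, dtype=int, delimiter=None if "\t" in path.read_text(
    )[:200] else ",", ndmin=2)
    return LabelMap(labels=grid.ravel(), grid_shape=grid.shape,
                    class_of_source=dict(class_of_source or {}))


def write_label_grid(label_map: LabelMap, path: str | Path) -> None:
    """Write a label map as an integer delimited grid."""
    grid = label_map.as_grid() if label_map.grid_shape is not None \
        else label_map.labels.reshape(1, -1)
    np.savetxt(Path(path), grid, fmt="%d", delimiter=",")


def nifti_to_feature_matrix(path: str | Path,
                            mask_path: str | Path | None = None) -> FeatureMatrix:
    """Optional adapter: load a 4-D NIfTI feature volume as a feature matrix.

    The last axis is treated as the feature axis; a 3-D mask volume selects
    the voxels included (mirroring a volume-of-interest restriction).
    Requires ``nibabel``.
    """
    import nibabel as nib

    img = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if img.ndim != 4:
        raise ValueError("expected a 4-D feature volume")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
    else:
        mask = np.ones(img.shape[:3], dtype=bool)
    X = img[mask].T  # features x voxels
    return FeatureMatrix(np.maximum(X, 0.0))
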