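"""Experiment driver: the initializer x solver comparison grid.

Runs every requested (initializer, solver) cell on one dataset — a loaded
feature matrix or a generated phantom — through initialize, solve (with
restart orchestration for the non-deterministic initializers), segment and
Dice-score against the reference segmentation.  Writes a Dice grid and an
iteration grid (rows = initializers, columns = solvers), per-cell residual
traces as CSV, label grids, factor matrices and a JSON manifest from which
every output can be regenerated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .hnmf import hnmf_solve
from .io import write_feature_matrix, write_label_grid
from .matrix import FeatureMatrix
from .phantom import Phantom, PhantomConfig, make_phantom
from .segmentation import (
    LabelMap,
    dice_report,
    match_sources,
    relabel,
    segment_abundances,
)
from .solvers import SolverConfig, run_with_restarts, solve

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "INITIALIZERS", "ALL_SOLVERS"]

logger = logging.getLogger(__name__)

INITIALIZERS = ("spa", "nndsvd", "fcm", "random")
ALL_SOLVERS = ("ahals", "gd", "pg", "convex", "hnmf")


@dataclass
class PipelineConfig:
    """Full configuration of one benchmark run."""

    rank: int = 4
    rank_split: int | None = None  # hNMF only
    initializers: tuple[str, ...] = ("spa",)
    solvers: tuple[str, ...] = ("ahals",)
    solver_config: SolverConfig = field(default_factory=SolverConfig)
    phantom: PhantomConfig | None = field(default_factory=PhantomConfig)
    base_seed: int = 0
    normalize_abundances: bool = True
    out_dir: str | None = None


@dataclass
class RunManifest:
    """Everything needed to regenerate a benchmark run's outputs."""

    version: str
    config: dict
    seeds: dict[str, int]
    cells: dict[str, dict]
    output_files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _run_cell(X: FeatureMatrix, r: int, init_method: str, solver: str,
              cfg: PipelineConfig):
    """One (initializer, solver) cell; returns (W, H, n_iter, converged, trace)."""
    scfg = cfg.solver_config
    if solver == "hnmf":
        res = hnmf_solve(X, r, cfg.rank_split, init_method, scfg,
                         base_seed=cfg.base_seed)
        n_iter = res.level1.n_iter + sum(f.n_iter for f in res.branch_factorizations)
        converged = (res.level1.converged
                     and all(f.converged for f in res.branch_factorizations))
        return res.W_pooled, res.H_final, n_iter, converged, \
            list(res.level1.residual_trace)
    if init_method in ("random", "fcm"):
        fac = run_with_restarts(X, r, solver, init_method, scfg,
                                base_seed=cfg.base_seed)
    else:
        fac = solve(X, r, solver, init_method, scfg)
    return fac.W, fac.H, fac.n_iter, fac.converged, list(fac.residual_trace)


def _segment_cell(W, H, reference: LabelMap, W_ref, cfg: PipelineConfig) -> LabelMap:
    """Segment abundances and anchor cluster identities to the reference.

    With ground-truth sources available (phantom data) the estimated sources
    are matched to the true ones by cosine similarity, playing the role the
    expert's tissue labels play on clinical data; cluster labels are
    permuted accordingly and inherit the reference tissue-class mapping.
    """
    seg = segment_abundances(H, normalize=cfg.normalize_abundances,
                             grid_shape=reference.grid_shape)
    if W_ref is not None:
        perm = match_sources(W, W_ref)
        seg.labels = relabel(seg.labels, perm)
    else:
        # anchor by majority overlap with the reference labels
        r = H.shape[0]
        perm = np.arange(r)
        for k in range(r):
            members = reference.labels[seg.labels == k + 1]
            if members.size:
                vals, counts = np.unique(members[members > 0], return_counts=True)
                if vals.size:
                    perm[k] = vals[np.argmax(counts)] - 1
        seg.labels = relabel(seg.labels, perm)
    seg.class_of_source = dict(reference.class_of_source)
    return seg


def run_pipeline(cfg: PipelineConfig,
                 X: FeatureMatrix | None = None,
                 reference: LabelMap | None = None,
                 W_ref=None) -> RunManifest:
    """Execute the full comparison grid.

    If ``X`` is not given, a phantom is generated from ``cfg.phantom`` and
    provides both the reference segmentation and the ground-truth sources.
    Cell failures are recorded in the manifest without aborting other cells.
    """
    phantom: Phantom | None = None
    if X is None:
        if cfg.phantom is None:
            raise ValueError("either X or a phantom config is required")
        phantom = make_phantom(cfg.phantom)
        X = phantom.X
        reference = phantom.label_map_true
        W_ref = phantom.W_true
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        version=__version__,
        config={
            "pipeline": {k: v for k, v in dataclasses.asdict(cfg).items()
                         if k != "solver_config"},
            "solver": dataclasses.asdict(cfg.solver_config),
        },
        seeds={"base_seed": cfg.base_seed,
               **({"phantom_seed": cfg.phantom.seed} if cfg.phantom else {})},
        cells={},
    )
    files: list[str] = []

    for init_method in cfg.initializers:
        for solver in cfg.solvers:
            cell = f"{init_method}:{solver}"
            try:
                W, H, n_iter, converged, trace = _run_cell(
                    X, cfg.rank, init_method, solver, cfg)
                record = {
                    "n_iter": n_iter,
                    "converged": converged,
                    "final_residual": float(np.linalg.norm(
                        X.data - W @ H, "fro")),
                }
                if reference is not None:
                    seg = _segment_cell(W, H, reference, W_ref, cfg)
                    rep = dice_report(seg, reference)
                    record["dice"] = rep.as_dict()
                else:
                    # no reference: labels keep raw source indices
                    seg = segment_abundances(
                        H, normalize=cfg.normalize_abundances,
                        grid_shape=X.grid_shape)
                if out_dir:
                    stem = cell.replace(":", "_")
                    np.savetxt(out_dir / f"{stem}_W.csv", W, delimiter=",")
                    np.savetxt(out_dir / f"{stem}_H.csv", H, delimiter=",")
                    np.savetxt(out_dir / f"{stem}_trace.csv",
                               np.column_stack([np.arange(len(trace)), trace]),
                               delimiter=",", header="iteration,residual",
                               comments="")
                    if seg is not None:
                        write_label_grid(seg, out_dir / f"{stem}_labels.csv")
                        files.append(str(out_dir / f"{stem}_labels.csv"))
                    files += [str(out_dir / f"{stem}_{s}.csv")
                              for s in ("W", "H", "trace")]
                manifest.cells[cell] = record
            except Exception as exc:  # noqa: BLE001 - isolate cell failures
                logger.error("cell %s failed: %s", cell, exc)
                manifest.cells[cell] = {"error": str(exc)}

    if out_dir:
        if phantom is not None:
            write_feature_matrix(X, out_dir / "phantom_X.csv")
            write_label_grid(reference, out_dir / "phantom_labels.csv")
            files += [str(out_dir / "phantom_X.csv"),
                      str(out_dir / "phantom_labels.csv")]
        _write_grids(manifest, cfg, out_dir, files)
        manifest.output_files = files
        (out_dir / "manifest.json").write_text(manifest.to_json())
    else:
        manifest.output_files = files
    return manifest


def _write_grids(manifest: RunManifest, cfg: PipelineConfig,
                 out_dir: Path, files: list[str]) -> None:
    """Dice grid (per tissue class) and iteration grid as TSV tables."""
    solvers = list(cfg.solvers)
    inits = list(cfg.initializers)
    for cls in ("active", "core", "whole"):
        lines = ["\t".join(["init"] + solvers)]
        for ini in inits:
            row = [ini]
            for sol in solvers:
                rec = manifest.cells.get(f"{ini}:{sol}", {})
                d = rec.get("dice", {}).get(cls)
                row.append(f"{d:.4f}" if d is not None else "NA")
            lines.append("\t".join(row))
        p = out_dir / f"dice_{cls}.tsv"
        p.write_text("\n".join(lines) + "\n")
        files.append(str(p))
    lines = ["\t".join(["init"] + solvers)]
    for ini in inits:
        row = [ini]
        for sol in solvers:
            rec = manifest.cells.get(f"{ini}:{sol}", {})
            row.append(str(rec.get("n_iter", "NA")))
        lines.append("\t".join(row))
    p = out_dir / "iterations.tsv"
    p.write_text("\n".join(lines) + "\n")
    files.append(str(p))
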