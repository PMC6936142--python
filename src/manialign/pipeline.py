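"""End-to-end pipeline: preprocess -> graphs -> correspondence -> align ->
cluster -> type -> evaluate.

The pipeline is a thin orchestration over the library modules.  All
randomness flows from ``RunConfig.seed``; a run is fully reproducible from
(inputs, config).  Outputs (when ``outdir`` is set) are written only after
every stage succeeds, so a failing run leaves no partial files.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    align_linear,
    align_nonparametric,
    cca_align,
    joint_system,
    manifold_warp,
    Embedding,
)
from .clustering import kmedoids_cluster, module_stats
from .correspondence import (
    identity_correspondence,
    ortholog_correspondence,
    path_to_matrix,
)
from .evaluation import alignment_error
from .graph import knn_graph
from .preprocess import (
    filter_low_expression,
    load_correspondence,
    load_expression,
    log2_transform,
    unit_normalize,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

METHODS = ("alignment_nonparametric", "alignment_linear", "warping", "cca", "none")


@dataclass
class RunConfig:
    """Parameters of a full run; echoed verbatim into the output summary.

    Defaults follow common practice for this family of methods: k = 3
    neighbors, manifold dimension d = 3, n = 60 modules, correspondence
    trade-off mu = 1/2.
    """

    x_path: str | None = None
    y_path: str | None = None
    pairs_path: str | None = None
    outdir: str | None = None
    method: str = "alignment_nonparametric"
    k: int = 3
    d: int = 3
    n_modules: int = 60
    mu: float = 0.5
    seed: int = 0
    metric: str = "euclidean"
    filter_threshold: float | None = None
    filter_how: str = "all"
    log2: bool = False
    pseudocount: float = 1.0
    normalize: str = "none"  # none | per_sample | per_gene
    kappa_mode: str = "specific"
    kappa_orientation: str = "ge_one"
    max_warp_iter: int = 10

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if self.k < 1 or self.d < 1 or self.n_modules < 1:
            raise ValueError("k, d and n_modules must all be >= 1")
        if self.normalize not in ("none", "per_sample", "per_gene"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")


@dataclass
class PipelineResult:
    embedding: Embedding
    modules: pd.DataFrame  # gene_id, dataset, module, module_type
    stats: pd.DataFrame  # per-module counts, J, kappa, S, type
    evaluation: dict
    summary: dict
    warnings: list = field(default_factory=list)


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _preprocess(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    if cfg.filter_threshold is not None:
        df = filter_low_expression(df, cfg.filter_threshold, how=cfg.filter_how)
    if cfg.log2:
        df = log2_transform(df, pseudocount=cfg.pseudocount)
    if cfg.normalize != "none":
        df = unit_normalize(df, axis=cfg.normalize)
    return df


def _build_correspondence(cfg, X, Y, pairs):
    if pairs is not None and len(pairs) > 0:
        return ortholog_correspondence(pairs, X.index, Y.index)
    return identity_correspondence(X.index, Y.index)


def run_pipeline(
    cfg: RunConfig,
    X: pd.DataFrame | None = None,
    Y: pd.DataFrame | None = None,
    pairs: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the full pipeline.

    Inputs may be given as in-memory frames (``X``, ``Y``, ``pairs``) or read
    from the paths in ``cfg``.  Returns a :class:`PipelineResult`; output
    files are additionally written when ``cfg.outdir`` is set.
    """
    cfg.validate()
    timings: dict[str, float] = {}
    run_warnings: list[str] = []

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc

        return _Timer()

    with stage("load"):
        if X is None:
            if cfg.x_path is None:
                raise ValueError("no X input: pass a frame or set x_path")
            X = load_expression(cfg.x_path)
        if Y is None:
            if cfg.y_path is None:
                raise ValueError("no Y input: pass a frame or set y_path")
            Y = load_expression(cfg.y_path)
        if pairs is None and cfg.pairs_path is not None:
            pairs = load_correspondence(cfg.pairs_path)

    with stage("preprocess"):
        X = _preprocess(X, cfg)
        Y = _preprocess(Y, cfg)

    with stage("correspondence"):
        # warping learns its correspondence from the data; every other
        # method needs shared ids or an explicit pair table up front
        W = None if cfg.method == "warping" else _build_correspondence(cfg, X, Y, pairs)

    with stage("align"):
        m_x, m_y = X.shape[0], Y.shape[0]
        warp_result = None
        if cfg.method in ("alignment_nonparametric", "alignment_linear"):
            WX = knn_graph(X, k=cfg.k, metric=cfg.metric)
            WY = knn_graph(Y, k=cfg.k, metric=cfg.metric)
            S = joint_system(WX, WY, W, mu=cfg.mu)
            if cfg.method == "alignment_nonparametric":
                emb = align_nonparametric(
                    S, cfg.d, gene_ids_x=X.index, gene_ids_y=Y.index
                )
            else:
                emb = align_linear(S, X, Y, cfg.d)
        elif cfg.method == "warping":
            warp_result = manifold_warp(
                X, Y, k=cfg.k, d=cfg.d, mu=cfg.mu,
                max_iter=cfg.max_warp_iter, metric=cfg.metric,
            )
            emb = warp_result.embedding
            W = path_to_matrix(warp_result.path, m_x, m_y)
            if not warp_result.converged:
                run_warnings.append("manifold warp did not converge")
        elif cfg.method == "cca":
            emb = cca_align(X, Y, W, cfg.d)
        else:  # none: pass-through baseline on the shared leading sample columns
            d_shared = min(X.shape[1], Y.shape[1])
            coords = np.vstack(
                [X.to_numpy()[:, :d_shared], Y.to_numpy()[:, :d_shared]]
            )
            emb = Embedding(
                coords=coords,
                block_sizes=(m_x, m_y),
                method="none",
                gene_ids_x=list(X.index),
                gene_ids_y=list(Y.index),
            )

    with stage("cluster"):
        labels = kmedoids_cluster(emb.coords, cfg.n_modules, seed=cfg.seed)

    with stage("typing"):
        origins = np.array(["X"] * m_x + ["Y"] * m_y)
        stats = module_stats(
            labels,
            origins,
            W,
            kappa_mode=cfg.kappa_mode,
            kappa_orientation=cfg.kappa_orientation,
            seed=cfg.seed,
        )
        modules = emb.to_frame()[["gene_id", "dataset"]].copy()
        modules["module"] = labels
        modules["module_type"] = stats["module_type"].reindex(labels).to_numpy()

    with stage("evaluate"):
        total, per_pair = alignment_error(emb.x_coords, emb.y_coords, W)
        evaluation = {
            "metric": "chebyshev",
            "total_pair_distance": total,
            "mean_pair_distance": float(np.mean(per_pair)),
            "median_pair_distance": float(np.median(per_pair)),
            "n_pairs": int(per_pair.size),
            "type_counts": stats["module_type"].value_counts().to_dict(),
        }

    summary = {
        "config": asdict(cfg),
        "version": __version__,
        "python": platform.python_version(),
        "n_genes_x": int(m_x),
        "n_genes_y": int(m_y),
        "eigenvalues": (
            [float(v) for v in emb.eigenvalues] if emb.eigenvalues is not None else None
        ),
        "timings_s": timings,
        "warnings": run_warnings,
    }
    if warp_result is not None:
        summary["warp"] = {
            "n_iter": warp_result.n_iter,
            "converged": warp_result.converged,
            "path_cost": warp_result.path.total_cost,
        }

    result = PipelineResult(
        embedding=emb,
        modules=modules,
        stats=stats,
        evaluation=evaluation,
        summary=summary,
        warnings=run_warnings,
    )
    if cfg.outdir is not None:
        _write_outputs(result, Path(cfg.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    emb = result.embedding.to_frame()
    emb.to_csv(outdir / "embedding.tsv", sep="\t", index=False)
    result.modules.to_csv(outdir / "modules.tsv", sep="\t", index=False)
    result.stats.to_csv(outdir / "module_stats.tsv", sep="\t", index_label="module")
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(result.evaluation, fh, indent=2)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
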