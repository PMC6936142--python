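"""Cross-dataset correspondence matrices.

The correspondence matrix W (m_X x m_Y) encodes which genes in the two
datasets should land near each other on the common manifold:

* identity — same gene ids across two conditions of one organism;
* ortholog — curated ortholog pairs across two species (many-to-many kept);
* warped   — a dynamic-time-warping path indicator learned when the two
  datasets are ordered sequences (e.g. time courses) with no given pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "identity_correspondence",
    "ortholog_correspondence",
    "dtw_path",
    "WarpPath",
    "path_to_matrix",
]


def identity_correspondence(ids_X, ids_Y) -> np.ndarray:
    """W[i, j] = 1 iff ids_X[i] == ids_Y[j]; errors if no id is shared."""
    ids_X = list(ids_X)
    ids_Y = list(ids_Y)
    pos_Y: dict = {}
    for j, g in enumerate(ids_Y):
        pos_Y.setdefault(g, []).append(j)
    W = np.zeros((len(ids_X), len(ids_Y)))
    hits = 0
    for i, g in enumerate(ids_X):
        for j in pos_Y.get(g, ()):
            W[i, j] = 1.0
            hits += 1
    if hits == 0:
        raise ValueError("no shared gene ids between the two datasets; alignment impossible")
    return W


def ortholog_correspondence(pairs: pd.DataFrame, ids_X, ids_Y) -> np.ndarray:
    """Binary/weighted W from an ortholog pair table.

    ``pairs`` has columns ``gene_x, gene_y`` and optionally ``weight``.
    Many-to-many pairs are kept as-is.  Pairs naming an absent id are dropped
    with a logged count; zero resolvable pairs is an error.
    """
    idx_X = {g: i for i, g in enumerate(ids_X)}
    idx_Y = {g: j for j, g in enumerate(ids_Y)}
    W = np.zeros((len(idx_X), len(idx_Y)))
    weights = pairs["weight"] if "weight" in pairs.columns else pd.Series(1.0, index=pairs.index)
    dropped = 0
    for gx, gy, w in zip(pairs["gene_x"], pairs["gene_y"], weights):
        i = idx_X.get(gx)
        j = idx_Y.get(gy)
        if i is None or j is None:
            dropped += 1
            continue
        W[i, j] = float(w)
    if dropped:
        logger.warning("dropped %d correspondence pairs naming absent gene ids", dropped)
    if not (W > 0).any():
        raise ValueError("no correspondence pair resolved against the given gene ids")
    return W


@dataclass(frozen=True)
class WarpPath:
    """A monotone DTW alignment path between two ordered sequences."""

    steps: tuple = field(default_factory=tuple)  # ordered (i, j) index pairs
    total_cost: float = 0.0

    def __post_init__(self):
        if not self.steps:
            raise ValueError("warp path must contain at least one step")
        i0, j0 = self.steps[0]
        if (i0, j0) != (0, 0):
            raise ValueError("warp path must start at (0, 0)")
        for (ia, ja), (ib, jb) in zip(self.steps, self.steps[1:]):
            di, dj = ib - ia, jb - ja
            if (di, dj) not in {(1, 0), (0, 1), (1, 1)}:
                raise ValueError(f"non-monotone warp step ({ia},{ja}) -> ({ib},{jb})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["i", "j"])


def _pointwise_distance(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        diff = A[:, None, :] - B[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "chebyshev":
        diff = np.abs(A[:, None, :] - B[None, :, :])
        return diff.max(axis=2)
    raise ValueError(f"unsupported metric {metric!r}")


def dtw_path(seq_A, seq_B, metric: str = "euclidean") -> WarpPath:
    """Classical dynamic time warping between two coordinate sequences.

    Finds the monotone, continuous path from (0, 0) to (|A|-1, |B|-1) using
    steps {(1,0), (0,1), (1,1)} that minimizes the sum of pointwise distances
    along the path.  Ties during backtracking prefer the diagonal move, then
    the vertical one, for determinism.
    """
    A = np.atleast_2d(np.asarray(seq_A, float))
    B = np.atleast_2d(np.asarray(seq_B, float))
    if A.shape[0] == 1 and np.asarray(seq_A).ndim == 1:
        A = A.T
    if B.shape[0] == 1 and np.asarray(seq_B).ndim == 1:
        B = B.T
    if A.size == 0 or B.size == 0:
        raise ValueError("both sequences must be nonempty")
    nA, nB = A.shape[0], B.shape[0]
    cost = _pointwise_distance(A, B, metric)

    acc = np.full((nA, nB), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(nA):
        for j in range(nB):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = acc[i - 1, j - 1]
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            acc[i, j] = cost[i, j] + best

    # backtrack, preferring diagonal on ties
    steps = [(nA - 1, nB - 1)]
    i, j = nA - 1, nB - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], 1, (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(candidates)
        steps.append((i, j))
    steps.reverse()
    return WarpPath(steps=tuple(steps), total_cost=float(acc[nA - 1, nB - 1]))


def path_to_matrix(path: WarpPath, m_X: int, m_Y: int) -> np.ndarray:
    """Binary correspondence matrix with 1 wherever the warp path visits."""
    W = np.zeros((m_X, m_Y))
    for i, j in path.steps:
        W[i, j] = 1.0
    return W
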