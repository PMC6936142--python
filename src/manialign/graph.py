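"""k-nearest-neighbor gene graphs and graph Laplacians.

Each dataset's manifold is approximated by a kNN graph over gene expression
profiles: gene i is connected to its k closest genes, and the directed edge
set is symmetrized by union so no gene is left isolated.  The unnormalized
Laplacian L = D - W of that graph measures smoothness of functions over the
manifold approximation: f'Lf = (1/2) * sum_ij W_ij (f_i - f_j)^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances

__all__ = ["knn_graph", "laplacian"]

_METRICS = {"euclidean", "correlation"}


def knn_graph(
    X,
    k: int,
    metric: str = "euclidean",
    weights: str = "binary",
    sigma: float | None = None,
) -> np.ndarray:
    """Union-symmetrized kNN affinity matrix over the rows of ``X``.

    Parameters
    ----------
    X : DataFrame or array, genes x samples
    k : neighbors per gene, 1 <= k <= m-1
    metric : 'euclidean' or 'correlation' (correlation distance 1 - r)
    weights : 'binary' (default) or 'heat' for exp(-d^2 / sigma^2) edge
        weights; ``sigma`` defaults to the median neighbor distance.

    Ties in neighbor distance are broken toward the smaller gene index
    (stable argsort), so the graph is deterministic.
    """
    values = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    m = values.shape[0]
    if not 1 <= k <= m - 1:
        raise ValueError(f"k must satisfy 1 <= k <= m-1 = {m - 1}, got {k}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}, got {metric!r}")

    D = pairwise_distances(values, metric=metric)
    np.fill_diagonal(D, np.inf)  # no self loops
    # stable sort -> deterministic tie-break by smaller index
    order = np.argsort(D, axis=1, kind="stable")
    neighbors = order[:, :k]

    W = np.zeros((m, m))
    rows = np.repeat(np.arange(m), k)
    cols = neighbors.ravel()
    if weights == "binary":
        W[rows, cols] = 1.0
    elif weights == "heat":
        d_sel = D[rows, cols]
        if sigma is None:
            sigma = float(np.median(d_sel))
            if sigma == 0:
                sigma = 1.0
        W[rows, cols] = np.exp(-(d_sel**2) / sigma**2)
    else:
        raise ValueError(f"weights must be 'binary' or 'heat', got {weights!r}")
    # union symmetrization: keep an edge if either endpoint selected the other
    W = np.maximum(W, W.T)
    return W


def laplacian(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized graph Laplacian ``L = D - W`` and the degree vector.

    Returns ``(L, degree)`` with ``degree`` the row sums of ``W``.
    """
    W = np.asarray(W, float)
    if W.shape[0] != W.shape[1]:
        raise ValueError("affinity matrix must be square")
    degree = W.sum(axis=1)
    L = np.diag(degree) - W
    return L, degree
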