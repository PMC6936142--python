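"""Joint-graph assembly and manifold alignment solvers.

Two datasets X (m_X genes) and Y (m_Y genes), each with its own kNN affinity
W_X / W_Y, are coupled through a cross-dataset correspondence W into a joint
similarity matrix

    W_joint = [[ mu * W_X,        (1 - mu) * W ],
               [ (1 - mu) * W^T,  mu * W_Y     ]]

whose Laplacian L and degree diagonal D define the alignment objective
trace(P' L P) under the scale constraint P' D P = I.  Minimizers are the
bottom nontrivial generalized eigenvectors of L p = lambda D p
(nonparametric variant) or Z'LZ p = lambda Z'DZ p with Z the block-diagonal
stack of the raw data (linear variant, yielding explicit projection maps
F and G).  mu in [0, 1] trades preserving each dataset's local geometry
(mu -> 1) against pulling corresponded genes together (mu -> 0); the default
is 1/2.

Manifold warping handles the case where the correspondence itself is
unknown but both datasets are ordered (e.g. time courses): it alternates
alignment with the current correspondence and dynamic time warping on the
embedded coordinates to re-estimate it.

A linear CCA alignment over corresponded pairs is provided as a baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cross_decomposition import CCA

from .correspondence import WarpPath, dtw_path, path_to_matrix
from .graph import knn_graph, laplacian

logger = logging.getLogger(__name__)

__all__ = [
    "JointSystem",
    "Embedding",
    "joint_system",
    "align_nonparametric",
    "align_linear",
    "manifold_warp",
    "WarpAlignment",
    "cca_align",
    "alignment_loss",
]

# eigenvalues below this are constant modes of connected components and carry
# no geometry; they are discarded before taking the d embedding coordinates
TRIVIAL_EIGENVALUE = 1e-8


@dataclass
class JointSystem:
    """Assembled joint similarity, Laplacian and degree for two coupled graphs."""

    similarity: np.ndarray
    laplacian: np.ndarray
    degree: np.ndarray
    mu: float
    block_sizes: tuple


@dataclass
class Embedding:
    """Coordinates of both datasets on the shared d-dimensional manifold.

    ``coords`` stacks the m_X rows for dataset X above the m_Y rows for
    dataset Y.  For the linear variant, ``F`` and ``G`` hold the explicit
    projection matrices with ``x_coords = X @ F``.
    """

    coords: np.ndarray
    block_sizes: tuple
    eigenvalues: np.ndarray | None = None
    method: str = "nonparametric"
    F: np.ndarray | None = None
    G: np.ndarray | None = None
    gene_ids_x: list = field(default_factory=list)
    gene_ids_y: list = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    @property
    def x_coords(self) -> np.ndarray:
        return self.coords[: self.block_sizes[0]]

    @property
    def y_coords(self) -> np.ndarray:
        return self.coords[self.block_sizes[0]:]

    def to_frame(self) -> pd.DataFrame:
        m_x, m_y = self.block_sizes
        ids = list(self.gene_ids_x) or [f"x{i}" for i in range(m_x)]
        ids += list(self.gene_ids_y) or [f"y{j}" for j in range(m_y)]
        out = pd.DataFrame(
            self.coords, columns=[f"dim_{k + 1}" for k in range(self.d)]
        )
        out.insert(0, "dataset", ["X"] * m_x + ["Y"] * m_y)
        out.insert(0, "gene_id", ids)
        return out


def joint_system(WX: np.ndarray, WY: np.ndarray, W: np.ndarray, mu: float = 0.5) -> JointSystem:
    """Combine within-dataset affinities and the correspondence into one graph."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    WX = np.asarray(WX, float)
    WY = np.asarray(WY, float)
    W = np.asarray(W, float)
    m_x, m_y = WX.shape[0], WY.shape[0]
    if W.shape != (m_x, m_y):
        raise ValueError(f"correspondence shape {W.shape} != ({m_x}, {m_y})")
    joint = np.block(
        [
            [mu * WX, (1.0 - mu) * W],
            [(1.0 - mu) * W.T, mu * WY],
        ]
    )
    L, degree = laplacian(joint)
    return JointSystem(
        similarity=joint, laplacian=L, degree=degree, mu=mu, block_sizes=(m_x, m_y)
    )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        idx = int(np.argmax(np.abs(out[:, k])))
        if out[idx, k] < 0:
            out[:, k] = -out[:, k]
    return out


def _solve_bottom(A: np.ndarray, B: np.ndarray, d: int):
    """Bottom-d nontrivial solutions of the generalized problem A p = lambda B p.

    B must be symmetric positive definite.  Eigenvalues below
    ``TRIVIAL_EIGENVALUE`` (constant modes of connected components) are
    discarded; the returned vectors are B-orthonormal with the
    largest-entry-positive sign convention.
    """
    eigvals, eigvecs = scipy.linalg.eigh(A, B)
    keep = eigvals >= TRIVIAL_EIGENVALUE
    n_kept = int(keep.sum())
    if n_kept < d:
        raise ValueError(
            f"only {n_kept} nontrivial eigenpairs available, need d={d}; "
            "increase k or strengthen the correspondence"
        )
    idx = np.flatnonzero(keep)[:d]
    return eigvals[idx], _fix_signs(eigvecs[:, idx])


def align_nonparametric(S: JointSystem, d: int, gene_ids_x=(), gene_ids_y=()) -> Embedding:
    """Nonparametric alignment: coordinates from L p = lambda D p directly."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if (S.degree <= 0).any():
        bad = int(np.argmax(S.degree <= 0))
        raise ValueError(
            f"joint graph vertex {bad} has zero degree; increase k or provide "
            "a correspondence touching every gene"
        )
    eigvals, P = _solve_bottom(S.laplacian, np.diag(S.degree), d)
    return Embedding(
        coords=P,
        block_sizes=S.block_sizes,
        eigenvalues=eigvals,
        method="nonparametric",
        gene_ids_x=list(gene_ids_x),
        gene_ids_y=list(gene_ids_y),
    )


def align_linear(S: JointSystem, X, Y, d: int) -> Embedding:
    """Linear (parametric) alignment: solve Z'LZ p = lambda Z'DZ p.

    Z is the block-diagonal stack of the raw data matrices, so the solution
    splits into projection maps F (d_X x d) and G (d_Y x d) with embedded
    coordinates X @ F and Y @ G.  A rank-deficient Z'DZ is ridge-regularized
    by 1e-9 on the diagonal (and logged).
    """
    Xv = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Yv = Y.to_numpy() if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    m_x, m_y = S.block_sizes
    if Xv.shape[0] != m_x or Yv.shape[0] != m_y:
        raise ValueError("data matrices do not match the joint system block sizes")
    d_x, d_y = Xv.shape[1], Yv.shape[1]
    if d > d_x + d_y:
        raise ValueError(f"d must be <= d_X + d_Y = {d_x + d_y}")
    Z = scipy.linalg.block_diag(Xv, Yv)
    A = Z.T @ S.laplacian @ Z
    B = Z.T @ (S.degree[:, None] * Z)
    A = (A + A.T) / 2
    B = (B + B.T) / 2
    try:
        scipy.linalg.cholesky(B)
    except scipy.linalg.LinAlgError:
        logger.warning("Z'DZ is rank deficient; adding 1e-9 ridge")
        B = B + 1e-9 * np.eye(B.shape[0])
    eigvals, P = _solve_bottom(A, B, d)
    F, G = P[:d_x], P[d_x:]
    coords = np.vstack([Xv @ F, Yv @ G])
    ids_x = list(X.index) if isinstance(X, pd.DataFrame) else []
    ids_y = list(Y.index) if isinstance(Y, pd.DataFrame) else []
    return Embedding(
        coords=coords,
        block_sizes=(m_x, m_y),
        eigenvalues=eigvals,
        method="linear",
        F=F,
        G=G,
        gene_ids_x=ids_x,
        gene_ids_y=ids_y,
    )


@dataclass
class WarpAlignment:
    """Result of the alternating align/warp loop."""

    embedding: Embedding
    path: WarpPath
    n_iter: int
    converged: bool


def manifold_warp(
    X,
    Y,
    k: int = 3,
    d: int = 3,
    mu: float = 0.5,
    max_iter: int = 10,
    metric: str = "euclidean",
) -> WarpAlignment:
    """Learn correspondence by dynamic time warping while aligning.

    Both datasets must have their rows in a meaningful order (e.g. by time).
    The initial correspondence couples only the first and last rows; each
    iteration embeds with the current correspondence, then re-estimates the
    warp path by DTW on the embedded coordinates.  Stops when the path stops
    changing or after ``max_iter`` iterations (``converged`` is False then).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    Xv = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Yv = Y.to_numpy() if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    m_x, m_y = Xv.shape[0], Yv.shape[0]
    WX = knn_graph(Xv, k=min(k, m_x - 1), metric=metric)
    WY = knn_graph(Yv, k=min(k, m_y - 1), metric=metric)

    W = np.zeros((m_x, m_y))
    W[0, 0] = 1.0
    W[m_x - 1, m_y - 1] = 1.0

    ids_x = list(X.index) if isinstance(X, pd.DataFrame) else []
    ids_y = list(Y.index) if isinstance(Y, pd.DataFrame) else []

    path = None
    converged = False
    for it in range(1, max_iter + 1):
        S = joint_system(WX, WY, W, mu=mu)
        emb = align_nonparametric(S, d, gene_ids_x=ids_x, gene_ids_y=ids_y)
        new_path = dtw_path(emb.x_coords, emb.y_coords, metric=metric)
        if path is not None and new_path.steps == path.steps:
            path = new_path
            converged = True
            break
        path = new_path
        W = path_to_matrix(path, m_x, m_y)
    else:
        it = max_iter
        logger.warning("manifold warp did not converge in %d iterations", max_iter)
    emb.method = "warped"
    return WarpAlignment(embedding=emb, path=path, n_iter=it, converged=converged)


def cca_align(X, Y, W: np.ndarray, d: int) -> Embedding:
    """Linear CCA baseline fitted on corresponded row pairs.

    Every (i, j) with W[i, j] > 0 contributes a paired observation; both full
    datasets are then projected onto the top-d canonical variates.
    """
    Xv = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Yv = Y.to_numpy() if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    pairs = np.argwhere(np.asarray(W) > 0)
    if pairs.shape[0] < d:
        raise ValueError(
            f"CCA needs at least d={d} corresponded pairs, found {pairs.shape[0]}"
        )
    if d > min(Xv.shape[1], Yv.shape[1]):
        raise ValueError("d exceeds the ambient dimension of one dataset")
    model = CCA(n_components=d, max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NIPALS convergence chatter on degenerate fits
        model.fit(Xv[pairs[:, 0]], Yv[pairs[:, 1]])
        fx = model.transform(Xv)
    # transform() only maps the X view; project Y with the fitted Y rotation
    gy = (Yv - model._y_mean) / model._y_std @ model.y_rotations_
    ids_x = list(X.index) if isinstance(X, pd.DataFrame) else []
    ids_y = list(Y.index) if isinstance(Y, pd.DataFrame) else []
    return Embedding(
        coords=np.vstack([fx, gy]),
        block_sizes=(Xv.shape[0], Yv.shape[0]),
        eigenvalues=None,
        method="cca",
        gene_ids_x=ids_x,
        gene_ids_y=ids_y,
    )


def alignment_loss(WX, WY, W, f: np.ndarray, g: np.ndarray, mu: float = 0.5) -> float:
    """Value of the alignment objective for given embedded coordinates.

    (1-mu) * sum_ij ||f_i - g_j||^2 W_ij
      + mu * sum_ij ||f_i - f_j||^2 WX_ij + mu * sum_ij ||g_i - g_j||^2 WY_ij
    """
    WX = np.asarray(WX, float)
    WY = np.asarray(WY, float)
    W = np.asarray(W, float)
    LX, _ = laplacian(WX)
    LY, _ = laplacian(WY)
    cross = 0.0
    for i, j in np.argwhere(W > 0):
        cross += W[i, j] * float(((f[i] - g[j]) ** 2).sum())
    # this equals trace(P' L_joint P) for the joint graph built by joint_system
    smooth_x = float(np.trace(f.T @ LX @ f))
    smooth_y = float(np.trace(g.T @ LY @ g))
    return (1.0 - mu) * cross + mu * smooth_x + mu * smooth_y
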