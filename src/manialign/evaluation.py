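"""Alignment and clustering quality metrics.

Alignment quality is the summed distance between corresponded gene pairs
after embedding (Chebyshev by default — the max coordinate-wise absolute
difference, a cheap proxy for Euclidean distance).  Clustering agreement is
the adjusted Rand index computed from the pair-counting contingency table:

    t1 = sum_i C(|C_i|, 2),  t2 = sum_j C(|C'_j|, 2),
    t3 = 2 t1 t2 / (n (n - 1)),
    ARI = (sum_ij C(m_ij, 2) - t3) / ((t1 + t2)/2 - t3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

__all__ = [
    "alignment_error",
    "adjusted_rand_index",
    "ClusteringComparison",
    "paired_distance_test",
    "planted_type_recovery",
]


def alignment_error(
    f_coords: np.ndarray,
    g_coords: np.ndarray,
    W: np.ndarray,
    metric: str = "chebyshev",
) -> tuple[float, np.ndarray]:
    """Sum of per-pair distances over all corresponded pairs (W > 0).

    Returns ``(total, per_pair)``; each pair's distance is weighted by its
    correspondence weight.
    """
    f_coords = np.asarray(f_coords, float)
    g_coords = np.asarray(g_coords, float)
    W = np.asarray(W, float)
    pairs = np.argwhere(W > 0)
    if pairs.shape[0] == 0:
        raise ValueError("correspondence matrix has no nonzero entries")
    diffs = f_coords[pairs[:, 0]] - g_coords[pairs[:, 1]]
    if metric == "chebyshev":
        dists = np.abs(diffs).max(axis=1)
    elif metric == "euclidean":
        dists = np.sqrt((diffs**2).sum(axis=1))
    else:
        raise ValueError(f"metric must be 'chebyshev' or 'euclidean', got {metric!r}")
    weighted = dists * W[pairs[:, 0], pairs[:, 1]]
    return float(weighted.sum()), weighted


@dataclass
class ClusteringComparison:
    """Contingency table, pair-count terms and the adjusted Rand index."""

    contingency: pd.DataFrame
    t1: float
    t2: float
    t3: float
    ari: float
    n: int


def adjusted_rand_index(C, C_prime) -> ClusteringComparison:
    """Chance-corrected agreement between two partitions of the same items.

    ARI = 1 for identical partitions (up to relabeling), ~0 for independent
    ones; can be negative for partitions that disagree more than chance.
    """
    a = pd.Series(list(C))
    b = pd.Series(list(C_prime))
    if len(a) != len(b):
        raise ValueError("partitions must cover the same observations")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 observations")
    contingency = pd.crosstab(a, b)
    m = contingency.to_numpy()
    t1 = float(comb(m.sum(axis=1), 2).sum())
    t2 = float(comb(m.sum(axis=0), 2).sum())
    t3 = 2.0 * t1 * t2 / (n * (n - 1))
    numer = float(comb(m, 2).sum()) - t3
    denom = 0.5 * (t1 + t2) - t3
    ari = 1.0 if denom == 0 else numer / denom
    return ClusteringComparison(
        contingency=contingency, t1=t1, t2=t2, t3=t3, ari=ari, n=n
    )


def paired_distance_test(dist_A, dist_B) -> float:
    """Welch two-sample t-test p-value on two per-pair distance vectors."""
    a = np.asarray(dist_A, float)
    b = np.asarray(dist_B, float)
    if a.shape != b.shape:
        raise ValueError("distance vectors must have equal length (same pairs)")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.array_equal(a, b):
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def planted_type_recovery(truth: pd.DataFrame, modules: pd.DataFrame) -> pd.DataFrame:
    """Compare recovered module types against planted ground truth.

    ``truth`` holds one row per (gene_id, dataset) with columns
    ``module`` (planted label) and ``module_type``; ``modules`` is a pipeline
    output with the same key columns plus the recovered ``module`` and
    ``module_type``.  Each planted module is matched to the recovered module
    containing the plurality of its members; recovery succeeds when the
    matched module's type equals the planted type.
    """
    merged = truth.merge(
        modules,
        on=["gene_id", "dataset"],
        suffixes=("_true", "_pred"),
        validate="one_to_one",
    )
    records = []
    for planted, grp in merged.groupby("module_true"):
        best = grp["module_pred"].mode().iloc[0]
        pred_type = modules.loc[modules["module"] == best, "module_type"].iloc[0]
        true_type = grp["module_type_true"].iloc[0]
        records.append(
            {
                "planted_module": planted,
                "matched_module": best,
                "true_type": true_type,
                "predicted_type": pred_type,
                "recovered": pred_type == true_type,
            }
        )
    return pd.DataFrame(records)
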