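"""Simultaneous clustering of the joint embedding and module typing.

After alignment, the concatenated embedded coordinates of both datasets are
clustered together with k-medoids (chosen for robustness to outliers), so a
module may mix genes from either dataset.  Each module C_i is then scored by

* intra-module Jaccard similarity
      J(C_i) = shared / (specific_1 + specific_2 + shared),
  where "shared" counts corresponded X-Y pairs co-clustered in the module;
* condition number kappa(C_i), the ratio of dataset-specific gene counts
  (by default oriented >= 1, i.e. max(r, 1/r));
* functional linkage score
      S(C_i) = 1 - (|1 - kappa_i|/max_i kappa_i + J_i/max_i J_i)
                   / max_i(|1 - kappa_i|/max_i kappa_i + J_i/max_i J_i),
  high when a module is balanced across datasets (kappa near 1) yet has few
  shared genes (low J) — the signature of a functional linkage module.

Module types are assigned with data-driven thresholds: 1-D k-means (k=2)
separates high from low J (high => conserved); among the rest, modules whose
specific counts are one-sided are condition-specific outright; the remaining
two-sided modules are split by k-means on S (high => functional linkage),
falling back to the raw kappa orientation (>1 dataset-1-specific, <1
dataset-2-specific, =1 functional linkage).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances

logger = logging.getLogger(__name__)

__all__ = [
    "kmedoids_cluster",
    "module_composition",
    "jaccard_similarity",
    "condition_number",
    "functional_linkage_scores",
    "classify_modules",
    "module_stats",
]


def _kmedoidspp_init(D: np.ndarray, n: int, rng: np.random.Generator) -> list:
    """k-medoids++ seeding: subsequent medoids sampled ~ squared distance."""
    m = D.shape[0]
    medoids = [int(rng.integers(m))]
    for _ in range(n - 1):
        closest = D[:, medoids].min(axis=1)
        weights = closest**2
        total = weights.sum()
        if total == 0:  # all remaining points coincide with a medoid
            candidates = [i for i in range(m) if i not in medoids]
            medoids.append(candidates[0])
            continue
        medoids.append(int(rng.choice(m, p=weights / total)))
    return medoids


def kmedoids_cluster(coords: np.ndarray, n: int, seed: int = 0, max_iter: int = 300) -> np.ndarray:
    """PAM-style k-medoids on Euclidean distances with seeded deterministic init.

    Alternates point-to-nearest-medoid assignment with exact medoid updates
    (each cluster's medoid minimizes the within-cluster distance sum) until
    the medoid set is stable.  Returns a 0-based label per row.
    """
    coords = np.asarray(coords, float)
    m = coords.shape[0]
    n_distinct = np.unique(coords, axis=0).shape[0]
    if not 1 <= n <= m:
        raise ValueError(f"module count n must be in [1, {m}], got {n}")
    if n > n_distinct:
        raise ValueError(
            f"n={n} exceeds the {n_distinct} distinct embedded points"
        )
    D = pairwise_distances(coords)
    rng = np.random.default_rng(seed)
    medoids = _kmedoidspp_init(D, n, rng)

    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = []
        for c in range(n):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                # re-seed an empty cluster at the point farthest from its medoid
                far = int(np.argmax(D[:, medoids].min(axis=1)))
                new_medoids.append(far)
                continue
            within = D[np.ix_(members, members)].sum(axis=0)
            new_medoids.append(int(members[np.argmin(within)]))
        if sorted(new_medoids) == sorted(medoids):
            medoids = new_medoids
            break
        medoids = new_medoids
    labels = np.argmin(D[:, medoids], axis=1)
    return labels.astype(int)


def module_composition(
    labels: np.ndarray,
    origins,
    W: np.ndarray,
) -> pd.DataFrame:
    """Per-module shared / dataset-specific gene counts.

    ``labels`` gives a module per embedded row (X rows first, then Y rows, in
    the order used to build the correspondence ``W``); ``origins`` marks each
    row 'X' or 'Y'.  A corresponded X-Y pair co-clustered in a module
    contributes one shared count; genes with no in-module partner count as
    dataset-specific.
    """
    labels = np.asarray(labels)
    origins = np.asarray(origins)
    W = np.asarray(W)
    x_rows = np.flatnonzero(origins == "X")
    y_rows = np.flatnonzero(origins == "Y")
    if W.shape != (x_rows.size, y_rows.size):
        raise ValueError(
            f"correspondence shape {W.shape} does not match origin counts "
            f"({x_rows.size}, {y_rows.size})"
        )
    pairs = np.argwhere(W > 0)
    records = []
    for module in np.unique(labels):
        in_x = np.flatnonzero(labels[x_rows] == module)  # X-local indices
        in_y = np.flatnonzero(labels[y_rows] == module)
        in_x_set, in_y_set = set(in_x), set(in_y)
        module_pairs = [
            (i, j) for i, j in pairs if i in in_x_set and j in in_y_set
        ]
        matched_x = {i for i, _ in module_pairs}
        matched_y = {j for _, j in module_pairs}
        records.append(
            {
                "module": int(module),
                "count_x_specific": len(in_x) - len(matched_x),
                "count_y_specific": len(in_y) - len(matched_y),
                "count_shared": len(module_pairs),
                "size": len(in_x) + len(in_y),
            }
        )
    return pd.DataFrame(records).set_index("module")


def jaccard_similarity(counts: pd.DataFrame) -> pd.Series:
    """J = shared / (x_specific + y_specific + shared) per module."""
    denom = (
        counts["count_x_specific"] + counts["count_y_specific"] + counts["count_shared"]
    )
    J = counts["count_shared"] / denom.where(denom > 0)
    if J.isna().any():
        logger.warning("empty module(s) %s: Jaccard undefined", list(J.index[J.isna()]))
    return J.rename("jaccard")


def condition_number(
    counts: pd.DataFrame, mode: str = "specific", orientation: str = "ge_one"
) -> pd.Series:
    """kappa per module: ratio of dataset-1 to dataset-2 gene counts.

    ``mode='specific'`` (default) uses dataset-specific counts only;
    ``mode='all'`` includes shared genes on both sides.  With
    ``orientation='ge_one'`` (default) the ratio is folded to max(r, 1/r);
    ``'raw'`` reports x/y as-is.  Both sides zero => kappa := 1 (fully
    conserved module); exactly one side zero => +inf sentinel.
    """
    if mode == "specific":
        num = counts["count_x_specific"].astype(float)
        den = counts["count_y_specific"].astype(float)
    elif mode == "all":
        num = (counts["count_x_specific"] + counts["count_shared"]).astype(float)
        den = (counts["count_y_specific"] + counts["count_shared"]).astype(float)
    else:
        raise ValueError(f"mode must be 'specific' or 'all', got {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = num / den
    kappa[(num == 0) & (den == 0)] = 1.0
    if orientation == "ge_one":
        kappa = np.maximum(kappa, np.where(kappa > 0, 1.0 / kappa, np.inf))
        kappa[(num == 0) & (den == 0)] = 1.0
    elif orientation != "raw":
        raise ValueError(f"orientation must be 'ge_one' or 'raw', got {orientation!r}")
    if orientation == "ge_one" and np.isinf(kappa).any():
        logger.warning(
            "module(s) %s have genes from one dataset only: kappa = inf",
            list(kappa.index[np.isinf(kappa)]),
        )
    return kappa.rename("condition_number")


def functional_linkage_scores(J: pd.Series, kappa: pd.Series) -> pd.Series:
    """Normalized composite of |1 - kappa| and J; 1 = most functionally linked.

    The kappa normalizer max_i kappa_i is taken over modules with finite
    kappa; a one-sided module (infinite kappa) receives the limiting value
    of its own term, |1 - kappa|/kappa -> 1, which correctly ranks it as far
    from the balanced kappa = 1 regime.  If every module has J = 0 and
    kappa = 1 the score is degenerate and set to 1 everywhere.
    """
    J = pd.Series(J, dtype=float)
    kappa = pd.Series(kappa, dtype=float)
    finite = np.isfinite(kappa)
    max_J = J.max()
    j_term = J / max_J if max_J > 0 else pd.Series(0.0, index=J.index)
    if finite.any():
        max_kappa = kappa[finite].max()
        k_term = (1.0 - kappa).abs() / max_kappa
    else:
        k_term = pd.Series(np.inf, index=J.index)
    k_term[~finite] = 1.0  # limit of |1 - kappa| / kappa as kappa -> inf
    combined = k_term + j_term
    max_combined = combined.max()
    if max_combined == 0:
        logger.warning("all modules have J=0 and kappa=1; linkage scores degenerate")
        return pd.Series(1.0, index=J.index, name="linkage_score")
    S = 1.0 - combined / max_combined
    if (~finite).any():
        logger.warning(
            "one-sided module(s) %s scored with the limiting kappa term",
            list(kappa.index[~finite]),
        )
    return S.clip(0.0, 1.0).rename("linkage_score")


def _split_high(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """Boolean mask of the 'high' group from 1-D k-means with k=2.

    Falls back to a 0.5 threshold when there are fewer than two distinct
    finite values.  Ties between centroids resolve with the lower centroid
    as the 'low' group.
    """
    values = np.asarray(values, float)
    finite = values[np.isfinite(values)]
    if np.unique(finite).size < 2:
        return values >= 0.5
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    high_label = int(np.argmax(km.cluster_centers_.ravel()))
    return labels == high_label


def classify_modules(
    J: pd.Series,
    S: pd.Series,
    kappa_raw: pd.Series,
    seed: int = 0,
) -> pd.Series:
    """Assign each module one of: conserved, X_specific, Y_specific, functional_linkage.

    ``kappa_raw`` must be the raw-orientation ratio of dataset-1-specific to
    dataset-2-specific counts (inf/0 for one-sided modules).  Thresholds on J
    and S are determined by 1-D k-means rather than fixed cutoffs; one-sided
    modules skip the linkage-score split because they are specific by
    construction.
    """
    J = pd.Series(J, dtype=float)
    S = pd.Series(S, dtype=float)
    kappa_raw = pd.Series(kappa_raw, dtype=float)
    types = pd.Series("", index=J.index, name="module_type")
    if len(J) < 2:
        for i in J.index:
            if J.loc[i] >= 0.5:
                types.loc[i] = "conserved"
            elif kappa_raw.loc[i] > 1:
                types.loc[i] = "X_specific"
            elif kappa_raw.loc[i] < 1:
                types.loc[i] = "Y_specific"
            else:
                types.loc[i] = "functional_linkage"
        return types

    high_J = pd.Series(_split_high(J.to_numpy(), seed=seed), index=J.index)
    types[high_J] = "conserved"

    low = ~high_J
    one_sided = low & (np.isinf(kappa_raw) | (kappa_raw == 0))
    types[one_sided & np.isinf(kappa_raw)] = "X_specific"
    types[one_sided & (kappa_raw == 0)] = "Y_specific"

    rest = low & ~one_sided
    if rest.any():
        rest_idx = J.index[rest]
        high_S = pd.Series(
            _split_high(S.loc[rest_idx].to_numpy(), seed=seed), index=rest_idx
        )
        for i in rest_idx:
            if high_S.loc[i]:
                types.loc[i] = "functional_linkage"
            elif kappa_raw.loc[i] > 1:
                types.loc[i] = "X_specific"
            elif kappa_raw.loc[i] < 1:
                types.loc[i] = "Y_specific"
            else:
                types.loc[i] = "functional_linkage"
    return types


def module_stats(
    labels: np.ndarray,
    origins,
    W: np.ndarray,
    kappa_mode: str = "specific",
    kappa_orientation: str = "ge_one",
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-module statistics table: counts, J, kappa, S and type."""
    counts = module_composition(labels, origins, W)
    J = jaccard_similarity(counts)
    kappa = condition_number(counts, mode=kappa_mode, orientation=kappa_orientation)
    kappa_raw = condition_number(counts, mode="specific", orientation="raw")
    S = functional_linkage_scores(J, condition_number(counts))
    types = classify_modules(J, S, kappa_raw, seed=seed)
    return pd.concat([counts, J, kappa, S, types], axis=1)
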