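"""Synthetic paired expression datasets with planted manifold structure.

The generator emulates the setting the method targets: two expression
datasets that share a 1-D latent trajectory (e.g. developmental or diurnal
progression) observed through different nonlinear "lifts" into each
dataset's sample space.  Genes are planted into modules of four types:

* conserved          — same gene ids in both datasets at the same latent
                       position (high in-module overlap after alignment);
* X_specific         — genes present in dataset X only;
* Y_specific         — genes present in dataset Y only;
* functional_linkage — disjoint X and Y gene sets at the same latent
                       position, bridged by a small shared set (5% of the
                       module by default), mirroring modules linked across
                       conditions by few common genes.

Module latent intervals are laid out as [conserved | X_specific |
functional_linkage | Y_specific] so that each dataset's own coverage keeps
the joint graph connected through the correspondence.

Default sample counts (13 for X, 15 for Y) echo a light/dark diurnal
time-course design; the default noise (sd 0.05 on unit-scale profiles) is
small relative to the arc-length signal so planted geometry is present but
not trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SyntheticScenario", "make_paired_manifold", "make_warp_pair"]

_TYPES = ("conserved", "X_specific", "Y_specific", "functional_linkage")


@dataclass
class SyntheticScenario:
    """A generated pair of expression matrices with ground truth."""

    X: pd.DataFrame
    Y: pd.DataFrame
    pairs: pd.DataFrame  # columns gene_x, gene_y, weight
    true_modules: pd.DataFrame | None  # columns gene_id, dataset, module, module_type
    seed: int
    noise_sd: float
    times_X: np.ndarray | None = None  # warp scenarios only
    times_Y: np.ndarray | None = None


def _curve3(t: np.ndarray, kind: str) -> np.ndarray:
    """Injective smooth 1-D curve in R^3 parameterized by t in [0, 1]."""
    t = np.asarray(t, float)
    if kind == "scurve":
        u = 3.0 * np.pi * (t - 0.5)
        return np.column_stack([np.sin(u), np.sign(u) * (np.cos(u) - 1.0), u / (3 * np.pi)])
    if kind == "swissroll":
        u = 1.5 * np.pi * (1.0 + 2.0 * t)
        return np.column_stack([u * np.cos(u), u * np.sin(u), u]) / (4.5 * np.pi)
    if kind == "linear":
        return np.column_stack([t, 2.0 * t, -t])
    raise ValueError(f"nonlinearity must be scurve, swissroll or linear, got {kind!r}")


def _lift(base3: np.ndarray, n_dims: int, rng: np.random.Generator) -> np.ndarray:
    """Embed a 3-D curve into n_dims ambient dimensions by a random rotation."""
    raw = rng.standard_normal((3, n_dims))
    q, _ = np.linalg.qr(raw.T)  # n_dims x 3 with orthonormal columns
    return base3 @ q[:, :3].T


def _lift_identity(base3: np.ndarray, n_dims: int) -> np.ndarray:
    out = np.zeros((base3.shape[0], n_dims))
    out[:, :3] = base3
    return out


def make_paired_manifold(
    n_genes_per_type: tuple = (40, 40, 40, 40),
    n_samples_X: int = 13,
    n_samples_Y: int = 15,
    nonlinearity: str = "scurve",
    noise_sd: float = 0.05,
    seed: int = 0,
    bridge_fraction: float = 0.05,
    same_lift: bool = False,
    amplitude: float = 8.0,
) -> SyntheticScenario:
    """Generate a paired-dataset scenario with one planted module per type.

    ``n_genes_per_type`` gives gene counts for (conserved, X_specific,
    Y_specific, functional_linkage).  With ``same_lift=True`` both datasets
    use the identical (axis-aligned) lift, which requires equal sample
    counts; combined with ``nonlinearity='linear'`` and ``noise_sd=0`` the
    corresponded rows are then identical — a useful degenerate check.

    ``amplitude`` scales the latent curve so profile dynamics span a
    log2-expression-like range (roughly +/- 2 x amplitude) against which the
    additive measurement noise is small but not negligible.
    """
    counts = tuple(int(c) for c in n_genes_per_type)
    if len(counts) != 4 or any(c < 0 for c in counts):
        raise ValueError("n_genes_per_type must be 4 non-negative counts")
    if sum(counts) == 0:
        raise ValueError("at least one module type must have genes")
    if same_lift and n_samples_X != n_samples_Y:
        raise ValueError("same_lift requires equal sample counts")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    # latent interval per planted module; this ordering keeps each dataset's
    # own arc coverage contiguous (X spans the first three intervals, Y the
    # last three) so both kNN graphs stay connected, and places the
    # functional-linkage region next to the conserved anchor
    layout = ["X_specific", "conserved", "functional_linkage", "Y_specific"]
    present = [t for t in layout if counts[_TYPES.index(t)] > 0]
    width = 1.0 / len(present)
    intervals = {t: (i * width, (i + 1) * width) for i, t in enumerate(present)}

    x_ids, x_t = [], []
    y_ids, y_t = [], []
    truth_rows = []
    pair_rows = []

    for module_idx, mtype in enumerate(present):
        c = counts[_TYPES.index(mtype)]
        lo, hi = intervals[mtype]
        # near-regular spacing with jitter: regular enough that the kNN chain
        # along the trajectory stays connected, jittered so runs differ by seed
        spacing = (hi - lo) / c
        t_vals = lo + spacing * (np.arange(c) + 0.5)
        t_vals = np.sort(t_vals + rng.uniform(-spacing / 4, spacing / 4, size=c))
        if mtype == "conserved":
            for g, t in enumerate(t_vals):
                gid = f"CONS_{g}"
                x_ids.append(gid); x_t.append(t)
                y_ids.append(gid); y_t.append(t)
                pair_rows.append((gid, gid, 1.0))
                truth_rows.append((gid, "X", module_idx, mtype))
                truth_rows.append((gid, "Y", module_idx, mtype))
        elif mtype == "X_specific":
            for g, t in enumerate(t_vals):
                gid = f"XSP_{g}"
                x_ids.append(gid); x_t.append(t)
                truth_rows.append((gid, "X", module_idx, mtype))
        elif mtype == "Y_specific":
            for g, t in enumerate(t_vals):
                gid = f"YSP_{g}"
                y_ids.append(gid); y_t.append(t)
                truth_rows.append((gid, "Y", module_idx, mtype))
        else:  # functional_linkage: disjoint halves plus a small shared bridge
            # both halves span the SAME latent positions, so the module sits
            # at one arc location in both datasets; bridge genes are spread
            # across the interval to tie the two strands together
            n_bridge = max(1, int(round(bridge_fraction * c)))
            n_half = max(1, (c - n_bridge) // 2)
            half_spacing = (hi - lo) / n_half
            t_half = lo + half_spacing * (np.arange(n_half) + 0.5)
            t_fx = np.sort(t_half + rng.uniform(-half_spacing / 4, half_spacing / 4, n_half))
            t_fy = np.sort(t_half + rng.uniform(-half_spacing / 4, half_spacing / 4, n_half))
            t_bridge = np.quantile(t_half, np.linspace(0.1, 0.9, n_bridge))
            for g, t in enumerate(t_fx):
                gid = f"FLX_{g}"
                x_ids.append(gid); x_t.append(t)
                truth_rows.append((gid, "X", module_idx, mtype))
            for g, t in enumerate(t_fy):
                gid = f"FLY_{g}"
                y_ids.append(gid); y_t.append(t)
                truth_rows.append((gid, "Y", module_idx, mtype))
            for g, t in enumerate(t_bridge):
                gid = f"FLB_{g}"
                x_ids.append(gid); x_t.append(t)
                y_ids.append(gid); y_t.append(t)
                pair_rows.append((gid, gid, 1.0))
                truth_rows.append((gid, "X", module_idx, mtype))
                truth_rows.append((gid, "Y", module_idx, mtype))

    base_x = amplitude * _curve3(np.array(x_t), nonlinearity)
    base_y = amplitude * _curve3(np.array(y_t), nonlinearity)
    if same_lift:
        profiles_x = _lift_identity(base_x, n_samples_X)
        profiles_y = _lift_identity(base_y, n_samples_Y)
    else:
        profiles_x = _lift(base_x, n_samples_X, rng)
        profiles_y = _lift(base_y, n_samples_Y, rng)
    if noise_sd > 0:
        profiles_x = profiles_x + rng.normal(0, noise_sd, profiles_x.shape)
        profiles_y = profiles_y + rng.normal(0, noise_sd, profiles_y.shape)

    X = pd.DataFrame(
        profiles_x, index=x_ids, columns=[f"sx{j}" for j in range(n_samples_X)]
    )
    Y = pd.DataFrame(
        profiles_y, index=y_ids, columns=[f"sy{j}" for j in range(n_samples_Y)]
    )
    pairs = pd.DataFrame(pair_rows, columns=["gene_x", "gene_y", "weight"])
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "dataset", "module", "module_type"]
    )
    return SyntheticScenario(
        X=X, Y=Y, pairs=pairs, true_modules=truth, seed=seed, noise_sd=noise_sd
    )


_WARPS = {
    "identity": lambda u: u,
    "quadratic": lambda u: u**2,
    "sqrt": lambda u: np.sqrt(u),
    # second half of the trajectory traversed at double speed
    "double_speed_second_half": lambda u: np.where(
        u < 0.5, u * 2.0 / 3.0, 1.0 / 3.0 + (u - 0.5) * 4.0 / 3.0
    ),
}


def make_warp_pair(
    n_timepoints_X: int = 30,
    n_timepoints_Y: int = 30,
    warp: str = "identity",
    n_features: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticScenario:
    """Sample one latent trajectory on two monotonically warped time grids.

    Rows are time points (ordered), columns are features; dataset Y observes
    the trajectory at times ``w(u_j)`` for a monotone warp ``w``.  Useful for
    exercising correspondence learning by dynamic time warping.
    """
    if n_timepoints_X < 3 or n_timepoints_Y < 3:
        raise ValueError("need at least 3 time points per dataset")
    if not 1 <= n_features <= 6:
        raise ValueError("n_features must be between 1 and 6")
    if callable(warp):
        warp_fn = warp
    else:
        try:
            warp_fn = _WARPS[warp]
        except KeyError:
            raise ValueError(f"unknown warp {warp!r}; choose from {sorted(_WARPS)}")
    rng = np.random.default_rng(seed)
    t_x = np.linspace(0.0, 1.0, n_timepoints_X)
    u_y = np.linspace(0.0, 1.0, n_timepoints_Y)
    t_y = np.asarray(warp_fn(u_y), float)
    if np.any(np.diff(t_y) < 0):
        raise ValueError("warp must be monotone non-decreasing on [0, 1]")

    def trajectory(t):
        base = np.column_stack(
            [t, np.sin(np.pi * t), np.cos(np.pi * t), t**2, np.sin(2 * np.pi * t) * 0.5, t**3]
        )
        return base[:, :n_features]

    Xv = trajectory(t_x)
    Yv = trajectory(t_y)
    if noise_sd > 0:
        Xv = Xv + rng.normal(0, noise_sd, Xv.shape)
        Yv = Yv + rng.normal(0, noise_sd, Yv.shape)
    X = pd.DataFrame(
        Xv, index=[f"tx{i}" for i in range(n_timepoints_X)],
        columns=[f"f{j}" for j in range(Xv.shape[1])],
    )
    Y = pd.DataFrame(
        Yv, index=[f"ty{j}" for j in range(n_timepoints_Y)],
        columns=[f"f{j}" for j in range(Yv.shape[1])],
    )
    pairs = pd.DataFrame(columns=["gene_x", "gene_y", "weight"])
    return SyntheticScenario(
        X=X, Y=Y, pairs=pairs, true_modules=None, seed=seed, noise_sd=noise_sd,
        times_X=t_x, times_Y=t_y,
    )
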