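"""Expression-table I/O and preprocessing.

An expression matrix is a pandas :class:`~pandas.DataFrame` with genes as the
index (rows) and samples/time points as columns.  All functions here validate
their inputs and return new frames; nothing is modified in place.

The preprocessing chain mirrors common RNA-seq practice for time-course data:
drop genes that never rise above a detection floor, log2-transform with a
pseudocount, and scale each sample column to unit Euclidean norm so that
between-gene distances compare expression *shape* rather than depth.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression",
    "save_expression",
    "load_correspondence",
    "save_correspondence",
    "filter_low_expression",
    "log2_transform",
    "unit_normalize",
    "validate_expression",
]


def validate_expression(X: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants, returning ``X`` unchanged.

    Raises ``ValueError`` on duplicate gene ids, missing values or
    non-finite entries.
    """
    if X.index.has_duplicates:
        dups = X.index[X.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    values = X.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = _first_non_numeric(X)
        raise ValueError(f"non-numeric cell at gene {bad[0]!r}, sample {bad[1]!r}")
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at gene {X.index[i]!r}, sample {X.columns[j]!r}"
        )
    return X


def _first_non_numeric(X: pd.DataFrame) -> tuple:
    for j, col in enumerate(X.columns):
        coerced = pd.to_numeric(X.iloc[:, j], errors="coerce")
        bad = coerced.isna() & X.iloc[:, j].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            return X.index[i], col
    return X.index[0], X.columns[0]


def load_expression(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a genes x samples table (first column gene ids, header row samples).

    Raises ``ValueError`` for empty files, duplicate gene ids, or cells that
    cannot be parsed as numbers (the error names the offending location).
    """
    try:
        X = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty expression file: {path}") from exc
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError(f"expression file has no data rows/columns: {path}")
    if X.index.has_duplicates:
        dups = X.index[X.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    non_numeric = [c for c in X.columns if not np.issubdtype(X[c].dtype, np.number)]
    if non_numeric:
        bad = _first_non_numeric(X[non_numeric])
        raise ValueError(
            f"non-numeric cell in {path} at gene {bad[0]!r}, sample {bad[1]!r}"
        )
    return validate_expression(X.astype(float))


def save_expression(X: pd.DataFrame, path, delimiter: str = "\t") -> None:
    X.to_csv(path, sep=delimiter, index_label="gene_id")


def load_correspondence(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a 2- or 3-column pair file ``(id_x, id_y[, weight])``.

    A header row is auto-detected: if a third column exists and its first
    entry is not numeric, or the first two entries of row one look like
    column labels (``id``/``gene`` prefixes), the row is treated as a header.
    Returns a frame with columns ``gene_x, gene_y, weight`` (default 1.0).
    """
    raw = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if raw.shape[1] not in (2, 3):
        raise ValueError(
            f"correspondence file must have 2 or 3 columns, got {raw.shape[1]}"
        )
    first = raw.iloc[0]
    has_header = False
    if raw.shape[1] == 3:
        try:
            float(first.iloc[2])
        except (TypeError, ValueError):
            has_header = True
    if not has_header:
        labels = {str(v).strip().lower() for v in first.iloc[:2]}
        if labels & {"id_x", "id_y", "gene_x", "gene_y", "gene_id_x", "gene_id_y"}:
            has_header = True
    if has_header:
        raw = raw.iloc[1:].reset_index(drop=True)
    if raw.empty:
        raise ValueError(f"correspondence file {path} contains no pairs")
    out = pd.DataFrame(
        {
            "gene_x": raw.iloc[:, 0].astype(str),
            "gene_y": raw.iloc[:, 1].astype(str),
            "weight": raw.iloc[:, 2].astype(float) if raw.shape[1] == 3 else 1.0,
        }
    )
    if (out["weight"] < 0).any():
        raise ValueError("correspondence weights must be non-negative")
    return out


def save_correspondence(pairs: pd.DataFrame, path, delimiter: str = "\t") -> None:
    pairs.to_csv(path, sep=delimiter, index=False, header=False)


def filter_low_expression(
    X: pd.DataFrame, threshold: float, how: str = "all"
) -> pd.DataFrame:
    """Drop genes whose expression stays below ``threshold``.

    ``how='all'`` (default) removes a gene only when *every* sample value is
    below the threshold; ``how='mean'`` removes genes whose mean is below it.
    Surviving gene order is preserved.  Raises if nothing survives.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if how == "all":
        keep = (X >= threshold).any(axis=1)
    elif how == "mean":
        keep = X.mean(axis=1) >= threshold
    else:
        raise ValueError(f"unknown filtering mode {how!r}")
    out = X.loc[keep]
    if out.shape[0] == 0:
        raise ValueError("low-expression filter removed every gene")
    n_removed = X.shape[0] - out.shape[0]
    if n_removed:
        logger.info("filtered %d low-expression genes (threshold=%g)", n_removed, threshold)
    return out


def log2_transform(X: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Replace every value v with log2(v + pseudocount)."""
    shifted = X + pseudocount
    if (shifted.to_numpy() <= 0).any():
        raise ValueError(
            "log2 transform requires value + pseudocount > 0 for every cell"
        )
    return np.log2(shifted)


def unit_normalize(X: pd.DataFrame, axis: str = "per_sample") -> pd.DataFrame:
    """Scale each sample column (or gene row) to Euclidean norm 1.

    All-zero vectors are passed through unchanged so degenerate inputs do not
    abort a run.
    """
    if axis == "per_sample":
        norms = np.linalg.norm(X.to_numpy(), axis=0)
        safe = np.where(norms == 0, 1.0, norms)
        return X / safe
    if axis == "per_gene":
        norms = np.linalg.norm(X.to_numpy(), axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        return X.div(safe, axis=0)
    raise ValueError(f"axis must be 'per_sample' or 'per_gene', got {axis!r}")
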