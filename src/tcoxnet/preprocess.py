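"""Expression-matrix preparation: log2(x+1) transform and degenerate-gene filter.

Expression matrices are plain :class:`pandas.DataFrame` objects with genes as
rows (index = gene ids) and samples as columns (columns = sample ids), on the
log2(x+1) scale once transformed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["log2_plus_one", "drop_null_sd", "validate_expression"]


def validate_expression(X: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix: unique ids, finite float values."""
    if X.index.has_duplicates:
        dup = X.index[X.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dup}")
    if X.columns.has_duplicates:
        dup = X.columns[X.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    values = X.to_numpy(dtype=float, copy=False)
    if not np.all(np.isfinite(values)):
        gi, si = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite expression value at gene {X.index[gi]!r}, "
            f"sample {X.columns[si]!r}"
        )
    return X


def log2_plus_one(raw: pd.DataFrame) -> pd.DataFrame:
    """Transform a non-negative matrix entrywise to log2(x + 1).

    The transform is the standard variance-stabilizing step for RSEM-style
    RNA-seq abundance estimates. Gene/sample identifiers are preserved.

    Raises
    ------
    ValueError
        If any entry is negative (the offending gene and sample are named).
    """
    validate_expression(raw)
    values = raw.to_numpy(dtype=float)
    if np.any(values < 0):
        gi, si = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative expression value {values[gi, si]} at gene "
            f"{raw.index[gi]!r}, sample {raw.columns[si]!r}; "
            "log2(x+1) requires non-negative input"
        )
    return pd.DataFrame(np.log2(values + 1.0), index=raw.index, columns=raw.columns)


def drop_null_sd(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove genes with a null standard deviation (all values identical).

    The test is exact (max equals min), not tolerance-based: the filter is a
    guard against degenerate covariates, for which population-vs-sample
    standard deviation conventions are irrelevant.

    Returns
    -------
    (filtered, removed):
        The matrix restricted to surviving genes, in their original order,
        and the list of removed gene ids.
    """
    validate_expression(X)
    values = X.to_numpy(dtype=float)
    constant = values.max(axis=1) == values.min(axis=1)
    removed = X.index[constant].tolist()
    return X.loc[~constant], removed
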