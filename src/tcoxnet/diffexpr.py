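"""Two-group differential expression on the log2 scale.

Ranks genes by log2 fold change (difference of group means on the already
log-transformed matrix) with a pluggable per-gene significance test and
Benjamini-Hochberg FDR control. The default test is Welch's unequal-variance
t-test; count-model tests (e.g. quasi-likelihood F-tests) are a separate
methodology and deliberately not reimplemented here - any callable mapping
two (genes x samples) arrays to per-gene p-values can be plugged in instead.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_fold_change",
    "per_gene_test",
    "benjamini_hochberg",
    "rank_by",
    "de_table",
]

logger = logging.getLogger(__name__)

#: signature of a pluggable per-gene test: (X_group1, X_group2) -> p-values
PerGeneTest = Callable[[np.ndarray, np.ndarray], np.ndarray]


def _split_groups(
    X: pd.DataFrame, groups: Sequence, group1=None
) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    if groups.shape != (X.shape[1],):
        raise ValueError("groups must have one label per sample (column)")
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two group labels, got {list(uniq)}")
    if group1 is None:
        group1 = uniq[0]
    elif group1 not in uniq:
        raise ValueError(f"group1 label {group1!r} not present in groups")
    mask1 = groups == group1
    X1 = X.to_numpy(dtype=float)[:, mask1]
    X2 = X.to_numpy(dtype=float)[:, ~mask1]
    if X1.shape[1] == 0 or X2.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    return X1, X2


def log_fold_change(
    X: pd.DataFrame, groups: Sequence, group1=None
) -> pd.Series:
    """Per-gene difference of group means (group1 - group2), log2 units.

    ``groups`` is a binary label vector over samples; ``group1`` names the
    reference group (default: the first sample's label), so e.g.
    ``group1="tumor"`` makes positive values "upregulated in tumor". On a
    log2-scale matrix the difference of means is the log2 fold change.
    Swapping the two roles negates every value.
    """
    X1, X2 = _split_groups(X, groups, group1)
    lfc = X1.mean(axis=1) - X2.mean(axis=1)
    return pd.Series(lfc, index=X.index, name="logFC")


def welch_t_test(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-test per gene; degenerate genes handled by convention.

    A gene constant within both groups gets p = 1 when the group means agree
    (no evidence either way) and p = 0 when they differ (infinite t); both
    cases are logged.
    """
    res = stats.ttest_ind(X1, X2, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        means_equal = np.isclose(X1.mean(axis=1), X2.mean(axis=1))
        p[degenerate & means_equal] = 1.0
        p[degenerate & ~means_equal] = 0.0
        logger.info(
            "welch_t_test: %d degenerate zero-variance genes given conventional p",
            int(degenerate.sum()),
        )
    return p


def per_gene_test(
    X: pd.DataFrame, groups: Sequence, method: PerGeneTest | str = "welch",
    group1=None,
) -> pd.Series:
    """Per-gene two-group p-values with a pluggable test.

    ``method`` is ``"welch"`` (default) or any callable mapping the two
    (genes x samples) group submatrices to a vector of p-values.
    """
    X1, X2 = _split_groups(X, groups, group1)
    if X1.shape[1] < 2 or X2.shape[1] < 2:
        raise ValueError("need >= 2 samples per group for a per-gene test")
    if method == "welch":
        test: PerGeneTest = welch_t_test
    elif callable(method):
        test = method
    else:
        raise ValueError(f"unknown test method {method!r}")
    p = np.asarray(test(X1, X2), dtype=float)
    if p.shape != (X.shape[0],) or np.any((p < 0) | (p > 1)):
        raise ValueError("per-gene test must return one p-value in [0,1] per gene")
    return pd.Series(p, index=X.index, name="p_value")


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_by(scores: pd.Series) -> pd.Series:
    """Ranked gene list: scores sorted decreasing, ties broken by gene id.

    The tie rule (lexicographic gene id) makes the ordering total and
    reproducible.
    """
    if scores.index.has_duplicates:
        dup = scores.index[scores.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate genes in score vector: {dup}")
    values = scores.to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        bad = scores.index[np.isnan(values)].tolist()
        raise ValueError(f"NaN scores for genes: {bad}")
    order = sorted(range(len(scores)), key=lambda i: (-values[i], str(scores.index[i])))
    return scores.iloc[order]


def de_table(
    X: pd.DataFrame,
    groups: Sequence,
    method: PerGeneTest | str = "welch",
    fdr_threshold: float = 0.05,
    group1=None,
) -> pd.DataFrame:
    """Full differential-expression table: logFC, p, FDR, direction, DEG call.

    ``direction`` is "up" when logFC(group1 - group2) > 0, "down" when < 0;
    a gene is called a DEG when its BH-adjusted p-value falls below
    ``fdr_threshold`` (configurable; 0.05 by default).
    """
    lfc = log_fold_change(X, groups, group1)
    p = per_gene_test(X, groups, method=method, group1=group1)
    fdr = benjamini_hochberg(p.to_numpy())
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "-"))
    return pd.DataFrame(
        {
            "logFC": lfc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
            "deg": fdr < fdr_threshold,
        },
        index=X.index,
    )
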