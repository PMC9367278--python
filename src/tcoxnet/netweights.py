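"""Correlation-dissimilarity penalty factors (the TCox weighting scheme).

For each gene j, build its correlation profile sigma_j (the j-th column of
the gene-gene Pearson correlation matrix) in the tumor group and in the
normal group, and measure the angular dissimilarity between the two profiles

    d_j = arccos( <sigma_j^T, sigma_j^N> / (||sigma_j^T|| ||sigma_j^N||) ).

Dissimilarities are normalized by their maximum, w_j = d_j / max_k d_k, and
inverted into per-gene penalty factors q_j = 1 / w_j: genes whose
co-expression pattern changes most between tumor and normal tissue receive
the smallest penalty and are therefore favored by the weighted elastic-net
Cox model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationProfiles",
    "PenaltyWeights",
    "correlation_profiles",
    "angular_dissimilarity",
    "normalize_dissimilarity",
    "penalty_factors",
    "penalty_weights",
    "rescale_factors",
]


@dataclass(frozen=True)
class CorrelationProfiles:
    """Aligned tumor/normal gene-gene Pearson correlation matrices."""

    sigma_tumor: np.ndarray
    sigma_normal: np.ndarray
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        p = len(self.gene_ids)
        for name, m in (("sigma_tumor", self.sigma_tumor), ("sigma_normal", self.sigma_normal)):
            if m.shape != (p, p):
                raise ValueError(f"{name} must be {p}x{p}")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.abs(m) > 1 + 1e-12):
                raise ValueError(f"{name} entries must lie in [-1, 1]")


@dataclass(frozen=True)
class PenaltyWeights:
    """Per-gene dissimilarity d, normalized weight w, penalty factor q."""

    d: np.ndarray
    w: np.ndarray
    q: np.ndarray
    gene_ids: tuple[str, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d": self.d, "w": self.w, "q": self.q},
            index=pd.Index(self.gene_ids, name="gene"),
        )


def _group_correlation(X: pd.DataFrame, label: str) -> np.ndarray:
    values = X.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValueError(f"{label} group needs >= 3 samples for correlations")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = X.index[sd == 0].tolist()
        raise ValueError(f"zero-variance gene(s) in {label} group: {bad}")
    corr = np.corrcoef(values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)  # enforce symmetry/bounds
    np.fill_diagonal(corr, 1.0)
    return corr


def correlation_profiles(
    X_tumor: pd.DataFrame, X_normal: pd.DataFrame
) -> CorrelationProfiles:
    """Pearson correlation matrices for the two tissue groups.

    Both matrices must carry the same genes in the same order; zero-variance
    genes must have been filtered upstream and are rejected by name here.
    """
    if not X_tumor.index.equals(X_normal.index):
        raise ValueError("tumor and normal matrices must share the same gene order")
    sigma_t = _group_correlation(X_tumor, "tumor")
    sigma_n = _group_correlation(X_normal, "normal")
    return CorrelationProfiles(sigma_t, sigma_n, tuple(map(str, X_tumor.index)))


def angular_dissimilarity(
    profiles: CorrelationProfiles, include_diagonal: bool = True
) -> np.ndarray:
    """Per-gene angle (radians, in [0, pi]) between the two correlation profiles.

    ``include_diagonal`` keeps the self-correlation entry (always 1) in each
    profile, the literal reading of "column of the correlation matrix"; it
    also bounds both norms away from zero. Setting it False excludes the
    self-entry from the inner product and norms.
    """
    st, sn = profiles.sigma_tumor, profiles.sigma_normal
    dots = np.einsum("ij,ij->j", st, sn)
    nt = np.einsum("ij,ij->j", st, st)
    nn = np.einsum("ij,ij->j", sn, sn)
    if not include_diagonal:
        dots = dots - 1.0
        nt = nt - 1.0
        nn = nn - 1.0
        if np.any(nt <= 0) or np.any(nn <= 0):
            raise ValueError(
                "a correlation profile vanishes when the diagonal is excluded"
            )
    cosine = dots / np.sqrt(nt * nn)
    return np.arccos(np.clip(cosine, -1.0, 1.0))


def normalize_dissimilarity(d: np.ndarray) -> np.ndarray:
    """Normalize dissimilarities by their maximum so that max(w) = 1."""
    d = np.asarray(d, dtype=float)
    dmax = d.max()
    if dmax <= 0:
        raise ValueError(
            "all dissimilarities are zero (identical correlation structure); "
            "correlation-dissimilarity weights are undefined"
        )
    return d / dmax


def penalty_factors(w: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Inverse normalized dissimilarities q = 1 / max(w, floor).

    The floor keeps q finite where w = 0 (a gene with identical correlation
    profiles in both groups would otherwise receive an infinite penalty).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    w = np.asarray(w, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("normalized weights must lie in [0, 1]")
    return 1.0 / np.maximum(w, floor)


def rescale_factors(q: np.ndarray) -> np.ndarray:
    """Rescale penalty factors to sum to the feature count.

    Mirrors the convention of the reference penalized-regression ecosystem,
    which internally rescales user penalty factors so their sum equals p;
    this keeps the lambda scale comparable between weighted and unweighted
    fits.
    """
    q = np.asarray(q, dtype=float)
    return q * (q.size / q.sum())


def penalty_weights(
    X_tumor: pd.DataFrame,
    X_normal: pd.DataFrame,
    floor: float = 1e-3,
    include_diagonal: bool = True,
) -> PenaltyWeights:
    """End-to-end convenience: correlations -> d -> w -> q for one gene set."""
    profiles = correlation_profiles(X_tumor, X_normal)
    d = angular_dissimilarity(profiles, include_diagonal=include_diagonal)
    w = normalize_dissimilarity(d)
    q = penalty_factors(w, floor=floor)
    return PenaltyWeights(d, w, q, profiles.gene_ids)
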