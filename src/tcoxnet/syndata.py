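"""Synthetic tumor/normal expression cohorts with right-censored survival.

The generator emulates the statistical structure a correlation-guided
penalized Cox analysis assumes in a bulk RNA-seq cancer cohort:

* two tissue groups (tumor, normal) with block-correlated expression on the
  log2(x+1) scale, drawn from a multivariate Gaussian with exact population
  correlation control (one shared factor per block);
* a known subset of genes whose *correlation profile* differs between the
  groups (their block assignment is permuted in the tumor group, keeping
  marginal variances equal so the effect is purely correlational);
* a known subset of mean-shift differentially expressed genes;
* event times for tumor samples drawn from an exponential-baseline Cox model
  ``rate_i = baseline_rate * exp(x_i' beta_true)`` with a sparse known beta,
  under independent exponential censoring whose rate is solved numerically to
  hit a target censoring fraction (default ~67%, typical of a kidney-cancer
  cohort with roughly one third of deaths observed).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .survival import Survival

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_expression",
    "generate_survival",
    "generate_dataset",
]

#: cohort-style default mean log2 abundance and its gene-to-gene spread
_BASELINE_MEAN = 6.0
_BASELINE_SD = 1.0


def _default_de_genes() -> dict[int, float]:
    # strong, DEG-scale log2 shifts in tumor (both directions)
    return {0: 2.0, 1: 2.0, 50: -2.0, 51: -2.0, 100: 1.5, 101: -1.5}


def _default_beta() -> dict[int, float]:
    # sparse 5-gene prognostic signal; gene 0 is also differentially correlated
    return {0: 0.8, 25: -0.8, 50: 0.6, 100: 0.7, 150: -0.6}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for one synthetic cohort.

    The defaults are the desk-scale testing world used throughout the test
    suite: 200 genes, 300 tumor and 300 normal samples, four 25-gene
    correlated blocks (correlation 0.6), ten differentially correlated genes,
    six mean-shift DE genes, a 5-gene sparse survival signal with effect
    sizes |beta| >= 0.5 and ~67% censoring.
    """

    n_genes: int = 200
    n_tumor: int = 300
    n_normal: int = 300
    block_sizes: tuple[int, ...] = (25, 25, 25, 25)
    within_block_correlation: float = 0.6
    diffcorr_genes: frozenset[int] = frozenset(range(10))
    de_genes: Mapping[int, float] = field(default_factory=_default_de_genes)
    beta_true: Mapping[int, float] = field(default_factory=_default_beta)
    baseline_rate: float = 1.0 / 1500.0  # events per day; median survival ~3 years
    target_censoring: float = 0.67
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_tumor <= 0 or self.n_normal <= 0:
            raise ValueError("n_genes, n_tumor and n_normal must be positive")
        if any(b <= 0 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if sum(self.block_sizes) > self.n_genes:
            raise ValueError("block sizes exceed n_genes")
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise ValueError("within_block_correlation must be in [0, 1)")
        genes = range(self.n_genes)
        if not set(self.diffcorr_genes) <= set(genes):
            raise ValueError("diffcorr_genes outside gene index range")
        if not set(self.de_genes) <= set(genes):
            raise ValueError("de_genes outside gene index range")
        if not set(self.beta_true) <= set(genes):
            raise ValueError("beta_true support outside gene index range")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not 0.0 < self.target_censoring < 1.0:
            raise ValueError("target_censoring must be in (0, 1)")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def beta_vector(self) -> np.ndarray:
        beta = np.zeros(self.n_genes)
        for g, b in self.beta_true.items():
            beta[g] = b
        return beta

    def truth(self) -> dict:
        d = asdict(self)
        d["diffcorr_genes"] = sorted(self.diffcorr_genes)
        d["de_genes"] = {str(k): v for k, v in dict(self.de_genes).items()}
        d["beta_true"] = {str(k): v for k, v in dict(self.beta_true).items()}
        d["block_sizes"] = list(self.block_sizes)
        return d


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated cohort: expression, per-sample annotation, survival, truth.

    ``expression`` is genes x samples (log2-like scale); ``annotation`` has one
    row per sample with columns ``tissue`` (tumor/normal) and ``stage``
    (I--IV for tumor samples); ``survival`` covers exactly the tumor samples.
    """

    expression: pd.DataFrame
    annotation: pd.DataFrame
    survival: Survival | None
    truth: dict

    def tumor_samples(self) -> list[str]:
        return self.annotation.index[self.annotation["tissue"] == "tumor"].tolist()

    def normal_samples(self) -> list[str]:
        return self.annotation.index[self.annotation["tissue"] == "normal"].tolist()


def _block_assignment(config: SyntheticConfig) -> np.ndarray:
    """Block id per gene for the normal group; -1 marks independent genes."""
    blocks = np.full(config.n_genes, -1, dtype=int)
    start = 0
    for b, size in enumerate(config.block_sizes):
        blocks[start : start + size] = b
        start += size
    return blocks


def _tumor_blocks(config: SyntheticConfig, normal_blocks: np.ndarray) -> np.ndarray:
    """Permute the block membership of differentially correlated genes."""
    blocks = normal_blocks.copy()
    n_blocks = max(len(config.block_sizes), 1)
    for g in sorted(config.diffcorr_genes):
        if blocks[g] >= 0:
            blocks[g] = (blocks[g] + 1) % n_blocks
        else:
            blocks[g] = 0  # an independent gene joins the first block
    return blocks


def _sample_group(
    rng: np.random.Generator,
    n_samples: int,
    blocks: np.ndarray,
    rho: float,
    means: np.ndarray,
) -> np.ndarray:
    p = blocks.size
    n_blocks = int(blocks.max()) + 1 if blocks.max() >= 0 else 0
    noise = rng.standard_normal((p, n_samples))
    values = np.sqrt(1.0 - rho) * noise
    values[blocks < 0] = noise[blocks < 0]
    if n_blocks > 0 and rho > 0:
        factors = rng.standard_normal((n_blocks, n_samples))
        in_block = blocks >= 0
        values[in_block] += np.sqrt(rho) * factors[blocks[in_block]]
    return means[:, None] + values


def generate_expression(config: SyntheticConfig) -> SyntheticDataset:
    """Generate expression and annotation (no survival) for one cohort.

    Genes within a block share pairwise population correlation
    ``within_block_correlation`` in the normal group; genes in
    ``diffcorr_genes`` are reassigned to a different block in the tumor group
    so that their correlation profiles differ between tissues. ``de_genes``
    receive their stated mean shift in tumor samples. Values are clipped at
    zero so the scale stays log2(x+1)-like.
    """
    rng = np.random.default_rng(config.seed)
    normal_blocks = _block_assignment(config)
    tumor_blocks = _tumor_blocks(config, normal_blocks)
    means = _BASELINE_MEAN + _BASELINE_SD * rng.standard_normal(config.n_genes)
    rho = config.within_block_correlation

    X_normal = _sample_group(rng, config.n_normal, normal_blocks, rho, means)
    X_tumor = _sample_group(rng, config.n_tumor, tumor_blocks, rho, means)
    for g, shift in config.de_genes.items():
        X_tumor[g] += shift
    X_normal = np.maximum(X_normal, 0.0)
    X_tumor = np.maximum(X_tumor, 0.0)

    gene_ids = config.gene_ids()
    wt = len(str(config.n_tumor))
    wn = len(str(config.n_normal))
    tumor_ids = [f"T{i + 1:0{wt}d}" for i in range(config.n_tumor)]
    normal_ids = [f"N{i + 1:0{wn}d}" for i in range(config.n_normal)]
    expression = pd.DataFrame(
        np.hstack([X_tumor, X_normal]),
        index=pd.Index(gene_ids, name="gene"),
        columns=tumor_ids + normal_ids,
    )

    stages = _assign_stages(X_tumor, config, rng)
    annotation = pd.DataFrame(
        {
            "tissue": ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
            "stage": list(stages) + [""] * config.n_normal,
        },
        index=pd.Index(tumor_ids + normal_ids, name="sample"),
    )
    return SyntheticDataset(expression, annotation, None, config.truth())


def _assign_stages(
    X_tumor: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Stage I--IV by quartile of the true linear predictor.

    A convenience so that early-vs-advanced differential expression is
    non-null, not a biological claim. With no survival signal the linear
    predictor is flat and stages are assigned uniformly at random.
    """
    beta = config.beta_vector()
    lp = ((X_tumor - X_tumor.mean(axis=1, keepdims=True)) * beta[:, None]).sum(axis=0)
    labels = np.array(["I", "II", "III", "IV"])
    if np.ptp(lp) == 0:
        return labels[rng.integers(0, 4, size=lp.size)]
    ranks = np.argsort(np.argsort(lp, kind="stable"), kind="stable")
    quartile = (ranks * 4) // lp.size
    return labels[quartile]


def censoring_rate_for_target(
    rates: np.ndarray, target_censoring: float
) -> float:
    """Exponential censoring rate c with mean_i c/(c + rate_i) = target.

    Under independent exponential event (rate r_i) and censoring (rate c)
    times, P(censored | r_i) = c / (c + r_i); the expected cohort fraction is
    its average, monotone in c, so the equation has a unique root solved by
    Brent's method in log space.
    """
    rates = np.asarray(rates, dtype=float)

    def frac(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(c / (c + rates))) - target_censoring

    lo = np.log(rates.min()) - 25.0
    hi = np.log(rates.max()) + 25.0
    return float(np.exp(brentq(frac, lo, hi, xtol=1e-12)))


def generate_survival(
    expression: pd.DataFrame | np.ndarray,
    beta_true: Mapping[int, float] | np.ndarray,
    baseline_rate: float,
    target_censoring: float,
    seed: int,
) -> Survival:
    """Draw right-censored survival for the given (tumor) samples.

    Event times are exponential with per-sample rate
    ``baseline_rate * exp(x_i' beta)`` where x is the gene-centered
    expression (centering is absorbed by the baseline hazard and keeps the
    rate scale interpretable). Censoring times are exponential with the rate
    solved by :func:`censoring_rate_for_target`; the recorded time is the
    minimum and ``event = 1`` iff the event time is not after the censoring
    time.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if not 0.0 < target_censoring < 1.0:
        raise ValueError("target_censoring must be in (0, 1)")
    if isinstance(expression, pd.DataFrame):
        values = expression.to_numpy(dtype=float)
        sample_ids: tuple[str, ...] | None = tuple(map(str, expression.columns))
    else:
        values = np.asarray(expression, dtype=float)
        sample_ids = None
    if values.ndim != 2 or values.shape[1] < 1:
        raise ValueError("expression must be a genes x samples matrix with >= 1 sample")

    p, n = values.shape
    if isinstance(beta_true, Mapping):
        beta = np.zeros(p)
        for g, b in beta_true.items():
            g = int(g)
            if not 0 <= g < p:
                raise ValueError(f"beta_true index {g} outside gene range")
            beta[g] = b
    else:
        beta = np.asarray(beta_true, dtype=float)
        if beta.shape != (p,):
            raise ValueError("beta_true length does not match gene count")

    centered = values - values.mean(axis=1, keepdims=True)
    lp = centered.T @ beta
    rates = baseline_rate * np.exp(lp)

    rng = np.random.default_rng(seed)
    event_times = rng.exponential(1.0 / rates)
    c_rate = censoring_rate_for_target(rates, target_censoring)
    censor_times = rng.exponential(1.0 / c_rate, size=n)

    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    time = np.maximum(time, 1e-9)  # guard strictly positive times
    return Survival(time, event, sample_ids)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full cohort: expression, annotation and survival for tumor samples."""
    ds = generate_expression(config)
    tumor = ds.tumor_samples()
    survival = generate_survival(
        ds.expression[tumor],
        dict(config.beta_true),
        config.baseline_rate,
        config.target_censoring,
        seed=config.seed + 1,
    )
    return SyntheticDataset(ds.expression, ds.annotation, survival, ds.truth)
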