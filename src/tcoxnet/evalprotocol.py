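"""Repeated-run evaluation protocol with stability selection.

One run of the protocol, given an expression matrix (genes x samples), the
survival response and a penalty configuration:

1. split samples 70/30, stratified on event status so the training set keeps
   the cohort's censoring proportion (~67% in a typical kidney-cancer
   cohort);
2. choose lambda on the training subset by 10-fold cross-validation;
3. re-fit the penalized Cox model on the *whole* dataset at that lambda
   (deliberately literal: the resulting log-rank p-values are optimistically
   biased because the evaluation data participated in the fit - the protocol
   reproduces the published procedure rather than a held-out evaluation);
4. split all samples at the median fitted relative risk into high/low risk
   groups and record the log-rank p-value together with the selected
   (nonzero-coefficient) gene set.

Repeating the run with different seeds gives per-gene selection frequencies;
stability selection keeps the genes selected in at least a threshold
fraction (default 50%) of runs. Kaplan-Meier estimation and the log-rank
test are delegated to lifelines behind this module's interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from . import coxnet
from .survival import Survival

__all__ = [
    "KMEstimate",
    "LogrankResult",
    "RunRecord",
    "StabilitySummary",
    "stratified_split",
    "median_risk_groups",
    "kaplan_meier",
    "logrank_test",
    "run_protocol",
    "stability_selection",
    "summarize_runs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray       # distinct event times (at least one death each)
    at_risk: np.ndarray     # n_i at each event time
    events: np.ndarray      # d_i at each event time
    survival: np.ndarray    # S(t_i) after the step at t_i

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(t) = 1 before the first event."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int = 1


@dataclass
class RunRecord:
    """Outcome of one protocol run."""

    run: int
    seed: int
    lam: float
    selected_genes: list[str]
    p_value: float | None      # None marks a degenerate (all-zero) fit
    n_selected: int
    degenerate: bool


@dataclass
class StabilitySummary:
    """Per-gene selection frequencies over the repeated runs."""

    frequency: pd.Series
    selected: list[str]
    always_selected: list[str]
    threshold: float
    n_runs: int


def stratified_split(y: Survival, frac: float = 0.7, seed: int = 0) -> np.ndarray:
    """Training indices from a censoring-stratified random split.

    Censored and uncensored samples are split separately at ``frac`` (sizes
    rounded to the nearest integer), so the training and test censoring
    proportions match the full data up to one sample per stratum.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    for value in (0, 1):
        idx = np.flatnonzero(y.event == value)
        if idx.size == 0:
            raise ValueError(f"empty stratum: no samples with event={value}")
        rng.shuffle(idx)
        n_train = int(round(frac * idx.size))
        train.append(idx[:n_train])
    return np.sort(np.concatenate(train))


def median_risk_groups(risks: np.ndarray) -> np.ndarray:
    """High/low risk labels by the median fitted relative risk.

    Returns 1 for high risk (risk > median) and 0 for low (risk <= median):
    ties at the median go to the low-risk group, so with all-distinct risks
    and even n the groups have equal size and with odd n the low-risk group
    gets the extra sample.
    """
    risks = np.asarray(risks, dtype=float)
    if risks.size < 2:
        raise ValueError("need at least two samples to split")
    if np.ptp(risks) == 0:
        raise ValueError(
            "all relative risks identical (degenerate fit, beta = 0); "
            "median split undefined"
        )
    return (risks > np.median(risks)).astype(int)


def kaplan_meier(y: Survival) -> KMEstimate:
    """Kaplan-Meier product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Censored-only times reduce the at-risk count without producing a step.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(y.time, y.event)
    table = kmf.event_table
    mask = table["observed"] > 0
    times = table.index.to_numpy(dtype=float)[mask]
    at_risk = table["at_risk"].to_numpy(dtype=float)[mask]
    events = table["observed"].to_numpy(dtype=float)[mask]
    surv = kmf.survival_function_["KM_estimate"].reindex(times).to_numpy(dtype=float)
    return KMEstimate(times, at_risk, events, surv)


def logrank_test(y: Survival, groups: np.ndarray) -> LogrankResult:
    """Two-group log-rank test (chi-square with 1 df).

    The statistic accumulates observed-minus-expected events over the
    distinct event times with hypergeometric variance; it is symmetric in
    the group labels.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError("exactly two non-empty groups are required")
    if y.n_events == 0:
        raise ValueError("no observed events; log-rank test undefined")
    m0 = groups == uniq[0]
    res = _ll_logrank(
        y.time[m0], y.time[~m0], event_observed_A=y.event[m0], event_observed_B=y.event[~m0]
    )
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def run_protocol(
    X: pd.DataFrame,
    y: Survival,
    alpha: float,
    q: np.ndarray | None = None,
    n_runs: int = 100,
    base_seed: int = 0,
    *,
    frac: float = 0.7,
    k: int = 10,
    n_lambda: int = 40,
    ratio: float = 0.05,
    rule: str = "min",
    cv_tol: float = 1e-4,
    fit_tol: float = 1e-7,
) -> list[RunRecord]:
    """Repeat the tune-on-70%/fit-on-all evaluation ``n_runs`` times.

    ``X`` is genes x samples; ``q`` optional per-gene penalty factors (the
    correlation-dissimilarity weighting). Run r uses seed ``base_seed + r``
    for both the split and the CV fold shuffle. Degenerate runs (no gene
    selected at the chosen lambda) record a missing p-value rather than a
    fabricated one.

    The CV path descends to 5% of lambda_max over 40 grid points with a
    1e-4 coefficient tolerance: lambda selection only needs the deviance
    curve around its minimum, so the expensive near-unpenalized tail of the
    path is skipped; the final full-data fit uses the tight ``fit_tol``.
    """
    genes = tuple(map(str, X.index))
    Xmat = X.to_numpy(dtype=float).T  # samples x genes for the solver
    records: list[RunRecord] = []
    for r in range(n_runs):
        seed = base_seed + r
        train_idx = stratified_split(y, frac=frac, seed=seed)
        cv = coxnet.cv_lambda(
            Xmat[train_idx],
            y.subset(train_idx),
            alpha,
            q,
            k=k,
            seed=seed,
            n_lambda=n_lambda,
            ratio=ratio,
            rule=rule,
            tol=cv_tol,
        )
        f = coxnet.fit(
            Xmat, y, cv.lambda_selected, alpha, q, tol=fit_tol, gene_ids=genes
        )
        selected = f.selected_genes()
        if not selected:
            logger.info("run %d: degenerate all-zero fit at lambda=%g", r, f.lam)
            records.append(
                RunRecord(r, seed, f.lam, [], None, 0, degenerate=True)
            )
            continue
        risks = coxnet.relative_risk(f, Xmat)
        labels = median_risk_groups(risks)
        lr = logrank_test(y, labels)
        records.append(
            RunRecord(r, seed, f.lam, selected, lr.p_value, len(selected), False)
        )
    return records


def stability_selection(
    records: list[RunRecord],
    threshold: float = 0.5,
    all_genes: list[str] | None = None,
) -> StabilitySummary:
    """Per-gene selection frequency and the stable gene set.

    A gene is stable when it appears in at least ``threshold`` of the runs
    (inclusive, matching an "at least 50%" rule); genes at frequency 1.0 are
    additionally flagged as always selected.
    """
    if not records:
        raise ValueError("need at least one run record")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    counts: dict[str, int] = {}
    for rec in records:
        for g in rec.selected_genes:
            counts[g] = counts.get(g, 0) + 1
    n_runs = len(records)
    index = list(all_genes) if all_genes is not None else sorted(counts)
    freq = pd.Series(
        [counts.get(g, 0) / n_runs for g in index],
        index=pd.Index(index, name="gene"),
        name="frequency",
    ).sort_values(ascending=False, kind="stable")
    selected = freq.index[freq >= threshold].tolist()
    always = freq.index[freq == 1.0].tolist()
    return StabilitySummary(freq, selected, always, threshold, n_runs)


def summarize_runs(records: list[RunRecord]) -> dict:
    """Arithmetic mean p-value and gene count over non-degenerate runs.

    Degenerate (all-zero) runs are excluded from the means but counted.
    Underflowed p-values (exactly 0.0 in floating point) are flagged rather
    than silently averaged as zero evidence.
    """
    if not records:
        raise ValueError("need at least one run record")
    good = [r for r in records if not r.degenerate]
    n_degenerate = len(records) - len(good)
    if not good:
        raise ValueError("all runs were degenerate; nothing to summarize")
    pvals = np.array([r.p_value for r in good], dtype=float)
    return {
        "n_runs": len(records),
        "n_degenerate": n_degenerate,
        "mean_p_value": float(pvals.mean()),
        "mean_n_genes": float(np.mean([r.n_selected for r in good])),
        "p_underflow": bool(np.any(pvals == 0.0)),
    }
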