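"""Tab-separated interchange formats for expression and clinical tables.

Expression TSV: first column ``gene`` (unique ids), remaining columns one per
sample, '.' decimal, UTF-8. Clinical TSV: columns ``sample``, ``tissue``
(tumor/normal), ``stage`` (I-IV, tumor samples), and either a single ``time``
column with ``event`` (0/1) or the pair ``days_to_death`` /
``days_to_last_followup`` from which the follow-up time is derived
(days_to_death when the event was observed, otherwise days to last
follow-up). Gene identifiers are opaque strings; no symbol mapping is
attempted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import validate_expression
from .survival import Survival

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "survival_from_clinical",
    "stage_group",
]

_STAGES = ("I", "II", "III", "IV")


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV, validating shape and values."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene id(s): {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample id(s): {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[gi, si]!r} at gene "
            f"{df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}"
        )
    out = numeric.astype(float)
    out.index.name = "gene"
    return validate_expression(out)


def write_expression_tsv(X: pd.DataFrame, path) -> None:
    validate_expression(X)
    X.to_csv(path, sep="\t", index_label="gene")


def _parse_stage(value, sample: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    s = str(value).strip().upper().removeprefix("STAGE").strip()
    if s == "":
        return ""
    if s not in _STAGES:
        raise ValueError(f"unknown stage code {value!r} for sample {sample!r}")
    return s


def stage_group(stage: str) -> str:
    """Early (I-III) vs advanced (IV) disease grouping."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return "advanced" if stage == "IV" else "early"


def read_clinical_tsv(path) -> pd.DataFrame:
    """Read and validate a per-sample clinical table.

    Returns a DataFrame indexed by sample with columns ``tissue``, ``stage``
    (may be empty for normal tissue), ``time`` and ``event`` (NaN for
    samples without follow-up, e.g. normal tissue).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "tissue"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing required column(s) {required - set(df.columns)}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicate sample id(s): {dup}")
    df = df.set_index("sample")

    tissue = df["tissue"].astype(str).str.strip().str.lower()
    bad_tissue = ~tissue.isin(["tumor", "normal"])
    if bad_tissue.any():
        raise ValueError(
            f"{path}: unknown tissue label(s) "
            f"{df.loc[bad_tissue, 'tissue'].unique().tolist()}"
        )

    if "stage" in df.columns:
        stage = pd.Series(
            [_parse_stage(v, s) for s, v in df["stage"].items()], index=df.index
        )
    else:
        stage = pd.Series("", index=df.index)

    if "time" in df.columns:
        time = pd.to_numeric(df["time"], errors="raise")
        if "event" not in df.columns:
            raise ValueError(f"{path}: 'time' column requires an 'event' column")
        event = pd.to_numeric(df["event"], errors="raise")
    elif {"days_to_death", "days_to_last_followup", "event"} <= set(df.columns):
        event = pd.to_numeric(df["event"], errors="raise")
        dtd = pd.to_numeric(df["days_to_death"], errors="coerce")
        dtf = pd.to_numeric(df["days_to_last_followup"], errors="coerce")
        # observed deaths use days_to_death; censored samples the last follow-up
        time = dtd.where(event == 1, dtf)
    else:
        raise ValueError(
            f"{path}: need either a 'time'+'event' pair or "
            "'days_to_death'/'days_to_last_followup'+'event' columns"
        )

    has_followup = time.notna() | event.notna()
    bad_event = has_followup & ~event.isin([0, 1])
    if bad_event.any():
        raise ValueError(
            f"{path}: event must be 0 or 1; offending sample(s) "
            f"{df.index[bad_event].tolist()}"
        )
    bad_time = has_followup & (time.isna() | (time <= 0))
    if bad_time.any():
        raise ValueError(
            f"{path}: non-positive or missing follow-up time for sample(s) "
            f"{df.index[bad_time].tolist()}"
        )

    return pd.DataFrame(
        {"tissue": tissue, "stage": stage, "time": time, "event": event},
        index=df.index,
    )


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample")


def survival_from_clinical(
    clinical: pd.DataFrame, samples=None
) -> Survival:
    """Extract the survival response for the given samples (default: tumor).

    Samples must appear in the clinical table and carry valid follow-up.
    """
    if samples is None:
        sub = clinical[clinical["tissue"] == "tumor"]
    else:
        missing = [s for s in samples if s not in clinical.index]
        if missing:
            raise ValueError(f"sample(s) absent from clinical table: {missing}")
        sub = clinical.loc[list(samples)]
    if sub["time"].isna().any() or sub["event"].isna().any():
        bad = sub.index[sub["time"].isna() | sub["event"].isna()].tolist()
        raise ValueError(f"sample(s) without follow-up data: {bad}")
    return Survival(
        sub["time"].to_numpy(dtype=float),
        sub["event"].to_numpy(dtype=int),
        tuple(map(str, sub.index)),
    )
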