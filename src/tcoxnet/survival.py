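"""Right-censored survival response container.

A sample's follow-up is a pair (time, event): ``event = 1`` when death was
observed at ``time`` (days), ``event = 0`` when the sample was censored, i.e.
still alive at its last follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Survival"]


@dataclass(frozen=True)
class Survival:
    """Follow-up times and event indicators for a set of samples.

    Parameters
    ----------
    time:
        Positive follow-up time per sample, in days.
    event:
        Event indicator per sample: 1 = death observed, 0 = censored.
    sample_ids:
        Optional sample identifiers aligned with ``time``/``event``.
    """

    time: np.ndarray
    event: np.ndarray
    sample_ids: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.ndim != 1 or event.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if time.size == 0:
            raise ValueError("empty survival response")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("follow-up times must be finite and > 0")
        uniq = np.unique(event)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int64))
        if self.sample_ids is not None:
            ids = tuple(str(s) for s in self.sample_ids)
            if len(ids) != time.size:
                raise ValueError("sample_ids length does not match time/event")
            object.__setattr__(self, "sample_ids", ids)

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def censored_fraction(self) -> float:
        """Fraction of samples whose event was not observed (delta = 0)."""
        return float(np.mean(self.event == 0))

    def subset(self, idx) -> "Survival":
        idx = np.asarray(idx)
        ids = None
        if self.sample_ids is not None:
            ids = tuple(np.asarray(self.sample_ids, dtype=object)[idx])
        return Survival(self.time[idx], self.event[idx], ids)
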