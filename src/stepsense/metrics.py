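"""Epoch aggregation, cadence/MVPA classification, and daily summaries.

Epochs are half-open ``[t, t + epoch_length_s)`` anchored at the span start
(the pipeline anchors day spans at midnight of the recording's start date).
Cadence is derived per epoch as ``steps * 60 / epoch_length_s`` and an epoch
is MVPA iff its cadence reaches the threshold (default 100 steps/min) — the
classification is instantaneous, no bout detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from ._util import DataError
from .step_core import StepEvents

__all__ = [
    "EpochSeries",
    "DailySummary",
    "PairedDaily",
    "aggregate_epochs",
    "classify_mvpa",
    "summarize_day",
    "pair_days",
    "day_span",
]

MVPA_CADENCE_SPM = 100.0


@dataclass
class EpochSeries:
    """Per-epoch step counts with derived cadence and MVPA flags."""

    epoch_start: pd.DatetimeIndex
    epoch_length_s: float
    steps: np.ndarray  # non-negative integers
    cadence_spm: np.ndarray
    is_mvpa: np.ndarray

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.cadence_spm = np.asarray(self.cadence_spm, dtype=float)
        self.is_mvpa = np.asarray(self.is_mvpa, dtype=bool)
        n = len(self.epoch_start)
        if not (len(self.steps) == len(self.cadence_spm) == len(self.is_mvpa) == n):
            raise DataError("epoch series columns must have equal length")
        if (self.steps < 0).any():
            raise DataError("step counts must be non-negative")

    def __len__(self) -> int:
        return len(self.epoch_start)

    @property
    def total_steps(self) -> int:
        return int(self.steps.sum())

    @property
    def mvpa_steps(self) -> int:
        return int(self.steps[self.is_mvpa].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_start": self.epoch_start,
                "steps": self.steps,
                "cadence_spm": np.round(self.cadence_spm, 2),
                "is_mvpa": self.is_mvpa,
            }
        )


@dataclass
class DailySummary:
    """Per-calendar-day totals for one device."""

    date: date
    total_steps: int
    mvpa_steps: int
    wear_complete: bool = True  # externally supplied 24 h wear flag
    qc_pass: bool = True  # externally supplied calibration QC flag

    def __post_init__(self) -> None:
        if self.mvpa_steps > self.total_steps:
            raise DataError("mvpa_steps cannot exceed total_steps")

    @property
    def valid(self) -> bool:
        return self.wear_complete and self.qc_pass


@dataclass
class PairedDaily:
    """One day valid on both devices: wrist vs reference totals."""

    date: date
    wrist_total: int
    reference_total: int
    wrist_mvpa: int
    reference_mvpa: int


def day_span(day: date) -> tuple[datetime, datetime]:
    """Midnight-to-midnight span for a calendar day."""
    start = datetime(day.year, day.month, day.day)
    return start, start + timedelta(days=1)


def aggregate_epochs(
    events: StepEvents,
    epoch_length_s: float = 5.0,
    span: tuple[datetime, datetime] | None = None,
    mvpa_cadence_spm: float = MVPA_CADENCE_SPM,
) -> EpochSeries:
    """Bin step events into half-open epochs ``[t, t + epoch_length_s)``.

    ``span`` defaults to midnight of the first event's date through the end
    of the epoch containing the last event.  Every event must fall inside the
    span; the sum of epoch steps always equals the event count.
    """
    if not epoch_length_s > 0:
        raise DataError("epoch_length_s must be positive")
    if span is None:
        if len(events) == 0:
            raise DataError("span is required when there are no events")
        first = events.times[0]
        start = first.normalize()
        end = events.times[-1] + pd.Timedelta(seconds=epoch_length_s)
    else:
        start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    if len(events):
        if events.times[0] < start or events.times[-1] >= end:
            raise DataError("step events fall outside the aggregation span")
    total_s = (end - start).total_seconds()
    n_epochs = int(np.ceil(total_s / epoch_length_s - 1e-9))
    if n_epochs <= 0:
        raise DataError("span shorter than one epoch")
    counts = np.zeros(n_epochs, dtype=np.int64)
    if len(events):
        offsets = (events.times - start).total_seconds()
        bins = np.floor(np.asarray(offsets) / epoch_length_s).astype(np.int64)
        np.add.at(counts, bins, 1)
    starts = start + pd.to_timedelta(np.arange(n_epochs) * epoch_length_s, unit="s")
    cadence = counts * (60.0 / epoch_length_s)
    return EpochSeries(
        epoch_start=pd.DatetimeIndex(starts),
        epoch_length_s=float(epoch_length_s),
        steps=counts,
        cadence_spm=cadence,
        is_mvpa=cadence >= mvpa_cadence_spm,
    )


def classify_mvpa(series: EpochSeries, mvpa_cadence_spm: float = MVPA_CADENCE_SPM) -> EpochSeries:
    """Re-flag epochs whose cadence reaches the threshold (>=)."""
    if not mvpa_cadence_spm > 0:
        raise DataError("mvpa_cadence_spm must be positive")
    return EpochSeries(
        epoch_start=series.epoch_start,
        epoch_length_s=series.epoch_length_s,
        steps=series.steps,
        cadence_spm=series.cadence_spm,
        is_mvpa=series.cadence_spm >= mvpa_cadence_spm,
    )


def summarize_day(
    series: EpochSeries, wear_complete: bool = True, qc_pass: bool = True
) -> DailySummary:
    """Collapse one calendar day of epochs to daily totals."""
    if len(series) == 0:
        raise DataError("cannot summarize an empty epoch series")
    dates = series.epoch_start.normalize().unique()
    if len(dates) != 1:
        raise DataError("epoch series spans more than one calendar day")
    return DailySummary(
        date=dates[0].date(),
        total_steps=series.total_steps,
        mvpa_steps=series.mvpa_steps,
        wear_complete=wear_complete,
        qc_pass=qc_pass,
    )


def pair_days(
    wrist: list[DailySummary], reference: list[DailySummary]
) -> list[PairedDaily]:
    """Inner join on date, keeping only days valid on both devices."""

    def by_date(summaries: list[DailySummary], label: str) -> dict[date, DailySummary]:
        out: dict[date, DailySummary] = {}
        for s in summaries:
            if s.date in out:
                raise DataError(f"duplicate {label} summary for {s.date}")
            out[s.date] = s
        return out

    w = by_date(wrist, "wrist")
    r = by_date(reference, "reference")
    pairs = []
    for day in sorted(set(w) & set(r)):
        if w[day].valid and r[day].valid:
            pairs.append(
                PairedDaily(
                    date=day,
                    wrist_total=w[day].total_steps,
                    reference_total=r[day].total_steps,
                    wrist_mvpa=w[day].mvpa_steps,
                    reference_mvpa=r[day].mvpa_steps,
                )
            )
    return pairs
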