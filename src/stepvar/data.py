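"""Core containers: per-day activity records and per-subject metric series.

The canonical in-memory representation of a cohort's tracker data is a long
pandas DataFrame with one row per subject-day (columns listed in
:data:`CANONICAL_COLUMNS`).  :class:`DailyActivityRecord` is the typed
row-level view used by the reader/writer and the simulator;
:class:`ActivitySeries` is the ordered (date, value) view of one
subject × metric that the variability layer consumes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Tracker channels in the canonical long format, in column order.
ACTIVITY_METRICS = (
    "steps",
    "distance_km",
    "minutes_sedentary",
    "minutes_lightly_active",
    "minutes_fairly_active",
    "minutes_very_active",
)

#: The four intensity-minute channels; their daily sum cannot exceed 1440.
MINUTE_METRICS = (
    "minutes_sedentary",
    "minutes_lightly_active",
    "minutes_fairly_active",
    "minutes_very_active",
)

CANONICAL_COLUMNS = ("subject_id", "date") + ACTIVITY_METRICS

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class DailyActivityRecord:
    """One subject-day of activity-tracker metrics.

    Counts are non-negative integers; the four minute categories sum to at
    most 1440 (one day); distance is kilometres.
    """

    subject_id: str
    date: dt.date
    steps: int
    distance_km: float
    minutes_sedentary: int
    minutes_lightly_active: int
    minutes_fairly_active: int
    minutes_very_active: int

    def minute_total(self) -> int:
        return (
            self.minutes_sedentary
            + self.minutes_lightly_active
            + self.minutes_fairly_active
            + self.minutes_very_active
        )

    def check(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        for name in ("steps", *MINUTE_METRICS):
            if getattr(self, name) < 0:
                problems.append(f"{name} < 0")
        if self.distance_km < 0:
            problems.append("distance_km < 0")
        if self.minute_total() > MINUTES_PER_DAY:
            problems.append(f"minute categories sum to {self.minute_total()} > {MINUTES_PER_DAY}")
        return problems


@dataclass(frozen=True)
class ActivitySeries:
    """Ordered (date, value) series for one subject and one metric.

    ``dates`` is a ``datetime64[D]`` array with strictly increasing entries;
    ``values`` is a float array of the same length with finite entries.
    """

    subject_id: str
    metric: str
    dates: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        dates = np.asarray(self.dates, dtype="datetime64[D]")
        values = np.asarray(self.values, dtype=float)
        if dates.shape != values.shape or dates.ndim != 1:
            raise ValidationError("dates and values must be 1-D arrays of equal length")
        if len(dates) > 1 and not np.all(np.diff(dates).astype(int) > 0):
            raise ValidationError("dates must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValidationError("values must be finite")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def records_to_frame(records: Iterable[DailyActivityRecord]) -> pd.DataFrame:
    """Convert records to the canonical long DataFrame, sorted by subject and date."""
    rows = [
        (
            r.subject_id,
            r.date,
            r.steps,
            r.distance_km,
            r.minutes_sedentary,
            r.minutes_lightly_active,
            r.minutes_fairly_active,
            r.minutes_very_active,
        )
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    return frame.sort_values(["subject_id", "date"], kind="stable").reset_index(drop=True)


def frame_to_records(frame: pd.DataFrame) -> list[DailyActivityRecord]:
    """Convert a canonical long DataFrame to typed records."""
    records = []
    for row in frame.itertuples(index=False):
        date = row.date
        if isinstance(date, pd.Timestamp):
            date = date.date()
        records.append(
            DailyActivityRecord(
                subject_id=str(row.subject_id),
                date=date,
                steps=int(row.steps),
                distance_km=float(row.distance_km),
                minutes_sedentary=int(row.minutes_sedentary),
                minutes_lightly_active=int(row.minutes_lightly_active),
                minutes_fairly_active=int(row.minutes_fairly_active),
                minutes_very_active=int(row.minutes_very_active),
            )
        )
    return records


def series_from_records(
    records: Sequence[DailyActivityRecord], metric: str
) -> ActivitySeries:
    """Extract one metric as an ActivitySeries from a single subject's records."""
    if metric not in ACTIVITY_METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    subjects = {r.subject_id for r in records}
    if len(subjects) != 1:
        raise ValidationError(f"records must belong to one subject, got {sorted(subjects)}")
    ordered = sorted(records, key=lambda r: r.date)
    dates = np.array([r.date for r in ordered], dtype="datetime64[D]")
    values = np.array([getattr(r, metric) for r in ordered], dtype=float)
    return ActivitySeries(subjects.pop(), metric, dates, values)


def series_from_frame(frame: pd.DataFrame, metric: str | None = None):
    """Yield ActivitySeries for each subject (× metric) in a canonical frame.

    With ``metric`` given, yields one series per subject for that metric;
    otherwise yields all subject × metric combinations.
    """
    metrics = [metric] if metric is not None else list(ACTIVITY_METRICS)
    for subject_id, group in frame.groupby("subject_id", sort=True):
        group = group.sort_values("date")
        dates = np.array(
            [d.date() if isinstance(d, pd.Timestamp) else d for d in group["date"]],
            dtype="datetime64[D]",
        )
        for m in metrics:
            yield ActivitySeries(
                str(subject_id), m, dates, group[m].to_numpy(dtype=float)
            )
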