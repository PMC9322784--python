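"""Reading, writing and validating daily activity exports.

Two CSV dialects are supported:

``canonical_long``
    One row per subject-day with explicit column names
    (subject_id, date, steps, distance_km, minutes_sedentary,
    minutes_lightly_active, minutes_fairly_active, minutes_very_active).
    This is the package's interchange format; :func:`write_canonical`
    produces it and round-trips exactly.

``fitbit_activities``
    The account-export style: a section headed ``Activities`` followed by a
    header row (Date, Steps, Distance, Minutes Sedentary, Minutes Lightly
    Active, Minutes Fairly Active, Minutes Very Active, ...), one file per
    subject, numbers possibly quoted with thousands separators ("9,908"),
    dates ISO by default with an MM/DD/YY fallback.  The exact layout of
    these exports varies by export vintage, so this dialect is isolated
    behind the dialect switch and kept forgiving.
"""

from __future__ import annotations

import csv
import datetime as dt
import io as _io
from dataclasses import dataclass, field

import pandas as pd

from .data import (
    ACTIVITY_METRICS,
    CANONICAL_COLUMNS,
    DailyActivityRecord,
)
from .exceptions import FormatError, RowParseError, ValidationError

MILES_TO_KM = 1.609344

_FITBIT_COLUMN_MAP = {
    "Date": "date",
    "Steps": "steps",
    "Distance": "distance_km",
    "Minutes Sedentary": "minutes_sedentary",
    "Minutes Lightly Active": "minutes_lightly_active",
    "Minutes Fairly Active": "minutes_fairly_active",
    "Minutes Very Active": "minutes_very_active",
}


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_records` — counts and human-readable notes."""

    n_records: int = 0
    n_duplicate_dates: int = 0
    n_out_of_range: int = 0
    date_gaps: list = field(default_factory=list)  # (first missing date, length in days)
    messages: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            self.n_duplicate_dates == 0
            and self.n_out_of_range == 0
            and not self.date_gaps
        )


def _parse_number(text: str, line_number: int, column: str) -> float:
    cleaned = text.strip().replace(",", "")
    if cleaned == "":
        raise RowParseError(f"empty value in column {column!r}", line_number)
    try:
        return float(cleaned)
    except ValueError:
        raise RowParseError(
            f"cannot parse {text!r} in column {column!r} as a number", line_number
        ) from None


def _parse_date(text: str, line_number: int, date_format: str | None) -> dt.date:
    text = text.strip()
    formats = [date_format] if date_format else ["%Y-%m-%d", "%m/%d/%y"]
    for fmt in formats:
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise RowParseError(f"cannot parse date {text!r}", line_number)


def _build_record(subject_id, date, values) -> DailyActivityRecord:
    return DailyActivityRecord(
        subject_id=subject_id,
        date=date,
        steps=int(values["steps"]),
        distance_km=float(values["distance_km"]),
        minutes_sedentary=int(values["minutes_sedentary"]),
        minutes_lightly_active=int(values["minutes_lightly_active"]),
        minutes_fairly_active=int(values["minutes_fairly_active"]),
        minutes_very_active=int(values["minutes_very_active"]),
    )


def _parse_canonical(lines: list[str], date_format: str | None) -> list[DailyActivityRecord]:
    reader = csv.reader(lines)
    try:
        header = next(reader)
    except StopIteration:
        return []
    header = [h.strip() for h in header]
    for required in CANONICAL_COLUMNS:
        if required not in header:
            raise FormatError(f"missing required column {required!r}")
    idx = {name: header.index(name) for name in CANONICAL_COLUMNS}
    records = []
    for line_no, row in enumerate(reader, start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        date = _parse_date(row[idx["date"]], line_no, date_format)
        values = {
            m: _parse_number(row[idx[m]], line_no, m) for m in ACTIVITY_METRICS
        }
        records.append(_build_record(row[idx["subject_id"]].strip(), date, values))
    return records


def _parse_fitbit(
    lines: list[str],
    subject_id: str,
    date_format: str | None,
    distance_unit: str,
) -> list[DailyActivityRecord]:
    # locate the Activities section
    start = None
    for i, line in enumerate(lines):
        if line.strip().strip('"').rstrip(",") == "Activities":
            start = i + 1
            break
    if start is None:
        raise FormatError('no "Activities" section found in Fitbit export')
    if start >= len(lines):
        return []
    header = [h.strip() for h in next(csv.reader([lines[start]]))]
    col_idx = {}
    for export_name, canonical in _FITBIT_COLUMN_MAP.items():
        if export_name not in header:
            raise FormatError(f"missing required column {export_name!r}")
        col_idx[canonical] = header.index(export_name)

    records = []
    for offset, line in enumerate(lines[start + 1 :]):
        line_no = start + 2 + offset  # 1-based line number in the stream
        if not line.strip():
            break  # blank line ends the section
        row = next(csv.reader([line]))
        if len(row) == 1:  # a new section header ends the section too
            break
        date = _parse_date(row[col_idx["date"]], line_no, date_format)
        values = {
            m: _parse_number(row[col_idx[m]], line_no, m)
            for m in ACTIVITY_METRICS
        }
        if distance_unit == "miles":
            values["distance_km"] *= MILES_TO_KM
        records.append(_build_record(subject_id, date, values))
    return records


def parse_fitbit_export(
    stream,
    dialect: str = "canonical_long",
    subject_id: str | None = None,
    date_format: str | None = None,
    distance_unit: str = "km",
) -> list[DailyActivityRecord]:
    """Parse daily activity records from a text stream or string.

    Parameters
    ----------
    stream
        A string or a text file-like object.
    dialect
        ``"canonical_long"`` or ``"fitbit_activities"``.
    subject_id
        Required for the Fitbit dialect (exports carry no subject column;
        supply it from the filename stem or a CLI flag).
    date_format
        Optional explicit ``strptime`` format; default tries ISO then
        MM/DD/YY.
    distance_unit
        ``"km"`` (default) or ``"miles"`` — Fitbit-dialect distances in
        miles are converted to kilometres on read.

    Returns records sorted by (subject_id, date); an empty stream yields an
    empty list.
    """
    if dialect not in ("canonical_long", "fitbit_activities"):
        raise FormatError(f"unknown dialect {dialect!r}")
    if distance_unit not in ("km", "miles"):
        raise FormatError(f"unknown distance unit {distance_unit!r}")
    text = stream.read() if hasattr(stream, "read") else stream
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        return []
    if dialect == "canonical_long":
        records = _parse_canonical(lines, date_format)
    else:
        if subject_id is None:
            raise FormatError("subject_id is required for the fitbit_activities dialect")
        records = _parse_fitbit(lines, subject_id, date_format, distance_unit)
    return sorted(records, key=lambda r: (r.subject_id, r.date))


def write_canonical(records) -> str:
    """Serialise records to canonical-long CSV text.

    Validates the type invariants first (non-negative counts, minute sum
    ≤ 1440, one record per subject-day); rows are written sorted by
    (subject_id, date) so output is order-insensitive in the input.
    ``parse_fitbit_export(write_canonical(r), "canonical_long")`` is the
    identity on valid records.
    """
    records = sorted(records, key=lambda r: (r.subject_id, r.date))
    seen = set()
    for r in records:
        problems = r.check()
        if problems:
            raise ValidationError(
                f"invalid record {r.subject_id}/{r.date}: {'; '.join(problems)}"
            )
        key = (r.subject_id, r.date)
        if key in seen:
            raise ValidationError(f"duplicate record for {r.subject_id} on {r.date}")
        seen.add(key)
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CANONICAL_COLUMNS)
    for r in records:
        writer.writerow(
            [
                r.subject_id,
                r.date.isoformat(),
                r.steps,
                repr(r.distance_km),
                r.minutes_sedentary,
                r.minutes_lightly_active,
                r.minutes_fairly_active,
                r.minutes_very_active,
            ]
        )
    return buf.getvalue()


def read_canonical_csv(path) -> pd.DataFrame:
    """Read a canonical-long CSV file into the canonical DataFrame."""
    with open(path, "r", encoding="utf-8") as fh:
        records = parse_fitbit_export(fh, dialect="canonical_long")
    from .data import records_to_frame

    return records_to_frame(records)


def validate_records(records) -> ValidationReport:
    """Audit a record list: duplicates, out-of-range values, calendar gaps.

    Never mutates or filters the input; gaps are reported per subject as
    (first missing date, gap length in days).
    """
    records = list(records)
    report = ValidationReport(n_records=len(records))
    seen: dict = {}
    for r in records:
        key = (r.subject_id, r.date)
        if key in seen:
            report.n_duplicate_dates += 1
            report.messages.append(f"duplicate date {r.date} for {r.subject_id} (keeping first)")
        else:
            seen[key] = r
        problems = r.check()
        if problems:
            report.n_out_of_range += 1
            report.messages.append(
                f"out-of-range record {r.subject_id}/{r.date}: {'; '.join(problems)}"
            )
    by_subject: dict[str, list[dt.date]] = {}
    for subject_id, date in seen:
        by_subject.setdefault(subject_id, []).append(date)
    for subject_id in sorted(by_subject):
        dates = sorted(by_subject[subject_id])
        for prev, nxt in zip(dates, dates[1:]):
            gap = (nxt - prev).days - 1
            if gap > 0:
                gap_start = prev + dt.timedelta(days=1)
                report.date_gaps.append((gap_start, gap))
                report.messages.append(
                    f"{subject_id}: {gap}-day gap starting {gap_start}"
                )
    return report
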