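"""Policy restriction-phase calendar and phase-based slicing.

The packaged default calendar covers the eight UK COVID-19 policy regimes in
Greater London from 2020-01-01 to 2021-02-27.  Each phase is a contiguous,
non-overlapping date interval; day counts are inclusive of both endpoints.

Note on the packaged calendar: the published day count for the last phase
("Third national lockdown", 51 days) does not match inclusive date arithmetic
(2021-01-06..2021-02-27 is 53 days).  The calendar stores the dates as
published and keeps the published count as ``reported_days`` metadata; the
:func:`phase_duration` function always returns the arithmetic count.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "RestrictionPhase",
    "default_calendar",
    "phase_duration",
    "slice_by_phase",
    "calendar_to_yaml",
    "calendar_from_yaml",
    "validate_calendar",
]


@dataclass(frozen=True)
class RestrictionPhase:
    """A named, contiguous date interval of a policy regime.

    ``reported_days`` carries an externally published day count where one
    exists; it is metadata only and may disagree with the inclusive
    arithmetic count (see module docstring).
    """

    name: str
    start_date: dt.date
    end_date: dt.date
    reported_days: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"phase {self.name!r}: start_date {self.start_date} "
                f"after end_date {self.end_date}"
            )

    def contains(self, day: dt.date) -> bool:
        return self.start_date <= day <= self.end_date


_DEFAULT_ROWS: tuple[tuple[str, str, str, int], ...] = (
    ("Before lockdown", "2020-01-01", "2020-03-22", 82),
    ("First national lockdown", "2020-03-23", "2020-07-03", 103),
    ("Minimal lockdown restrictions", "2020-07-04", "2020-09-13", 72),
    ("Reimposing restrictions", "2020-09-14", "2020-10-13", 30),
    ("Three-tire restrictions", "2020-10-14", "2020-11-04", 22),
    ("Second national lockdown", "2020-11-05", "2020-12-02", 28),
    ("Four-tier restrictions", "2020-12-03", "2021-01-05", 34),
    ("Third national lockdown", "2021-01-06", "2021-02-27", 51),
)


def default_calendar() -> list[RestrictionPhase]:
    """The eight packaged restriction phases, ordered by start date."""
    return [
        RestrictionPhase(
            name,
            dt.date.fromisoformat(start),
            dt.date.fromisoformat(end),
            reported_days=days,
        )
        for name, start, end, days in _DEFAULT_ROWS
    ]


def phase_duration(phase: RestrictionPhase) -> int:
    """Inclusive day count of a phase: ``end_date - start_date + 1``."""
    return (phase.end_date - phase.start_date).days + 1


def validate_calendar(calendar: Sequence[RestrictionPhase]) -> None:
    """Raise ``ValueError`` unless phases are sorted and non-overlapping."""
    for prev, cur in zip(calendar, calendar[1:]):
        if cur.start_date <= prev.end_date:
            raise ValueError(
                f"phases {prev.name!r} and {cur.name!r} overlap or are unsorted"
            )


def _as_dates(values: Iterable) -> list[dt.date]:
    out = []
    for v in values:
        if isinstance(v, dt.datetime):
            out.append(v.date())
        elif isinstance(v, dt.date):
            out.append(v)
        else:
            out.append(pd.Timestamp(v).date())
    return out


def slice_by_phase(daily_indexed, phase: RestrictionPhase):
    """Restrict a date-keyed structure to the dates inside ``phase``.

    Accepts a DataFrame with date-like columns (units x days matrices), a
    Series with a date-like index, or a plain mapping keyed by dates.  Order
    is preserved; an empty result simply means no overlap.
    """
    if isinstance(daily_indexed, pd.DataFrame):
        keep = [
            c
            for c, d in zip(daily_indexed.columns, _as_dates(daily_indexed.columns))
            if phase.contains(d)
        ]
        return daily_indexed.loc[:, keep]
    if isinstance(daily_indexed, pd.Series):
        mask = [phase.contains(d) for d in _as_dates(daily_indexed.index)]
        return daily_indexed[mask]
    if isinstance(daily_indexed, dict):
        return {
            k: v
            for k, v in daily_indexed.items()
            if phase.contains(_as_dates([k])[0])
        }
    raise TypeError(f"unsupported daily-indexed structure: {type(daily_indexed)!r}")


def calendar_to_yaml(calendar: Sequence[RestrictionPhase], path) -> None:
    """Serialise a calendar to a YAML file with ISO dates."""
    payload = [
        {
            "name": p.name,
            "start": p.start_date.isoformat(),
            "end": p.end_date.isoformat(),
            **({"reported_days": p.reported_days} if p.reported_days is not None else {}),
        }
        for p in calendar
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def calendar_from_yaml(path) -> list[RestrictionPhase]:
    """Load a calendar written by :func:`calendar_to_yaml`; validates order."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    cal = [
        RestrictionPhase(
            row["name"],
            dt.date.fromisoformat(str(row["start"])),
            dt.date.fromisoformat(str(row["end"])),
            reported_days=row.get("reported_days"),
        )
        for row in payload
    ]
    validate_calendar(cal)
    return cal
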