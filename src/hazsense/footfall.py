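"""Footfall aggregation: stays -> units x days count matrix, and the daily
recovery index against a pre-pandemic benchmark window.

Footfall counts *stays* per unit-day by default (a user with two stays in a
unit on one day contributes two); a unique-user variant is available behind
``count="users"``.  A stay is attributed wholly to the unit containing its
centroid and to its start date.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

from .geo import validate_disjoint_units

logger = logging.getLogger(__name__)

__all__ = [
    "assign_stays_to_units",
    "build_footfall_matrix",
    "recovery_index",
    "RecoverySeries",
    "coverage_share",
    "write_matrix",
    "read_matrix",
]


def assign_stays_to_units(
    stays: pd.DataFrame, units: pd.DataFrame, validate: bool = True
) -> pd.DataFrame:
    """Attach a ``unit_id`` column to a stay table by centroid point-in-polygon.

    A centroid on a shared boundary is assigned to exactly one unit: among
    all units whose closure covers the point, the smallest ``unit_id`` wins
    (a fixed, deterministic edge convention).  Centroids outside every unit
    get ``unit_id = NaN``; the unassigned count is logged and stored in
    ``result.attrs["n_unassigned"]``.  Overlapping unit interiors are a
    fatal validation error.
    """
    if validate:
        validate_disjoint_units(units)
    geoms = list(units["geometry"])
    ids = list(units["unit_id"])
    tree = STRtree(geoms)
    out = stays.copy()
    assigned = []
    for lon, lat in zip(out["centroid_lon"], out["centroid_lat"]):
        pt = Point(lon, lat)
        hits = [ids[int(j)] for j in tree.query(pt) if geoms[int(j)].covers(pt)]
        assigned.append(min(hits) if hits else np.nan)
    out["unit_id"] = assigned
    n_unassigned = int(pd.isna(out["unit_id"]).sum())
    out.attrs["n_unassigned"] = n_unassigned
    logger.info("assigned %d stays, %d outside all units", len(out) - n_unassigned, n_unassigned)
    return out


def build_footfall_matrix(
    assigned_stays: pd.DataFrame,
    unit_ids,
    start: dt.date,
    end: dt.date,
    strict: bool = True,
    count: str = "stays",
) -> pd.DataFrame:
    """Build the units x days footfall count matrix.

    Cell (i, j) is the number of assigned stays (or unique users, with
    ``count="users"``) in unit i starting on day j.  Units without stays
    appear as all-zero rows; the date axis is gap-free from ``start`` to
    ``end``.  Stays outside the range are an error in strict mode and
    clipped with a warning otherwise.
    """
    dates = pd.date_range(start, end, freq="D")
    rows = pd.Index(sorted(unit_ids), name="unit_id")
    matrix = pd.DataFrame(0, index=rows, columns=dates, dtype=int)
    stays = assigned_stays.dropna(subset=["unit_id"]).copy()
    if len(stays):
        day = pd.to_datetime(stays["start_time"]).dt.normalize()
        outside = (day < dates[0]) | (day > dates[-1])
        if outside.any():
            msg = f"{int(outside.sum())} stay(s) outside the date range {start}..{end}"
            if strict:
                raise ValueError(msg)
            logger.warning("%s; clipped", msg)
            stays = stays.loc[~outside]
            day = day.loc[~outside]
        if count == "stays":
            grouped = stays.groupby([stays["unit_id"], day]).size()
        elif count == "users":
            grouped = stays.groupby([stays["unit_id"], day])["user_id"].nunique()
        else:
            raise ValueError(f"count must be 'stays' or 'users', got {count!r}")
        for (uid, d), value in grouped.items():
            matrix.loc[uid, d] = int(value)
    return matrix


@dataclass(frozen=True)
class RecoverySeries:
    """City-wide daily footfall as a percentage of a benchmark mean.

    ``daily`` is 100 x total(day) / benchmark; ``rolling`` a trailing 7-day
    mean using the days available at the series head.
    """

    daily: pd.Series
    rolling: pd.Series
    benchmark: float
    n_benchmark_days: int


def recovery_index(
    matrix: pd.DataFrame, benchmark_start: dt.date, benchmark_end: dt.date
) -> RecoverySeries:
    """Daily recovery index of the city-wide footfall total.

    The benchmark is the mean, over the benchmark window, of the daily total
    summed across all units; each day's index is its total as a percentage
    of that benchmark.  Scale-invariant: multiplying all counts by a
    constant leaves the series unchanged.  A zero benchmark is fatal.
    """
    totals = matrix.sum(axis=0).astype(float)
    dates = pd.to_datetime(matrix.columns)
    window = (dates >= pd.Timestamp(benchmark_start)) & (dates <= pd.Timestamp(benchmark_end))
    if not window.any():
        raise ValueError("benchmark window does not overlap the matrix dates")
    benchmark = float(totals[window].mean())
    if benchmark == 0:
        raise ValueError("benchmark footfall is zero; recovery index undefined")
    daily = 100.0 * totals / benchmark
    rolling = daily.rolling(window=7, min_periods=1).mean()
    return RecoverySeries(daily, rolling, benchmark, int(window.sum()))


def coverage_share(part: float, whole: float, ndigits: int = 1) -> float:
    """Percentage share of a subpopulation, rounded to ``ndigits``.

    E.g. the share of study-area users among all users in a GPS panel.
    """
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, ndigits)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a footfall matrix: first column unit_id, then ISO-dated columns."""
    out = matrix.copy()
    out.columns = [pd.Timestamp(c).date().isoformat() for c in out.columns]
    out.to_csv(path)


def read_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, index_col="unit_id")
    matrix.columns = pd.DatetimeIndex([pd.Timestamp(c) for c in matrix.columns])
    return matrix
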