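"""Stay (stay-point) detection from per-user GPS trajectories.

A stay is a stationary episode: a maximal run of consecutive points that all
lie within ``d_max`` metres of the run's first point (the anchor) and whose
time span is at least ``t_min`` seconds.  The scan is greedy and anchored:

* anchor at index ``i``; extend ``j`` while ``dist(p_i, p_j) <= d_max``;
* on the first violation (or at the end of the sequence) the candidate
  window is ``p_i .. p_{j-1}``; it is emitted as a stay iff
  ``t_{j-1} - t_i >= t_min``;
* after an emitted stay the anchor restarts at ``j``; after a rejected
  window it advances by one point, so stays beginning inside a rejected
  window are not skipped.

Distances are measured from the anchor, not between consecutive points, so a
slow drift that stays within ``d_max`` of where it began still counts as one
stay.  The default thresholds are ``d_max = 50`` m and ``t_min = 300`` s
(at least five minutes within a 50-metre radius), and the duration test is
boundary-inclusive.  Distances default to haversine; a locally projected
Euclidean metric is available for comparison.

No maximum-gap rule is applied: a recording gap inside a candidate window is
allowed, but gaps longer than an hour are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import equirectangular_m, haversine_m

logger = logging.getLogger(__name__)

__all__ = [
    "StayParams",
    "detect_stays",
    "detect_stays_all",
    "read_trajectories",
    "write_stays",
    "read_stays",
]

TRAJECTORY_COLUMNS = ["user_id", "timestamp", "longitude", "latitude"]
STAY_COLUMNS = [
    "user_id",
    "centroid_lon",
    "centroid_lat",
    "start_time",
    "end_time",
    "duration_s",
    "n_points",
]

_GAP_LOG_S = 3600.0


@dataclass(frozen=True)
class StayParams:
    """Detection thresholds: radius ``d_max_m`` (m) and dwell ``t_min_s`` (s)."""

    d_max_m: float = 50.0
    t_min_s: float = 300.0

    def __post_init__(self) -> None:
        if self.d_max_m <= 0 or self.t_min_s <= 0:
            raise ValueError("d_max_m and t_min_s must both be positive")


def _distance(metric: str):
    if metric == "haversine":
        return haversine_m
    if metric == "euclidean":
        return equirectangular_m
    raise ValueError(f"unknown metric {metric!r}")


def detect_stays(
    points: pd.DataFrame,
    params: StayParams = StayParams(),
    metric: str = "haversine",
) -> pd.DataFrame:
    """Detect stays in one user's time-sorted point sequence.

    ``points`` needs columns ``user_id``, ``timestamp`` (datetime64),
    ``longitude``, ``latitude``.  Returns a stay table with centroid
    (arithmetic mean of member lon/lat), start/end time, duration and member
    count; empty for fewer than two points.
    """
    if len(points) < 2:
        return pd.DataFrame(columns=STAY_COLUMNS)
    users = points["user_id"].unique()
    if len(users) != 1:
        raise ValueError("detect_stays expects a single user's sequence")
    ts = pd.to_datetime(points["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("points must be sorted by timestamp")

    dist = _distance(metric)
    lon = points["longitude"].to_numpy(dtype=float)
    lat = points["latitude"].to_numpy(dtype=float)
    t = ts.astype("int64").to_numpy() / 1e9  # seconds

    gaps = np.diff(t)
    if (gaps > _GAP_LOG_S).any():
        logger.info(
            "user %s: %d recording gap(s) longer than %d s (max %.0f s)",
            users[0], int((gaps > _GAP_LOG_S).sum()), int(_GAP_LOG_S), gaps.max(),
        )

    m = len(lon)
    rows = []
    i = 0
    while i < m:
        j = i + 1
        while j < m and dist(lon[i], lat[i], lon[j], lat[j]) <= params.d_max_m:
            j += 1
        last = j - 1
        if t[last] - t[i] >= params.t_min_s:
            rows.append(
                (
                    users[0],
                    float(lon[i : j].mean()),
                    float(lat[i : j].mean()),
                    ts.iloc[i],
                    ts.iloc[last],
                    float(t[last] - t[i]),
                    j - i,
                )
            )
            i = j
        else:
            i += 1
    return pd.DataFrame(rows, columns=STAY_COLUMNS)


def detect_stays_all(
    trajectories: pd.DataFrame,
    params: StayParams = StayParams(),
    metric: str = "haversine",
) -> pd.DataFrame:
    """Run :func:`detect_stays` per user on a multi-user trajectory table."""
    parts = []
    for _, group in trajectories.groupby("user_id", sort=True):
        stays = detect_stays(group.reset_index(drop=True), params, metric)
        if len(stays):
            parts.append(stays)
    if not parts:
        return pd.DataFrame(columns=STAY_COLUMNS)
    out = pd.concat(parts, ignore_index=True)
    logger.info("detected %d stays from %d points", len(out), len(trajectories))
    return out


def read_trajectories(path, strict: bool = False) -> pd.DataFrame:
    """Read a delimited trajectory file into a clean multi-user table.

    Expects a header ``user_id,timestamp,longitude,latitude``.  Rows are
    grouped by user and sorted by timestamp within user; exact duplicate
    records are dropped (count logged).  Unparseable timestamps are fatal in
    strict mode and skipped with a warning otherwise; the offending line
    numbers are reported.
    """
    raw = pd.read_csv(path, dtype={"user_id": str})
    missing = [c for c in TRAJECTORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"trajectory file missing columns: {missing}")

    parsed = pd.to_datetime(raw["timestamp"], utc=True, errors="coerce")
    bad = parsed.isna() & raw["timestamp"].notna()
    if bad.any():
        lines = (raw.index[bad] + 2).tolist()  # +2: header + 1-based
        msg = f"{int(bad.sum())} unparseable timestamp(s) at line(s) {lines[:20]}"
        if strict:
            raise ValueError(msg)
        logger.warning("%s; rows skipped", msg)
    raw = raw.loc[~bad].copy()
    raw["timestamp"] = parsed.loc[~bad].dt.tz_localize(None)

    before = len(raw)
    raw = raw.drop_duplicates(subset=TRAJECTORY_COLUMNS)
    dropped = before - len(raw)
    if dropped:
        logger.info("dropped %d exact-duplicate trajectory record(s)", dropped)

    raw = raw.sort_values(["user_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    raw.attrs["n_duplicates_dropped"] = dropped
    return raw[TRAJECTORY_COLUMNS]


def write_stays(stays: pd.DataFrame, path) -> None:
    """Write a stay table as delimited text with ISO timestamps."""
    out = stays.copy()
    for col in ("start_time", "end_time"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_stays(path) -> pd.DataFrame:
    stays = pd.read_csv(path, dtype={"user_id": str})
    for col in ("start_time", "end_time"):
        stays[col] = pd.to_datetime(stays[col])
    return stays
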