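"""Seeded synthetic inputs: unit grids, GPS trajectories with planted stays,
and urban-feature tables with planted associations.

The generator emulates the statistical structure the downstream stages
assume, at desk scale:

* a rectangular grid of non-overlapping cells stands in for census output
  areas;
* each unit belongs to a temporal *archetype* (busy-weekday, busy-weekend,
  flat, recovering) whose expected daily stay count follows a rate model
  ``base_rate x weekday/weekend multiplier x phase multiplier`` with Poisson
  counts per unit-day;
* each planted stay becomes a tight burst of GPS points (default four points
  over ten minutes within a 20 m jitter radius), bracketed by transit points
  placed so they can never merge into or extend a detected stay — the
  planted-stay ledger is therefore an exact oracle for stay detection at the
  default thresholds (50 m / 5 min);
* the urban-feature table has ten nonnegative land-use acreage columns and
  one eight-level socio-demographic supergroup column; designated columns
  get archetype-dependent means, the rest are archetype-independent noise.

Everything is driven by one integer seed and regenerates deterministically.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geo import offset_lonlat
from .phases import RestrictionPhase, default_calendar, validate_calendar

__all__ = [
    "ArchetypeSpec",
    "SyntheticScenario",
    "default_archetypes",
    "demo_scenario",
    "association_scenario",
    "generate_units",
    "archetype_assignment",
    "expected_rate",
    "generate_trajectories",
    "sample_footfall_matrix",
    "generate_urban_features",
    "SUPERGROUPS",
]

#: The eight top-level ONS output-area socio-demographic supergroups.
SUPERGROUPS = (
    "rural residents",
    "cosmopolitans",
    "ethnic mix",
    "blue collar neighbourhoods",
    "multicultural metropolitan",
    "suburbanites",
    "hard-pressed households",
    "urbanites",
)

#: Baseline mean acreage (km^2-scale arbitrary units) for the ten land-use columns.
_LU_BASE_MEANS = (4.0, 5.0, 3.0, 6.0, 2.0, 5.0, 3.0, 4.0, 2.0, 3.0)

LAND_USE_COLUMNS = tuple(f"lu_{i}" for i in range(10))


@dataclass(frozen=True)
class ArchetypeSpec:
    """Rate model of one temporal archetype of units.

    Expected stays per unit-day = ``base_rate`` x the weekday or weekend
    multiplier x the multiplier of the phase the day falls in.
    """

    name: str
    base_rate: float
    weekday_multiplier: float
    weekend_multiplier: float
    phase_multipliers: dict[str, float]

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        mults = [self.weekday_multiplier, self.weekend_multiplier, *self.phase_multipliers.values()]
        if any(m <= 0 for m in mults):
            raise ValueError("all multipliers must be > 0")


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of a seeded synthetic study.

    ``n_units`` maps archetype name to unit count; the grid must contain at
    least the total.  ``feature_effect`` maps a land-use column to
    per-archetype mean shifts, making that column informative about
    archetype membership.
    """

    archetypes: tuple[ArchetypeSpec, ...]
    n_units: dict[str, int]
    n_users: int
    calendar: tuple[RestrictionPhase, ...]
    grid_rows: int
    grid_cols: int
    cell_size_m: float = 500.0
    origin: tuple[float, float] = (-0.1276, 51.5072)  # central London
    feature_effect: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0
    jitter_radius_m: float = 20.0
    stay_duration_s: float = 600.0
    points_per_stay: int = 4

    def __post_init__(self) -> None:
        validate_calendar(self.calendar)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.grid_rows * self.grid_cols < sum(self.n_units.values()):
            raise ValueError("grid too small for the requested unit counts")
        named = {a.name for a in self.archetypes}
        if set(self.n_units) - named:
            raise ValueError("n_units refers to unknown archetypes")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.calendar[0].start_date, self.calendar[-1].end_date, freq="D")


def default_archetypes(calendar=None) -> tuple[ArchetypeSpec, ...]:
    """Four packaged archetypes over the default eight-phase calendar.

    Phase multipliers emulate the observed city-wide pattern: a drop to
    roughly a third of baseline activity at the first national lockdown,
    partial summer recovery, renewed suppression in later lockdowns, with
    the *recovering* archetype climbing back towards baseline instead.
    """
    cal = list(calendar) if calendar is not None else default_calendar()
    names = [p.name for p in cal]

    def mults(values):
        return dict(zip(names, values))

    return (
        ArchetypeSpec("busy-weekday", 6.0, 1.4, 0.6,
                      mults([1.0, 0.30, 0.55, 0.50, 0.45, 0.35, 0.40, 0.30][: len(names)] or [1.0])),
        ArchetypeSpec("busy-weekend", 5.0, 0.7, 1.6,
                      mults([1.0, 0.40, 0.70, 0.60, 0.55, 0.60, 0.55, 0.45][: len(names)] or [1.0])),
        ArchetypeSpec("flat", 4.0, 1.0, 1.0,
                      mults([1.0, 0.50, 0.65, 0.60, 0.55, 0.50, 0.50, 0.45][: len(names)] or [1.0])),
        ArchetypeSpec("recovering", 4.0, 1.0, 1.0,
                      mults([1.0, 0.30, 0.55, 0.70, 0.80, 0.75, 0.85, 0.90][: len(names)] or [1.0])),
    )


_DEFAULT_EFFECT = {
    "lu_0": {"busy-weekday": 6.0, "busy-weekend": 4.0, "flat": 2.0, "recovering": 0.0}
}


def demo_scenario(seed: int = 0) -> SyntheticScenario:
    """The packaged end-to-end trajectory demo: 3x3 grid, 20 users, 8 phases."""
    return SyntheticScenario(
        archetypes=default_archetypes(),
        n_units={"busy-weekday": 3, "busy-weekend": 2, "flat": 2, "recovering": 2},
        n_users=20,
        calendar=tuple(default_calendar()),
        grid_rows=3,
        grid_cols=3,
        feature_effect=dict(_DEFAULT_EFFECT),
        seed=seed,
    )


def association_scenario(seed: int = 0) -> SyntheticScenario:
    """The packaged association study: 100 units (25 per archetype).

    Sized so a stratified 10-fold cross-validated classifier fit is
    meaningful; footfall is sampled directly from the rate model rather than
    via trajectories at this scale.
    """
    return SyntheticScenario(
        archetypes=default_archetypes(),
        n_units={"busy-weekday": 25, "busy-weekend": 25, "flat": 25, "recovering": 25},
        n_users=200,
        calendar=tuple(default_calendar()),
        grid_rows=10,
        grid_cols=10,
        feature_effect=dict(_DEFAULT_EFFECT),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# units


def generate_units(rows: int, cols: int, cell_size_m: float, origin=(-0.1276, 51.5072)) -> pd.DataFrame:
    """Tile ``rows x cols`` rectangular cells north-east of ``origin``.

    Cells are laid out in a local metric frame and converted to lon/lat, so
    haversine distances match the nominal cell size at the origin latitude.
    Ids are ``u<row>_<col>``, stable across runs.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be > 0")
    lon0, lat0 = origin
    records = []
    for r in range(rows):
        for c in range(cols):
            corners_m = [
                (c * cell_size_m, r * cell_size_m),
                ((c + 1) * cell_size_m, r * cell_size_m),
                ((c + 1) * cell_size_m, (r + 1) * cell_size_m),
                (c * cell_size_m, (r + 1) * cell_size_m),
            ]
            poly = Polygon([offset_lonlat(lon0, lat0, x, y) for x, y in corners_m])
            records.append({"unit_id": f"u{r}_{c}", "geometry": poly})
    return pd.DataFrame(records)


def archetype_assignment(unit_ids, scenario: SyntheticScenario) -> pd.Series:
    """Deterministic unit -> archetype map (round-robin over sorted ids)."""
    ids = sorted(unit_ids)
    total = sum(scenario.n_units.values())
    if len(ids) < total:
        raise ValueError("fewer units than the scenario requests")
    pool: list[str] = []
    remaining = dict(scenario.n_units)
    order = [a.name for a in scenario.archetypes if a.name in remaining]
    while any(remaining.get(n, 0) > 0 for n in order):
        for name in order:
            if remaining.get(name, 0) > 0:
                pool.append(name)
                remaining[name] -= 1
    return pd.Series(pool, index=ids[:total], name="archetype")


# ---------------------------------------------------------------------------
# rate model


def expected_rate(arch: ArchetypeSpec, day: dt.date, calendar) -> float:
    """Expected planted stays per unit on ``day`` under the archetype model."""
    wd = arch.weekday_multiplier if day.weekday() < 5 else arch.weekend_multiplier
    for phase in calendar:
        if phase.contains(day):
            return arch.base_rate * wd * arch.phase_multipliers[phase.name]
    return 0.0


def _rate_matrix(scenario: SyntheticScenario, assignment: pd.Series) -> pd.DataFrame:
    arch_by_name = {a.name: a for a in scenario.archetypes}
    dates = scenario.dates
    rates = {
        name: [expected_rate(arch_by_name[name], d.date(), scenario.calendar) for d in dates]
        for name in assignment.unique()
    }
    return pd.DataFrame(
        [rates[assignment[uid]] for uid in assignment.index],
        index=assignment.index,
        columns=dates,
        dtype=float,
    )


def sample_footfall_matrix(
    scenario: SyntheticScenario, assignment: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a units x days Poisson count matrix straight from the rate model.

    A cheap alternative to full trajectory simulation for clustering- and
    association-scale studies; shares the exact rate model with
    :func:`generate_trajectories`.  Returns ``(matrix, assignment)``.
    """
    if assignment is None:
        units = generate_units(scenario.grid_rows, scenario.grid_cols, scenario.cell_size_m, scenario.origin)
        assignment = archetype_assignment(units["unit_id"], scenario)
    rng = np.random.default_rng(scenario.seed)
    lam = _rate_matrix(scenario, assignment)
    counts = rng.poisson(lam.to_numpy())
    matrix = pd.DataFrame(counts, index=lam.index, columns=lam.columns)
    matrix.index.name = "unit_id"
    return matrix, assignment


# ---------------------------------------------------------------------------
# trajectories

_SLOT_S = 1800.0  # scheduling slots per user-day; stays occupy the slot head
_TRANSIT_NEAR_M = 150.0
_TRANSIT_FAR_M = 350.0


def _cell_frame(poly) -> tuple[float, float, float, float]:
    lons = [p[0] for p in poly.exterior.coords]
    lats = [p[1] for p in poly.exterior.coords]
    return min(lons), min(lats), max(lons), max(lats)


def generate_trajectories(
    scenario: SyntheticScenario, units: pd.DataFrame, assignment: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate GPS point streams with planted stays; return ``(points, ledger)``.

    Every planted stay is a burst of ``points_per_stay`` points jittered
    within ``jitter_radius_m`` of a centroid placed well inside one unit
    cell, spanning ``stay_duration_s``.  Between consecutive stays of a user
    (and before the first / after the last) transit points are placed
    >100 m from both adjacent stay centroids and >50 m apart, so no transit
    point can join or seed a detected stay.  The ledger lists every planted
    stay with its unit, date, centroid and times, and is an exact oracle for
    the detector at default thresholds.
    """
    if assignment is None:
        assignment = archetype_assignment(units["unit_id"], scenario)
    rng = np.random.default_rng(scenario.seed)
    point_cols = ["user_id", "timestamp", "longitude", "latitude"]
    ledger_cols = [
        "stay_id", "user_id", "unit_id", "date",
        "start_time", "end_time", "centroid_lon", "centroid_lat", "n_points",
    ]
    if scenario.n_users == 0:
        return pd.DataFrame(columns=point_cols), pd.DataFrame(columns=ledger_cols)

    lam = _rate_matrix(scenario, assignment)
    counts = rng.poisson(lam.to_numpy())
    frames = {uid: _cell_frame(geom) for uid, geom in zip(units["unit_id"], units["geometry"])}
    # keep planted centroids this far (in degrees, approx.) inside the cell
    # so the detected centroid cannot drift across a cell edge
    margin_m = scenario.jitter_radius_m + 10.0

    dates = scenario.dates
    n_slots = int(86400 // _SLOT_S)
    per_user_day: dict[tuple[int, int], list[str]] = {}
    for row, uid in enumerate(lam.index):
        for col in range(len(dates)):
            for _ in range(int(counts[row, col])):
                user = int(rng.integers(scenario.n_users))
                per_user_day.setdefault((user, col), []).append(uid)

    stay_rows = []  # ledger
    pts_by_user: dict[int, list[tuple[float, float, float]]] = {u: [] for u in range(scenario.n_users)}
    stays_by_user: dict[int, list[dict]] = {u: [] for u in range(scenario.n_users)}
    stay_id = 0
    for (user, col), unit_list in sorted(per_user_day.items()):
        k = len(unit_list)
        if k > n_slots:  # cannot schedule more stays than slots in a day
            unit_list = unit_list[:n_slots]
            k = n_slots
        slots = rng.choice(n_slots, size=k, replace=False)
        slots.sort()
        day_start = dates[col].timestamp()
        for slot, uid in zip(slots, unit_list):
            start = day_start + slot * _SLOT_S + float(rng.uniform(0, 300.0))
            lon_min, lat_min, lon_max, lat_max = frames[uid]
            # metric margin converted via the frame's own degree spans
            dlon = (lon_max - lon_min) * margin_m / scenario.cell_size_m
            dlat = (lat_max - lat_min) * margin_m / scenario.cell_size_m
            clon = float(rng.uniform(lon_min + dlon, lon_max - dlon))
            clat = float(rng.uniform(lat_min + dlat, lat_max - dlat))
            npts = scenario.points_per_stay
            times = np.linspace(0.0, scenario.stay_duration_s, npts)
            ang = rng.uniform(0, 2 * np.pi, size=npts)
            rad = scenario.jitter_radius_m * np.sqrt(rng.uniform(0, 1, size=npts))
            for k2 in range(npts):
                plon, plat = offset_lonlat(clon, clat, rad[k2] * np.cos(ang[k2]), rad[k2] * np.sin(ang[k2]))
                pts_by_user[user].append((start + times[k2], plon, plat))
            stays_by_user[user].append(
                {"start": start, "end": start + scenario.stay_duration_s, "lon": clon, "lat": clat}
            )
            stay_rows.append(
                (
                    stay_id, f"user{user:04d}", uid, dates[col].date().isoformat(),
                    start, start + scenario.stay_duration_s, clon, clat, npts,
                )
            )
            stay_id += 1

    # transit points: bracket each user's stay sequence
    for user, stay_list in stays_by_user.items():
        stay_list.sort(key=lambda s: s["start"])
        for idx, cur in enumerate(stay_list):
            # two outbound transit points after the current stay, walking away
            # from both the current and the next stay along the line between them
            nxt = stay_list[idx + 1] if idx + 1 < len(stay_list) else None
            gap_end = nxt["start"] if nxt is not None else cur["end"] + 1200.0
            if nxt is not None:
                w = np.array([cur["lon"] - nxt["lon"], cur["lat"] - nxt["lat"]])
                nw = np.linalg.norm(w)
                w = w / nw if nw > 1e-9 else np.array([1.0, 0.0])
            else:
                w = np.array([1.0, 0.0])
            t1 = cur["end"] + (gap_end - cur["end"]) / 3.0
            t2 = cur["end"] + 2.0 * (gap_end - cur["end"]) / 3.0
            for dist_m, tt in ((_TRANSIT_NEAR_M, t1), (_TRANSIT_FAR_M, t2)):
                tlon, tlat = offset_lonlat(cur["lon"], cur["lat"], w[0] * dist_m, w[1] * dist_m)
                pts_by_user[user].append((tt, tlon, tlat))
        if stay_list:
            first = stay_list[0]
            tlon, tlat = offset_lonlat(first["lon"], first["lat"], -_TRANSIT_FAR_M, 0.0)
            pts_by_user[user].append((first["start"] - 600.0, tlon, tlat))

    records = []
    for user in range(scenario.n_users):
        pts = sorted(pts_by_user[user])
        name = f"user{user:04d}"
        for tt, plon, plat in pts:
            records.append((name, pd.Timestamp(tt, unit="s"), plon, plat))
    points = pd.DataFrame(records, columns=point_cols)
    ledger = pd.DataFrame(stay_rows, columns=ledger_cols)
    for col in ("start_time", "end_time"):
        ledger[col] = pd.to_datetime(ledger[col], unit="s")
    return points, ledger


def write_trajectories(points: pd.DataFrame, path) -> None:
    """Write trajectory points as delimited text with ISO-8601 UTC timestamps."""
    out = points.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# urban features


def generate_urban_features(
    units: pd.DataFrame, archetype_map: pd.Series, scenario: SyntheticScenario
) -> pd.DataFrame:
    """Per-unit static features: 10 land-use acreages + 1 supergroup column.

    Acreage columns are truncated-normal noise around fixed baselines;
    columns named in ``scenario.feature_effect`` get archetype-dependent
    mean shifts.  The supergroup column is archetype-independent (uniform
    over the eight levels) so the continuous planted effects alone carry the
    association signal.
    """
    ids = sorted(archetype_map.index)
    missing = [u for u in ids if u not in set(units["unit_id"])]
    if missing:
        raise ValueError(f"archetype map names unknown units: {missing[:5]}")
    rng = np.random.default_rng(scenario.seed + 1)
    n = len(ids)
    data = {"unit_id": ids}
    for j, col in enumerate(LAND_USE_COLUMNS):
        shifts = np.zeros(n)
        if col in scenario.feature_effect:
            eff = scenario.feature_effect[col]
            shifts = np.array([eff.get(archetype_map[u], 0.0) for u in ids])
        vals = rng.normal(_LU_BASE_MEANS[j] + shifts, scenario.noise_sd)
        data[col] = np.clip(vals, 0.0, None)
    data["supergroup"] = [SUPERGROUPS[i] for i in rng.integers(0, len(SUPERGROUPS), size=n)]
    return pd.DataFrame(data)
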