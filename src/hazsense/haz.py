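"""Human activity zone (HAZ) delineation.

A HAZ is a cluster of geospatial units with homogeneous *standardised*
temporal footfall profiles within an observation period.  The procedure is:

1. row-standardise the footfall matrix: each unit's daily series is centred
   on its mean and divided by its population standard deviation (divisor t),
   so clustering sees the shape of the temporal pattern, not its volume;
   constant (zero-variance) rows have no defined pattern and are excluded;
2. agglomerative clustering (Euclidean metric; Ward linkage by default,
   average/complete available) on the standardised rows, for every candidate
   cluster count n in a search range;
3. pick the n that maximises the mean silhouette coefficient, ties broken
   toward smaller n;
4. relabel clusters by descending mean daily *raw* footfall of their member
   units, so label 0 is always the busiest zone.

Per-phase delineation re-standardises within each phase slice: a unit's HAZ
membership in a phase depends only on its pattern during that phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .phases import RestrictionPhase, slice_by_phase

logger = logging.getLogger(__name__)

__all__ = [
    "SENTINEL_LABEL",
    "StandardizedMatrix",
    "standardize_rows",
    "HazPartition",
    "delineate_hazs",
    "delineate_per_phase",
    "write_partition",
    "read_partition",
]

#: Label given to units excluded from clustering (zero-variance rows).
SENTINEL_LABEL = -1


@dataclass(frozen=True)
class StandardizedMatrix:
    """Row-standardised footfall: retained rows plus the excluded unit ids."""

    values: pd.DataFrame
    excluded_units: tuple[str, ...] = ()


def standardize_rows(matrix: pd.DataFrame) -> StandardizedMatrix:
    """Centre and scale each row by its mean and population SD (divisor t).

    Rows with zero variance are moved to ``excluded_units``; if every row is
    degenerate the matrix cannot be standardised and the call fails.
    Requires at least two date columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("standardisation needs at least two temporal columns")
    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sigma = values.std(axis=1, ddof=0, keepdims=True)
    degenerate = sigma[:, 0] == 0.0
    if degenerate.all():
        raise ValueError("all rows are constant; nothing to standardise")
    retained = ~degenerate
    std = (values[retained] - mu[retained]) / sigma[retained]
    out = pd.DataFrame(std, index=matrix.index[retained], columns=matrix.columns)
    excluded = tuple(matrix.index[degenerate])
    if excluded:
        logger.info("excluded %d zero-variance unit(s) from standardisation", len(excluded))
    return StandardizedMatrix(out, excluded)


@dataclass(frozen=True)
class HazPartition:
    """One period's unit -> HAZ assignment.

    Labels are consecutive ranks 0..n-1 ordered by descending mean daily raw
    footfall; excluded units carry :data:`SENTINEL_LABEL`.
    """

    period: str
    labels: pd.Series  # unit_id -> label (SENTINEL_LABEL for excluded)
    n: int
    silhouette: float
    mean_daily_footfall: pd.Series = field(default=None)  # label -> mean count

    def clustered_units(self) -> pd.Series:
        return self.labels[self.labels != SENTINEL_LABEL]


def _rank_labels(raw_row_means: pd.Series, labels: np.ndarray) -> tuple[np.ndarray, pd.Series]:
    """Permute cluster labels so 0 is the busiest; return (labels, label means)."""
    means = raw_row_means.groupby(labels).mean()
    order = means.sort_values(ascending=False, kind="mergesort").index
    remap = {old: new for new, old in enumerate(order)}
    ranked = np.array([remap[l] for l in labels])
    ranked_means = pd.Series(
        {remap[old]: means[old] for old in means.index}, name="mean_daily_footfall"
    ).sort_index()
    return ranked, ranked_means


def delineate_hazs(
    std: StandardizedMatrix,
    raw: pd.DataFrame,
    n_min: int = 2,
    n_max: int = 15,
    linkage: str = "ward",
    period: str = "all",
) -> HazPartition:
    """Cluster standardised rows into HAZs with silhouette-selected n.

    Fits agglomerative clustering for each n in ``[n_min, n_max]``, scores
    each partition by the mean silhouette coefficient on the standardised
    matrix (Euclidean distance), and keeps the best (ties -> smallest n).
    ``raw`` is the unstandardised count matrix on the same period, used only
    to rank the final labels by mean daily footfall.
    """
    m = len(std.values)
    if not (2 <= n_min <= n_max):
        raise ValueError("need 2 <= n_min <= n_max")
    if n_max >= m:
        raise ValueError(f"n_max={n_max} must be < number of clustered units ({m})")
    X = std.values.to_numpy(dtype=float)
    best = None
    for n in range(n_min, n_max + 1):
        model = AgglomerativeClustering(n_clusters=n, metric="euclidean", linkage=linkage)
        labels = model.fit_predict(X)
        score = float(silhouette_score(X, labels, metric="euclidean"))
        if best is None or score > best[0]:  # strict >: ties keep smaller n
            best = (score, n, labels)
    score, n, labels = best

    raw_means = raw.loc[std.values.index].mean(axis=1)
    ranked, label_means = _rank_labels(raw_means, labels)
    series = pd.Series(SENTINEL_LABEL, index=raw.index, name="haz_label", dtype=int)
    series.loc[std.values.index] = ranked
    return HazPartition(period, series, n, score, label_means)


def delineate_per_phase(
    matrix: pd.DataFrame,
    calendar: list[RestrictionPhase],
    n_min: int = 2,
    n_max: int = 15,
    linkage: str = "ward",
    include_all_period: bool = True,
) -> dict[str, HazPartition]:
    """Delineate HAZs for each phase plus (optionally) the full period.

    Each phase's slice is re-standardised before clustering, so membership
    reflects only that phase's pattern.  Phases shorter than two days are
    rejected; ``n_max`` is clamped to one below the number of clusterable
    units in a slice (logged) so sparse phases still delineate.
    """
    partitions: dict[str, HazPartition] = {}
    jobs = [("all", matrix)] if include_all_period else []
    for phase in calendar:
        sliced = slice_by_phase(matrix, phase)
        if sliced.shape[1] < 2:
            raise ValueError(f"phase {phase.name!r} has fewer than 2 days in the matrix")
        jobs.append((phase.name, sliced))
    for name, sliced in jobs:
        std = standardize_rows(sliced)
        eff_max = min(n_max, len(std.values) - 1)
        if eff_max < n_max:
            logger.info("%s: clamped n_max from %d to %d (m'=%d)", name, n_max, eff_max, len(std.values))
        partitions[name] = delineate_hazs(std, sliced, n_min, eff_max, linkage, period=name)
    return partitions


def write_partition(partition: HazPartition, path) -> None:
    """Write unit_id,haz_label rows plus silhouette/n metadata in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# period={partition.period} n={partition.n} silhouette={partition.silhouette:.6f}\n")
        partition.labels.rename("haz_label").to_csv(fh)


def read_partition(path) -> HazPartition:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=", 1) for kv in header.split())
        labels = pd.read_csv(fh, index_col="unit_id")["haz_label"]
    return HazPartition(meta["period"], labels, int(meta["n"]), float(meta["silhouette"]))
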