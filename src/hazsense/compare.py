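"""Partition similarity across observation periods.

Two HAZ partitions of the same unit universe are compared by
cross-tabulating joint label counts and summarising the table with
Pearson's contingency coefficient

    C = sqrt(chi2 / (chi2 + N)),

where chi2 is the plain Pearson chi-square statistic (no continuity
correction) and N the number of jointly clustered units.  C lies in
[0, 1): 0 for exact independence, approaching 1 for strong association.
C is invariant under relabelling of either partition, so HAZ rank
re-orderings between phases do not affect it.  Units excluded (sentinel
label) in either partition are dropped pairwise.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .haz import SENTINEL_LABEL, HazPartition

logger = logging.getLogger(__name__)

__all__ = ["crosstab", "contingency_coefficient", "pairwise_matrix"]


def crosstab(pa: HazPartition, pb: HazPartition) -> pd.DataFrame:
    """Joint label counts over units clustered in both partitions.

    Units with a sentinel label in either partition are dropped (count
    logged).  An empty intersection is fatal.
    """
    common = pa.labels.index.intersection(pb.labels.index)
    a = pa.labels.loc[common]
    b = pb.labels.loc[common]
    keep = (a != SENTINEL_LABEL) & (b != SENTINEL_LABEL)
    dropped = int((~keep).sum()) + (len(pa.labels) - len(common)) + (len(pb.labels) - len(common))
    if dropped:
        logger.info("crosstab %s vs %s: dropped %d unit(s)", pa.period, pb.period, dropped)
    if not keep.any():
        raise ValueError(f"no units jointly clustered in {pa.period!r} and {pb.period!r}")
    return pd.crosstab(a[keep], b[keep])


def contingency_coefficient(tab: pd.DataFrame) -> float:
    """Pearson's C of a cross-tabulation; 0 for degenerate 1 x k tables.

    Zero-margin rows and columns are dropped before expected counts are
    formed; expected cells below 5 trigger a descriptive warning only.
    """
    counts = np.asarray(tab, dtype=float)
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    n = counts.sum()
    if n < 1:
        raise ValueError("empty contingency table")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return 0.0
    chi2 = chi2_contingency(counts, correction=False).statistic
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    if (expected < 5).any():
        logger.warning("contingency table has expected counts below 5; C is descriptive")
    return math.sqrt(chi2 / (chi2 + n))


def pairwise_matrix(partitions: list[HazPartition]) -> pd.DataFrame:
    """Symmetric matrix of C over every pair of partitions (diagonal: self-C)."""
    if len(partitions) < 2:
        raise ValueError("need at least two partitions")
    names = [p.period for p in partitions]
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, pa in enumerate(partitions):
        for j, pb in enumerate(partitions):
            if j < i:
                continue
            try:
                c = contingency_coefficient(crosstab(pa, pb))
            except ValueError as exc:
                raise ValueError(f"pair ({pa.period!r}, {pb.period!r}): {exc}") from exc
            out.iloc[i, j] = out.iloc[j, i] = c
    return out
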