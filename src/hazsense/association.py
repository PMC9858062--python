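"""Relating static urban characteristics to HAZ membership.

For each observation period a random-forest classifier predicts a unit's
HAZ label from its 11 static features (ten land-use acreages and the
integer-coded socio-demographic supergroup).  Cross-validated accuracy
summarises the *global* relationship between urban form and activity
pattern; normalised Gini importance — each feature's total decrease in
Gini impurity accumulated over all splits of all trees, scaled to sum to
one — gives the *local*, per-feature relationship.

Hyper-parameters are chosen by a seeded randomised search (15 sampled
configurations by default, an exhaustive grid optionally) scored by
stratified k-fold accuracy; the best configuration is refit on all rows.
All randomness (search order, fold shuffling, forests) derives from one
seed, so a result is exactly reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score

from .haz import SENTINEL_LABEL, HazPartition
from .synth import LAND_USE_COLUMNS, SUPERGROUPS

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "build_design",
    "fit_classifier",
    "gini_importance",
    "per_phase_association",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = list(LAND_USE_COLUMNS) + ["supergroup"]

_PARAM_GRID = {
    "n_estimators": [100, 200, 300],
    "max_depth": [None, 4, 8, 16],
    "max_features": ["sqrt", "log2", None, 0.5],
}


@dataclass(frozen=True)
class AssociationResult:
    period: str
    cv_accuracy: float
    importances: pd.Series  # feature -> normalised Gini importance
    best_params: dict
    n_units: int
    seed: int
    model: RandomForestClassifier


def build_design(
    features: pd.DataFrame, partition: HazPartition, one_hot: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix X and label vector y for one period's classifier.

    One row per unit with a non-sentinel HAZ label, ordered by sorted
    ``unit_id`` so the design is independent of input row order.  The
    supergroup is integer-coded as a single column, keeping the 11-column
    design; ``one_hot=True`` expands it instead (note this changes how the
    importance total decomposes across features).  Fewer than two distinct
    labels is fatal.
    """
    feats = features.set_index("unit_id") if "unit_id" in features.columns else features
    clustered = partition.clustered_units()
    common = sorted(feats.index.intersection(clustered.index))
    if not common:
        raise ValueError("no units shared between features and partition")
    X = feats.loc[common, FEATURE_COLUMNS].copy()
    codes = {name: i for i, name in enumerate(SUPERGROUPS)}
    X["supergroup"] = [codes[s] for s in X["supergroup"]]
    if one_hot:
        X = pd.get_dummies(X, columns=["supergroup"], prefix="supergroup")
    y = clustered.loc[common].astype(int)
    if y.nunique() < 2:
        raise ValueError(f"period {partition.period!r}: fewer than 2 distinct HAZ labels")
    return X, y


def _sample_params(n_draws: int, rng: np.random.Generator, exhaustive: bool) -> list[dict]:
    keys = list(_PARAM_GRID)
    grid = [dict(zip(keys, combo)) for combo in itertools.product(*_PARAM_GRID.values())]
    if exhaustive or n_draws >= len(grid):
        return grid
    idx = rng.choice(len(grid), size=n_draws, replace=False)
    return [grid[i] for i in sorted(idx)]


def fit_classifier(
    design: pd.DataFrame,
    labels: pd.Series,
    cv_folds: int = 10,
    n_param_draws: int = 15,
    seed: int = 0,
    period: str = "all",
    exhaustive: bool = False,
) -> AssociationResult:
    """Seeded randomised hyper-parameter search + stratified CV + final refit.

    ``cv_accuracy`` is the best configuration's mean stratified k-fold
    accuracy.  If the rarest label has fewer members than ``cv_folds`` the
    fold count is reduced (warning logged); with singleton classes the CV
    falls back to unstratified folds.
    """
    X = design.to_numpy(dtype=float)
    y = labels.to_numpy()
    rng = np.random.default_rng(seed)
    min_class = int(pd.Series(y).value_counts().min())
    folds = cv_folds
    if min_class < cv_folds:
        folds = max(2, min_class)
        logger.warning(
            "rarest label has %d member(s) < %d folds; reducing to %d fold(s)",
            min_class, cv_folds, folds,
        )
    if min_class >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        logger.warning("singleton class present; falling back to unstratified 2-fold CV")
        cv = KFold(n_splits=2, shuffle=True, random_state=seed)

    best_score, best_params = -np.inf, None
    for params in _sample_params(n_param_draws, rng, exhaustive):
        clf = RandomForestClassifier(random_state=seed, **params)
        score = float(np.mean(cross_val_score(clf, X, y, cv=cv, scoring="accuracy")))
        if score > best_score:
            best_score, best_params = score, params

    model = RandomForestClassifier(random_state=seed, **best_params)
    model.fit(X, y)
    importances = pd.Series(model.feature_importances_, index=design.columns, name="gini_importance")
    return AssociationResult(
        period=period,
        cv_accuracy=best_score,
        importances=importances,
        best_params=best_params,
        n_units=len(design),
        seed=seed,
        model=model,
    )


def gini_importance(result: AssociationResult) -> pd.Series:
    """Normalised Gini importances of a fitted classifier (sum to 1).

    The underlying quantity is each feature's mean decrease in Gini
    impurity accumulated over all splits and trees; the forest normalises
    per tree and averages, so the vector sums to one whenever every tree
    contains at least one split.
    """
    total = float(result.importances.sum())
    if total <= 0:
        raise ValueError("classifier has no splits; importances undefined")
    return result.importances / total


def per_phase_association(
    features: pd.DataFrame,
    partitions: list[HazPartition],
    cv_folds: int = 10,
    n_param_draws: int = 15,
    seed: int = 0,
) -> tuple[list[AssociationResult], pd.DataFrame, pd.DataFrame]:
    """Fit one classifier per partition.

    Returns ``(results, accuracy_table, importance_matrix)`` where the
    importance matrix has features as rows and periods as columns (each
    column summing to 1).  A failing period is reported and skipped; the
    remaining periods are still produced.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    results = []
    for part in partitions:
        try:
            X, y = build_design(features, part)
            results.append(fit_classifier(X, y, cv_folds, n_param_draws, seed, period=part.period))
        except ValueError as exc:
            logger.error("period %r failed: %s", part.period, exc)
    if not results:
        raise ValueError("every period failed to fit")
    accuracy = pd.DataFrame(
        {"period": [r.period for r in results], "cv_accuracy": [r.cv_accuracy for r in results]}
    ).set_index("period")
    importance = pd.DataFrame({r.period: gini_importance(r) for r in results})
    return results, accuracy, importance
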