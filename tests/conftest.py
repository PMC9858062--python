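import datetime as dt

import pytest

import hazsense as hz
from hazsense.phases import RestrictionPhase
from hazsense.synth import ArchetypeSpec, archetype_assignment


@pytest.fixture(scope="session")
def mini_calendar():
    """Two one-week phases — enough temporal structure for cheap tests."""
    return (
        RestrictionPhase("open", dt.date(2020, 1, 1), dt.date(2020, 1, 7)),
        RestrictionPhase("closed", dt.date(2020, 1, 8), dt.date(2020, 1, 14)),
    )


@pytest.fixture(scope="session")
def grid3():
    return hz.generate_units(3, 3, 500)


@pytest.fixture(scope="session")
def demo14(mini_calendar, grid3):
    """3x3-grid, 20-user, 14-day trajectory scenario with its planted ledger."""
    scenario = hz.SyntheticScenario(
        archetypes=hz.default_archetypes(mini_calendar),
        n_units={"busy-weekday": 3, "busy-weekend": 2, "flat": 2, "recovering": 2},
        n_users=20,
        calendar=mini_calendar,
        grid_rows=3,
        grid_cols=3,
        seed=7,
    )
    assignment = archetype_assignment(grid3["unit_id"], scenario)
    points, ledger = hz.generate_trajectories(scenario, grid3, assignment)
    return {
        "scenario": scenario,
        "units": grid3,
        "assignment": assignment,
        "points": points,
        "ledger": ledger,
    }


def strong_two_archetype_scenario(seed=5):
    """Two sharply separated archetypes; Poisson noise negligible vs separation."""
    archs = tuple(a for a in hz.default_archetypes() if a.name in ("busy-weekday", "busy-weekend"))
    return hz.SyntheticScenario(
        archetypes=archs,
        n_units={"busy-weekday": 20, "busy-weekend": 20},
        n_users=50,
        calendar=tuple(hz.default_calendar()),
        grid_rows=7,
        grid_cols=7,
        seed=seed,
    )


def four_archetype_scenario(seed=11):
    """Four archetypes at moderate noise (signal-to-noise around three)."""
    cal = tuple(hz.default_calendar())
    names = [p.name for p in cal]

    def mults(vals):
        return dict(zip(names, vals))

    archs = (
        ArchetypeSpec("busy-weekday", 30, 1.5, 0.5, mults([1.0, 0.35, 0.6, 0.55, 0.5, 0.4, 0.45, 0.35])),
        ArchetypeSpec("busy-weekend", 30, 0.5, 1.5, mults([1.0, 0.45, 0.7, 0.6, 0.55, 0.6, 0.55, 0.45])),
        ArchetypeSpec("flat", 30, 1.0, 1.0, mults([1.0] * 8)),
        ArchetypeSpec("recovering", 30, 1.0, 1.0, mults([0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1])),
    )
    return hz.SyntheticScenario(
        archetypes=archs,
        n_units={a.name: 25 for a in archs},
        n_users=100,
        calendar=cal,
        grid_rows=10,
        grid_cols=10,
        seed=seed,
    )


@pytest.fixture(scope="session")
def association_fixture():
    """Seeded association study: footfall, partition, features, fitted classifier."""
    scenario = hz.association_scenario(seed=3)
    matrix, assignment = hz.sample_footfall_matrix(scenario)
    partition = hz.delineate_hazs(hz.standardize_rows(matrix), matrix, 2, 15)
    units = hz.generate_units(scenario.grid_rows, scenario.grid_cols, scenario.cell_size_m, scenario.origin)
    features = hz.generate_urban_features(units, assignment, scenario)
    X, y = hz.build_design(features, partition)
    result = hz.fit_classifier(X, y, cv_folds=10, n_param_draws=15, seed=3)
    return {
        "scenario": scenario,
        "matrix": matrix,
        "assignment": assignment,
        "partition": partition,
        "features": features,
        "X": X,
        "y": y,
        "result": result,
    }
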