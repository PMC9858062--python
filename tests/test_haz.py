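import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import hazsense as hz
from conftest import four_archetype_scenario, strong_two_archetype_scenario
from hazsense.haz import SENTINEL_LABEL, standardize_rows


def matrix_from(rows, units=None):
    dates = pd.date_range("2020-01-01", periods=len(rows[0]), freq="D")
    index = pd.Index(units or [f"u{i}" for i in range(len(rows))], name="unit_id")
    return pd.DataFrame(rows, index=index, columns=dates)


class TestStandardize:
    def test_simple_row_closed_form(self):
        std = standardize_rows(matrix_from([[1, 2, 3], [5, 1, 0]]))
        np.testing.assert_allclose(
            std.values.iloc[0], [-1.2247, 0.0, 1.2247], atol=1e-3
        )

    def test_constant_row_excluded(self):
        std = standardize_rows(matrix_from([[5, 5, 5], [1, 2, 3]]))
        assert std.excluded_units == ("u0",)
        assert list(std.values.index) == ["u1"]

    def test_retained_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(3)
        std = standardize_rows(matrix_from(rng.integers(0, 40, size=(20, 60)).tolist()))
        values = std.values.to_numpy()
        assert np.abs(values.mean(axis=1)).max() < 1e-9
        assert np.abs(values.std(axis=1, ddof=0) - 1).max() < 1e-9

    def test_all_degenerate_fatal(self):
        with pytest.raises(ValueError):
            standardize_rows(matrix_from([[2, 2, 2], [7, 7, 7]]))

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            standardize_rows(matrix_from([[1], [2]]))


class TestDelineate:
    def test_two_planted_archetypes_recovered_exactly(self):
        matrix, assignment = hz.sample_footfall_matrix(strong_two_archetype_scenario())
        part = hz.delineate_hazs(standardize_rows(matrix), matrix, 2, 8)
        assert part.n == 2
        assert adjusted_rand_score(assignment.loc[part.labels.index], part.labels) == 1.0
        assert -1.0 <= part.silhouette <= 1.0

    def test_four_archetypes_moderate_noise(self):
        matrix, assignment = hz.sample_footfall_matrix(four_archetype_scenario())
        part = hz.delineate_hazs(standardize_rows(matrix), matrix, 2, 15)
        assert part.n == 4
        assert adjusted_rand_score(assignment.loc[part.labels.index], part.labels) >= 0.9

    def test_labels_ranked_by_mean_footfall(self):
        matrix, _ = hz.sample_footfall_matrix(strong_two_archetype_scenario())
        part = hz.delineate_hazs(standardize_rows(matrix), matrix, 2, 8)
        means = part.mean_daily_footfall
        assert list(means.index) == list(range(part.n))
        assert (means.diff().dropna() <= 0).all()

    def test_ranking_only_permutes_memberships(self):
        matrix, assignment = hz.sample_footfall_matrix(strong_two_archetype_scenario())
        part = hz.delineate_hazs(standardize_rows(matrix), matrix, 2, 8)
        # the ranked labels and the planted assignment induce the same partition
        assert adjusted_rand_score(assignment.loc[part.labels.index], part.labels) == 1.0

    def test_deterministic_across_runs(self):
        matrix, _ = hz.sample_footfall_matrix(four_archetype_scenario())
        std = standardize_rows(matrix)
        a = hz.delineate_hazs(std, matrix, 2, 10)
        b = hz.delineate_hazs(std, matrix, 2, 10)
        assert a.n == b.n and a.silhouette == b.silhouette
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_n_max_at_least_m_rejected(self):
        matrix, _ = hz.sample_footfall_matrix(strong_two_archetype_scenario())
        std = standardize_rows(matrix)
        with pytest.raises(ValueError):
            hz.delineate_hazs(std, matrix, 2, len(std.values))


class TestPerPhase:
    def test_nine_partitions_for_eight_phases(self):
        scenario = four_archetype_scenario()
        matrix, _ = hz.sample_footfall_matrix(scenario)
        parts = hz.delineate_per_phase(matrix, list(scenario.calendar), 2, 10)
        assert len(parts) == 9
        assert set(p.name for p in scenario.calendar) | {"all"} == set(parts)

    def test_zero_count_unit_excluded_only_in_its_phase(self, mini_calendar):
        rng = np.random.default_rng(8)
        counts = rng.integers(5, 30, size=(6, 14))
        counts[0, :7] = 0  # silent in phase "open" only
        dates = pd.date_range("2020-01-01", periods=14, freq="D")
        matrix = pd.DataFrame(
            counts, index=pd.Index([f"u{i}" for i in range(6)], name="unit_id"), columns=dates
        )
        parts = hz.delineate_per_phase(matrix, list(mini_calendar), 2, 3)
        assert parts["open"].labels["u0"] == SENTINEL_LABEL
        assert parts["closed"].labels["u0"] != SENTINEL_LABEL

    def test_short_phase_rejected(self, mini_calendar):
        import datetime as dt

        from hazsense.phases import RestrictionPhase

        matrix = matrix_from(np.random.default_rng(1).integers(1, 9, size=(5, 14)).tolist())
        one_day = RestrictionPhase("blip", dt.date(2020, 1, 3), dt.date(2020, 1, 3))
        with pytest.raises(ValueError):
            hz.delineate_per_phase(matrix, [one_day], 2, 3)

    def test_phase_degeneracy_reduces_selected_n(self, mini_calendar):
        """If two archetypes coincide within one phase, that phase needs fewer zones."""
        from hazsense.synth import ArchetypeSpec

        names = [p.name for p in mini_calendar]
        archs = (
            ArchetypeSpec("busy-weekday", 40, 1.6, 0.4, dict(zip(names, [1.0, 1.0]))),
            ArchetypeSpec("busy-weekend", 40, 0.4, 1.6, dict(zip(names, [1.0, 1.0]))),
            # identical to busy-weekday in phase "closed", distinct in "open"
            ArchetypeSpec("shifting", 40, 0.4, 1.6, dict(zip(names, [1.0, 4.0]))),
        )
        # within "closed" the weekday/weekend shapes are the only signal, so
        # "shifting" (a weekend shape there) merges with busy-weekend
        scenario = hz.SyntheticScenario(
            archetypes=archs,
            n_units={a.name: 12 for a in archs},
            n_users=10,
            calendar=mini_calendar,
            grid_rows=6,
            grid_cols=6,
            seed=21,
        )
        matrix, _ = hz.sample_footfall_matrix(scenario)
        parts = hz.delineate_per_phase(matrix, list(scenario.calendar), 2, 6)
        assert parts["closed"].n < parts["all"].n


def test_partition_round_trip(tmp_path):
    matrix, _ = hz.sample_footfall_matrix(strong_two_archetype_scenario())
    part = hz.delineate_hazs(standardize_rows(matrix), matrix, 2, 8)
    path = tmp_path / "partition.csv"
    hz.haz.write_partition(part, path)
    loaded = hz.haz.read_partition(path)
    assert loaded.n == part.n
    pd.testing.assert_series_equal(loaded.labels, part.labels, check_names=False)
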