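"""Grid alignment, design statistics, descriptives, ICC and within-person r."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emadsem import (align_to_grid, compute_design_stats, icc,
                     mean_within_person_correlation, person_level_descriptives,
                     suggest_delta)
from conftest import make_records


class TestAlignToGrid:
    def test_on_grid_times_map_one_to_one(self):
        rec = make_records([0, 0, 0], [0.0, 2.0, 4.0], na=[1, 2, 3])
        grid, s = align_to_grid(rec, 2.0, value_columns=("na",))
        assert list(grid["bin_index"]) == [0, 1, 2]
        assert s.n_inserted_missing == 0 and s.n_collisions == 0

    def test_half_up_rounding_inserts_skipped_bin(self):
        # 11.0/2 = 5.5 rounds half-up to 6, leaving bin 5 inserted missing
        rec = make_records([0] * 6, [0, 2.2, 4.4, 6.6, 8.8, 11.0], na=range(6))
        grid, s = align_to_grid(rec, 2.0, value_columns=("na",))
        got = grid.loc[grid["source_prompt_index"] >= 0, "bin_index"].tolist()
        assert got == [0, 1, 2, 3, 4, 6]
        assert s.n_inserted_missing == 1
        assert grid.loc[grid["bin_index"] == 5, "na"].isna().all()

    def test_collision_keeps_earlier_and_logs(self):
        rec = make_records([0, 0, 0], [0.0, 1.9, 2.1], na=[10, 20, 30])
        grid, s = align_to_grid(rec, 2.0, value_columns=("na",))
        assert s.n_collisions == 1
        assert grid.loc[grid["bin_index"] == 1, "na"].iloc[0] == 20  # earlier kept

    def test_collision_keep_later_policy(self):
        rec = make_records([0, 0, 0], [0.0, 1.9, 2.1], na=[10, 20, 30])
        grid, s = align_to_grid(rec, 2.0, value_columns=("na",),
                                collision_policy="keep_later")
        assert grid.loc[grid["bin_index"] == 1, "na"].iloc[0] == 30

    def test_negative_times_and_unsorted_rejected(self):
        with pytest.raises(ValueError):
            align_to_grid(make_records([0], [-1.0], na=[1]), 2.0, ("na",))
        bad = make_records([0, 0], [4.0, 2.0], na=[1, 2])
        with pytest.raises(ValueError):
            align_to_grid(bad, 2.0, ("na",))

    def test_never_invents_data(self, small_records):
        grid, s = align_to_grid(small_records, 2.0)
        n_obs = int(small_records["observed"].sum())
        assert int(grid["na"].notna().sum()) <= n_obs
        assert s.n_observed <= n_obs

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.3, 3.0), min_size=2, max_size=30))
    def test_gaps_preserve_observation_count_up_to_collisions(self, gaps):
        times = np.cumsum(np.asarray(gaps))
        rec = make_records([0] * len(times), times, na=np.arange(len(times)))
        grid, s = align_to_grid(rec, 2.0, value_columns=("na",))
        assert int(grid["na"].notna().sum()) == len(times) - s.n_collisions
        b = grid["bin_index"].to_numpy()
        assert (np.diff(b) == 1).all()  # consecutive, no duplicates


class TestDesignStats:
    def test_full_compliance(self):
        rec = make_records([0, 0, 1, 1], [0, 2, 0, 2], na=[1, 2, 3, 4])
        assert compute_design_stats(rec)["compliance"] == 1.0

    def test_median_gap_by_definition(self):
        rec = make_records([0] * 5, [0.0, 2.0, 4.2, 6.4, 10.8], na=range(5))
        stats = compute_design_stats(rec)
        # gaps {2.0, 2.2, 2.2, 4.4} -> median 2.2
        assert stats["median_gap_h"] == pytest.approx(2.2)

    def test_synthetic_compliance_within_binomial_bounds(self, default_dataset):
        records, truth = default_dataset
        stats = compute_design_stats(records)
        p = truth.design.compliance
        se = np.sqrt(p * (1 - p) / stats["n_scheduled"])
        assert abs(stats["compliance"] - p) < 3 * se

    def test_suggest_delta_recommends_two_hours(self, default_dataset):
        records, _ = default_dataset
        delta, median_gap = suggest_delta(records)
        assert delta == 2.0
        assert 1.9 < median_gap < 2.6

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            compute_design_stats(make_records([], [], na=[]))


class TestPersonDescriptives:
    def test_two_point_perfect_correlation(self):
        rec = make_records([0, 0, 1, 1], [0, 2, 0, 2],
                           na=[1, 1, 3, 3], pa=[2, 2, 6, 6])
        out = person_level_descriptives(rec, variables=("na", "pa"))
        assert out["correlations"].loc["na", "pa"] == pytest.approx(1.0)

    def test_constant_variable_flagged(self):
        rec = make_records([0, 0, 1, 1], [0, 2, 0, 2],
                           na=[5, 5, 5, 5], pa=[1, 2, 3, 4])
        with pytest.warns(UserWarning, match="zero between-person variance"):
            out = person_level_descriptives(rec, variables=("na", "pa"))
        assert "na" in out["zero_variance"]
        assert out["descriptives"].loc["na", "sd"] == 0

    def test_synthetic_sign_pattern(self, default_dataset):
        records, _ = default_dataset
        corr = person_level_descriptives(records)["correlations"]
        assert corr.loc["na", "si_dim"] > 0
        assert corr.loc["pa", "si_dim"] < 0
        assert corr.loc["na", "pa"] < 0


class TestIcc:
    def test_balanced_toy_matches_hand_anova(self):
        rec = make_records([0] * 4 + [1] * 4, list(range(4)) * 2,
                           na=[1, 1, 3, 3, 5, 5, 7, 7])
        out = icc(rec, "na")
        # hand ANOVA: grand=4; SSB=4*(2-4)^2+4*(6-4)^2=32, MSB=32
        # SSW=8 (each dev 1), MSW=8/6; n_bar=4
        msw = 8 / 6
        var_b = (32 - msw) / 4
        assert out["icc"] == pytest.approx(var_b / (var_b + msw), abs=1e-10)

    def test_no_within_variance_gives_one(self):
        rec = make_records([0, 0, 1, 1], [0, 2, 0, 2], na=[1, 1, 5, 5])
        assert icc(rec, "na")["icc"] == pytest.approx(1.0)

    def test_single_person_rejected(self):
        with pytest.raises(ValueError):
            icc(make_records([0, 0], [0, 2], na=[1, 2]), "na")

    def test_variance_ratio_target(self):
        # persons drawn with between:within variance 0.69:0.31
        rng = np.random.default_rng(0)
        P, n = 300, 60
        y = (rng.normal(0, np.sqrt(0.69), P)[:, None]
             + rng.normal(0, np.sqrt(0.31), (P, n)))
        rec = make_records(np.repeat(np.arange(P), n),
                           np.tile(np.arange(n) * 2.0, P), na=y.reshape(-1))
        assert icc(rec, "na")["icc"] == pytest.approx(0.69, abs=0.05)


class TestWithinPersonCorrelation:
    def test_identical_variables_give_unit_r(self):
        rec = make_records([0] * 5 + [1] * 5, list(range(5)) * 2,
                           na=np.arange(10, dtype=float))
        rec["pa"] = rec["na"]
        out = mean_within_person_correlation(rec, "na", "pa")
        assert out["mean_r"] == pytest.approx(1.0)
        assert out["n_contributing"] == 2

    def test_average_of_exact_person_correlations(self):
        # build persons with exact r in {0.5, 0.3, 0.7} via orthogonalization
        rng = np.random.default_rng(1)
        frames = []
        for pid, r in enumerate((0.5, 0.3, 0.7)):
            n = 40
            x = rng.standard_normal(n)
            e = rng.standard_normal(n)
            x = (x - x.mean()) / x.std()
            e = e - e.mean()
            e -= x * (x @ e) / (x @ x)
            e /= e.std()
            y = r * x + np.sqrt(1 - r ** 2) * e
            frames.append(make_records([pid] * n, np.arange(n) * 2.0, na=x, pa=y))
        rec = pd.concat(frames, ignore_index=True)
        out = mean_within_person_correlation(rec, "na", "pa")
        assert out["mean_r"] == pytest.approx(0.5, abs=1e-10)

    def test_zero_variance_persons_excluded(self):
        rec = make_records([0] * 4 + [1] * 4, list(range(4)) * 2,
                           na=[1, 2, 3, 4, 5, 5, 5, 5],
                           pa=[1, 2, 3, 4, 1, 2, 3, 4])
        out = mean_within_person_correlation(rec, "na", "pa")
        assert out["n_contributing"] == 1

    def test_no_contributors_rejected(self):
        rec = make_records([0, 0], [0, 2], na=[1, 2], pa=[3, 4])
        with pytest.raises(ValueError):
            mean_within_person_correlation(rec, "na", "pa")
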