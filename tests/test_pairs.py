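"""Selected-pairs procedure: presence rule, selection, mixed model, footprint."""

import numpy as np
import pandas as pd
import pytest

from emadsem import (fit_state_mixed_model, flag_si_presence, select_pairs,
                     selection_footprint)
from emadsem.pairs import PairSet
from conftest import make_records


def presence_records(times, presence, person=0, na=None, pa=None):
    """Records whose SI-presence flags equal the given pattern."""
    n = len(times)
    desire = [40.0 if p else 0.0 for p in presence]
    si_bin = [1.0 if p else 0.0 for p in presence]
    return make_records([person] * n, times, desire_die=desire, si_bin=si_bin,
                        na=na if na is not None else np.arange(n, dtype=float),
                        pa=pa if pa is not None else np.arange(n, dtype=float))


class TestPresenceRule:
    @pytest.mark.parametrize("desire,si,expected", [
        (40.0, 1.0, True),    # both components -> present
        (0.0, 1.0, False),    # zero desire
        (40.0, 0.0, False),   # binary not endorsed
        (np.nan, 1.0, False),  # missing component
        (40.0, np.nan, False),
    ])
    def test_conjunction(self, desire, si, expected):
        rec = make_records([0], [0.0], desire_die=[desire], si_bin=[si],
                           na=[1.0], pa=[1.0])
        assert flag_si_presence(rec).iloc[0] == expected


class TestSelectPairs:
    def test_no_presence_no_pairs(self):
        rec = presence_records([0, 2, 4], [0, 0, 0])
        assert select_pairs(rec).n_pairs == 0

    def test_printed_six_prompt_fixture(self):
        # presence {1,0,1,1,0,0} at times {0,2,4,7,9,14}:
        # pairs (0->2) and (7->9); (4->7) excluded because SI continues
        rec = presence_records([0, 2, 4, 7, 9, 14], [1, 0, 1, 1, 0, 0])
        ps = select_pairs(rec, max_gap_h=4.0)
        assert ps.n_pairs == 2
        assert sorted(zip(ps.pairs["time_during"], ps.pairs["time_after"])) == \
            [(0.0, 2.0), (7.0, 9.0)]
        assert ps.selection_log["n_continued_si"] == 1

    def test_gap_rule_excludes_slow_resolution(self):
        rec = presence_records([0, 4.5], [1, 0])
        ps = select_pairs(rec, max_gap_h=4.0)
        assert ps.n_pairs == 0
        assert ps.selection_log["n_gap_excluded"] == 1

    def test_unanswered_prompts_do_not_break_adjacency(self):
        rec = presence_records([0, 2, 4], [1, 0, 0])
        rec.loc[1, "observed"] = False
        ps = select_pairs(rec)
        # consecutive among observed prompts: 0 -> 4 with gap 4 qualifies
        assert ps.n_pairs == 1
        assert ps.pairs["gap_h"].iloc[0] == 4.0

    def test_every_pair_satisfies_all_filters_brute_force(self, default_dataset):
        records, _ = default_dataset
        ps = select_pairs(records)
        obs = records[records["observed"]].sort_values(["person_id", "time_h"])
        present = flag_si_presence(obs)
        for _, pr in ps.pairs.iterrows():
            grp = obs[obs["person_id"] == pr["person_id"]]
            i = grp.index[grp["time_h"] == pr["time_during"]][0]
            j = grp.index[grp["time_h"] == pr["time_after"]][0]
            assert present.loc[i] and not present.loc[j]
            assert pr["gap_h"] <= 4.0
            # adjacent in observed sequence
            pos = grp.index.get_indexer([i, j])
            assert pos[1] == pos[0] + 1

    def test_invariant_to_person_order(self, small_records):
        ps1 = select_pairs(small_records)
        shuffled = small_records.sample(frac=1.0, random_state=0).sort_values(
            ["person_id", "time_h"], ascending=[False, True])
        # regroup: select_pairs sorts internally
        ps2 = select_pairs(shuffled)
        assert ps1.n_pairs == ps2.n_pairs


def gls_oracle(long: pd.DataFrame, outcome: str, vp: float, ve: float, vr: float):
    """GLS estimate with known variance components (independent oracle)."""
    X = np.column_stack([np.ones(len(long)), long["state"].to_numpy(float)])
    y = long[outcome].to_numpy(float)
    n = len(long)
    V = np.zeros((n, n))
    part = long["person_id"].to_numpy()
    ev = long["event"].to_numpy()
    for i in range(n):
        for j in range(n):
            v = 0.0
            if part[i] == part[j]:
                v += vp
            if ev[i] == ev[j]:
                v += ve
            if i == j:
                v += vr
            V[i, j] = v
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    cov = np.linalg.inv(X.T @ Vinv @ X)
    return beta[1], np.sqrt(cov[1, 1])


class TestMixedModel:
    def make_pairset(self, n_pairs=24, n_persons=8, seed=0, shift=-5.0):
        rng = np.random.default_rng(seed)
        rows = []
        for e in range(n_pairs):
            pid = e % n_persons
            during = 40 + rng.normal(0, 6)
            after = during + shift + rng.normal(0, 4)
            rows.append({"person_id": pid, "event": e, "prompt_during": 0,
                         "prompt_after": 1, "time_during": 0.0, "time_after": 2.0,
                         "gap_h": 2.0, "na_during": during, "na_after": after,
                         "pa_during": during, "pa_after": after})
        return PairSet(pairs=pd.DataFrame(rows), selection_log={})

    def test_identical_during_after_gives_zero_contrast(self):
        ps = self.make_pairset(shift=0.0, seed=1)
        ps.pairs["na_after"] = ps.pairs["na_during"]
        fit = fit_state_mixed_model(ps, "na")
        assert fit.B == pytest.approx(0.0, abs=1e-8)

    def test_matches_paired_closed_form_without_clustering(self):
        ps = self.make_pairset(seed=2)
        fit = fit_state_mixed_model(ps, "na")
        diffs = ps.pairs["na_after"] - ps.pairs["na_during"]
        assert fit.B == pytest.approx(float(diffs.mean()), abs=0.3)
        assert fit.ci_lower < fit.B < fit.ci_upper
        assert fit.p < 0.01

    def test_reml_coefficient_matches_gls_at_fitted_components(self):
        ps = self.make_pairset(seed=3)
        fit = fit_state_mixed_model(ps, "na")
        long = ps.long_format("na")
        B, se = gls_oracle(long, "na", fit.var_participant, fit.var_event,
                           fit.var_residual)
        assert fit.B == pytest.approx(B, abs=1e-8)
        assert fit.se == pytest.approx(se, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        ps = self.make_pairset(n_pairs=1, n_persons=1)
        with pytest.raises(ValueError):
            fit_state_mixed_model(ps, "na")

    def test_missing_affect_drops_pair(self):
        ps = self.make_pairset(seed=4)
        ps.pairs.loc[0, "na_after"] = np.nan
        fit = fit_state_mixed_model(ps, "na")
        assert fit.n_pairs == ps.n_pairs - 1


class TestFootprint:
    def test_zero_pairs(self):
        rec = presence_records([0, 2], [0, 0])
        ps = select_pairs(rec)
        fp = selection_footprint(ps, rec)
        assert fp["fraction_observations"] == 0.0

    def test_arithmetic(self):
        # 2 pairs over 100 observations -> 4%
        times = np.arange(100) * 2.0
        presence = [0] * 100
        presence[10] = presence[50] = 1
        rec = presence_records(times, presence)
        ps = select_pairs(rec)
        fp = selection_footprint(ps, rec)
        assert ps.n_pairs == 2
        assert fp["fraction_observations"] == pytest.approx(0.04)

    def test_default_regime_same_order_as_observed_study(self, default_dataset):
        records, _ = default_dataset
        fp = selection_footprint(select_pairs(records), records)
        assert 0.005 < fp["fraction_observations"] < 0.10
        assert 0.2 < fp["fraction_participants"] < 0.8
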