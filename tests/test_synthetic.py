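"""Generator: schedule geometry, dynamics, measurement and determinism."""

import numpy as np
import pytest

from emadsem import GenDesign, GenParams, export_ground_truth, simulate_dataset
from emadsem.synthetic import (ConfigurationError, _coefs_to_lag_matrix,
                               draw_person_effects, simulate_latent_panel,
                               simulate_schedule, NA_ITEMS, PA_ITEMS, SI_ITEMS)


class TestSchedule:
    def test_protocol_maximum_prompts(self):
        times = simulate_schedule(GenDesign(n_persons=5))
        assert times.shape == (5, 147)

    def test_degenerate_design_hits_block_midpoint(self):
        d = GenDesign(n_persons=1, n_days=1, prompts_per_day=1,
                      wake_hour=8, sleep_hour=22, jitter_sd=0.0)
        times = simulate_schedule(d)
        assert times.shape == (1, 1)
        assert times[0, 0] == pytest.approx(15.0)  # midpoint of 8-22

    def test_same_day_gap_matches_block_width_without_jitter(self):
        # direct enumeration: zero jitter puts prompts at block centers
        d = GenDesign(n_persons=2, wake_hour=9, sleep_hour=23, jitter_sd=0.0)
        times = simulate_schedule(d)
        gaps = np.diff(times[0])
        same_day = gaps[gaps < 12]
        assert np.allclose(same_day, (23 - 9) / 7)
        assert np.median(same_day) == pytest.approx(2.0)

    def test_times_strictly_increasing_within_person(self):
        times = simulate_schedule(GenDesign(n_persons=8, jitter_sd=1.5, seed=2))
        assert (np.diff(times, axis=1) > 0).all()

    @pytest.mark.parametrize("bad", [
        dict(prompts_per_day=0), dict(compliance=0.0), dict(compliance=1.2),
        dict(wake_hour=23, sleep_hour=9), dict(jitter_sd=-1.0),
    ])
    def test_invalid_designs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            GenDesign(**bad)


class TestLatentDynamics:
    def test_innovation_scaling_matches_ar1_closed_form(self):
        # univariate AR(1): unit stationary variance requires sigma^2 = 1 - phi^2
        p = GenParams.null(phi=(0.4, 0.0, 0.0))
        sig = p.innovation_cov()
        assert sig[0, 0] == pytest.approx(1 - 0.4 ** 2, abs=1e-10)
        assert sig[1, 1] == pytest.approx(1.0, abs=1e-10)

    def test_white_noise_has_no_autocorrelation(self):
        p = GenParams.null(phi=(0.0, 0.0, 0.0), coef_sd=(0.0,) * 10,
                           delta_days=(0.0, 0.0, 0.0))
        rng = np.random.default_rng(0)
        sched = np.arange(10000)[None, :] * 2.0
        coefs = np.tile(p.coef_mean(), (1, 1))
        s, _, _ = simulate_latent_panel(p, sched, coefs, rng)
        for k in range(3):
            x = s[0, :, k]
            r = np.corrcoef(x[:-1], x[1:])[0, 1]
            assert abs(r) < 0.03

    def test_stationary_variance_near_one_for_ar(self):
        p = GenParams.null(phi=(0.4, 0.0, 0.0), coef_sd=(0.0,) * 10,
                           delta_days=(0.0, 0.0, 0.0))
        rng = np.random.default_rng(1)
        sched = np.arange(20000)[None, :] * 2.0
        s, _, _ = simulate_latent_panel(p, sched, np.tile(p.coef_mean(), (1, 1)), rng)
        assert np.var(s[0, :, 0]) == pytest.approx(1.0, abs=0.05)

    def test_cross_correlations_positive_both_directions_at_default_truth(self):
        # maintenance regime: NA(t-1)->SI and SI(t-1)->NA lag correlations positive
        p = GenParams()
        rng = np.random.default_rng(3)
        sched = np.arange(8000)[None, :] * 2.0
        s, _, _ = simulate_latent_panel(p, sched, np.tile(p.coef_mean(), (1, 1)), rng)
        na, si = s[0, :, 0], s[0, :, 2]
        assert np.corrcoef(na[:-1], si[1:])[0, 1] > 0
        assert np.corrcoef(si[:-1], na[1:])[0, 1] > 0

    def test_person_effects_stationary_and_nearly_unbiased(self):
        p = GenParams()
        rng = np.random.default_rng(5)
        mu, coefs = draw_person_effects(p, 10000, rng)
        A = _coefs_to_lag_matrix(coefs)
        radius = np.max(np.abs(np.linalg.eigvals(A)), axis=1)
        assert (radius < 1.0).all()
        mc_se = p.coef_sd[0] / np.sqrt(10000)
        assert abs(coefs[:, 0].mean() - p.phi[0]) < 0.005 + 3 * mc_se


class TestRenderedRecords:
    def test_full_compliance_observes_every_prompt(self):
        d = GenDesign(n_persons=4, n_days=3, compliance=1.0, seed=1)
        records, _ = simulate_dataset(d, GenParams())
        assert records["observed"].all()
        assert records["na"].notna().all()

    def test_observed_count_within_binomial_bounds(self, default_dataset):
        records, truth = default_dataset
        n = len(records)
        p = truth.design.compliance
        sd = np.sqrt(n * p * (1 - p))
        assert abs(records["observed"].sum() - n * p) < 3 * sd

    def test_composites_are_item_means_with_reversal(self, small_records):
        obs = small_records[small_records.observed]
        na = obs[list(NA_ITEMS)].mean(axis=1)
        pa = obs[list(PA_ITEMS)].mean(axis=1)
        si = np.column_stack([100 - obs["wish_live"], obs["wish_die"],
                              obs["desire_die"]]).mean(axis=1)
        assert np.allclose(na, obs["na"]) and np.allclose(pa, obs["pa"])
        assert np.allclose(si, obs["si_dim"])

    def test_responses_within_scale_bounds(self, small_records):
        obs = small_records[small_records.observed]
        for col in NA_ITEMS + PA_ITEMS + SI_ITEMS + ("na", "pa", "si_dim"):
            assert obs[col].between(0, 100).all()

    def test_si_bin_missing_iff_unanswered(self, small_records):
        assert small_records.loc[~small_records.observed, "si_bin"].isna().all()
        assert small_records.loc[small_records.observed, "si_bin"].isin([0.0, 1.0]).all()


class TestDeterminismAndTruth:
    def test_identical_seed_identical_output(self):
        d = GenDesign(n_persons=10, n_days=4, seed=9)
        r1, t1 = simulate_dataset(d, GenParams())
        r2, t2 = simulate_dataset(d, GenParams())
        assert r1.equals(r2)
        assert t1.person.equals(t2.person)

    def test_seed_override_changes_output(self):
        d = GenDesign(n_persons=10, n_days=4, seed=9)
        r1, _ = simulate_dataset(d, GenParams())
        r3, _ = simulate_dataset(d, GenParams(), seed=10)
        assert not r1.equals(r3)

    def test_ground_truth_export(self, small_dataset):
        records, truth = small_dataset
        person, fixed = export_ground_truth(truth)
        assert len(person) == truth.design.n_persons
        # raw cross-lag = latent coefficient scaled by outcome/predictor SD ratio
        wsd = np.asarray(truth.params.within_sd)
        expected = person["lat_b_na_to_si"] * wsd[2] / wsd[0]
        assert np.allclose(person["raw_b_na_to_si"], expected)
        assert fixed["design"]["n_persons"] == truth.design.n_persons
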