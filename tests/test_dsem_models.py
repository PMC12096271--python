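"""Substantive model families: recovery, nulls, degenerate reductions."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from emadsem import (DsemSpec, Equation, GenDesign, GenParams, align_to_grid,
                     fit_dsem, fit_model_1a, fit_model_1b, fit_model_2a,
                     fit_moderation_3a, simulate_dataset)


def small_grid(params, n_persons=50, n_days=10, seed=13):
    records, _ = simulate_dataset(
        GenDesign(n_persons=n_persons, n_days=n_days, seed=seed), params)
    grid, _ = align_to_grid(records)
    return grid, records


def ci(table, name, std=True):
    row = table.loc[name]
    return (row["std_ci_lower"], row["std_ci_upper"]) if std else \
        (row["ci_lower"], row["ci_upper"])


class TestDimensionalModels:
    def test_null_cross_lags_not_detected(self):
        grid, _ = small_grid(GenParams.null(), seed=23)
        res = fit_model_1a(grid, n_iter=400, n_chains=1, seed=1)
        t = res.summary.table
        for name in ("si_dim~na.l1", "na~si_dim.l1"):
            lo, hi = ci(t, name)
            assert lo < 0 < hi, f"{name} CI {lo, hi} should cover 0"
            assert abs(t.loc[name, "std_mean"]) < 0.06

    def test_negative_pa_cross_lag_recovered(self):
        grid, _ = small_grid(GenParams(), n_persons=60, n_days=14, seed=29)
        res = fit_model_1b(grid, n_iter=400, n_chains=1, seed=2)
        lo, hi = ci(res.summary.table, "si_dim~pa.l1")
        assert hi < 0, f"PA->SI CI {lo, hi} should be negative"

    def test_raw_and_standardized_estimates_share_sign(self):
        grid, _ = small_grid(GenParams(), seed=31)
        res = fit_model_1a(grid, n_iter=300, n_chains=1, seed=3)
        t = res.summary.table
        strong = t[(t["mean"].abs() > 2 * t["sd"]) & t["std_mean"].notna()]
        assert (np.sign(strong["mean"]) == np.sign(strong["std_mean"])).all()

    def test_attempt_history_between_covariate(self):
        grid, _ = small_grid(GenParams(), seed=37)
        res = fit_model_1a(grid, attempt_covariate=True,
                           n_iter=300, n_chains=1, seed=4)
        row = res.summary.table.loc["mu(si_dim)~attempt"]
        assert np.isfinite(row["mean"]) and row["sd"] > 0

    def test_psr_shrinks_toward_one_with_more_iterations(self):
        grid, _ = small_grid(GenParams(), n_persons=30, n_days=7, seed=41)
        short = fit_model_1a(grid, n_iter=80, n_chains=2, seed=5)
        longer = fit_model_1a(grid, n_iter=600, n_chains=2, seed=5)
        coef_rows = [i for i in longer.summary.table.index if "~" in i]
        p_short = short.summary.table.loc[coef_rows, "psr"].max()
        p_long = longer.summary.table.loc[coef_rows, "psr"].max()
        assert p_long <= p_short + 0.02
        assert p_long < 1.1


class TestBinaryModels:
    def test_null_binary_cross_lag_covers_zero(self):
        grid, _ = small_grid(GenParams.null(), n_persons=60, seed=43)
        res = fit_model_2a(grid, n_iter=400, n_chains=1, seed=6)
        lo, hi = ci(res.summary.table, "si_bin~na.l1", std=False)
        assert lo < 0 < hi

    def test_endorsers_only_filter(self):
        grid, _ = small_grid(GenParams(), seed=47)
        full = fit_model_2a(grid, n_iter=60, n_chains=1, seed=7)
        sub = fit_model_2a(grid, endorsers_only=True, n_iter=60, n_chains=1, seed=7)
        n_endorse = int((grid.groupby("person_id")["si_bin"].max() > 0).sum())
        assert sub.notes["n_persons"] == n_endorse < full.notes["n_persons"]

    def test_probit_augmentation_recovers_known_slopes(self):
        """Data simulated exactly from the estimation model: probit slopes
        must come back within +/-15%."""
        rng = np.random.default_rng(11)
        P, T = 60, 90
        phi_na, alpha_mu, c_lag, c_na = 0.35, -1.0, 0.8, 0.5
        rows = []
        for p in range(P):
            alpha = alpha_mu + 0.3 * rng.standard_normal()
            w = np.zeros(T)
            for t in range(1, T):
                w[t] = phi_na * w[t - 1] + rng.standard_normal()
            si = np.zeros(T)
            for t in range(1, T):
                eta = alpha + c_lag * si[t - 1] + c_na * w[t - 1]
                si[t] = float(rng.random() < ndtr(eta))
            for t in range(T):
                rows.append((p, t, w[t] + 5.0, si[t]))
        lattice = pd.DataFrame(rows, columns=["person_id", "bin_index", "na", "si_bin"])
        lattice["day_c"] = 0.0
        spec = DsemSpec(
            equations=(
                Equation(outcome="si_bin", link="probit",
                         lag_predictors=("si_bin", "na"), days=False, random=False),
                Equation(outcome="na", lag_predictors=("na",), days=False,
                         random=False),
            ), n_chains=1, n_iter=600, seed=8)
        res = fit_dsem(lattice, spec)
        t = res.summary.table
        assert t.loc["si_bin~si_bin.l1", "mean"] == pytest.approx(c_lag, rel=0.15)
        assert t.loc["si_bin~na.l1", "mean"] == pytest.approx(c_na, rel=0.15)
        assert t.loc["na~na.l1", "mean"] == pytest.approx(phi_na, abs=0.05)


def simulate_moderation_data(inter, P=70, T=110, seed=17):
    """Affect AR(1) with binary SI shifting the level and moderating the AR."""
    rng = np.random.default_rng(seed)
    phi, beta, alpha_mu = 0.4, 0.8, -1.2
    rows = []
    for p in range(P):
        alpha = alpha_mu + 0.5 * rng.standard_normal()
        w = np.zeros(T)
        si = np.zeros(T)
        for t in range(1, T):
            si[t] = float(rng.random() < ndtr(alpha + 0.6 * si[t - 1]))
            w[t] = ((phi + inter * si[t]) * w[t - 1] + beta * si[t]
                    + rng.standard_normal())
        for t in range(T):
            rows.append((p, t, w[t] + 30.0, si[t]))
    lattice = pd.DataFrame(rows, columns=["person_id", "bin_index", "na", "si_bin"])
    lattice["day_c"] = 0.0
    return lattice


class TestModerationModels:
    def test_null_interaction_covers_zero(self):
        lattice = simulate_moderation_data(inter=0.0)
        res = fit_moderation_3a(lattice, n_iter=400, n_chains=1, seed=9)
        lo, hi = ci(res.summary.table, "na~si_bin:na.l1", std=False)
        assert lo < 0 < hi

    def test_negative_interaction_recovered(self):
        lattice = simulate_moderation_data(inter=-0.25, seed=19)
        res = fit_moderation_3a(lattice, n_iter=400, n_chains=1, seed=10)
        lo, hi = ci(res.summary.table, "na~si_bin:na.l1", std=False)
        assert hi < 0, f"interaction CI {lo, hi} should be negative"
        assert res.summary.table.loc["na~si_bin", "mean"] > 0

    def test_all_zero_binary_reduces_to_autoregression(self):
        grid, _ = small_grid(GenParams(), n_persons=30, n_days=7, seed=53)
        grid = grid.copy()
        grid.loc[grid["si_bin"].notna(), "si_bin"] = 0.0
        res3 = fit_moderation_3a(grid, n_iter=400, n_chains=1, seed=11)
        spec = DsemSpec(equations=(Equation(outcome="na", lag_predictors=("na",),
                                            random=True),),
                        n_chains=1, n_iter=400, seed=11)
        res1 = fit_dsem(grid, spec)
        phi3 = res3.summary.table.loc["na~na.l1", "mean"]
        phi1 = res1.summary.table.loc["na~na.l1", "mean"]
        assert phi3 == pytest.approx(phi1, abs=0.04)
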