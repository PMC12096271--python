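"""Fit the bidirectional SI <-> negative-affect dynamic model (Model 1a).

Two-level dynamic SEM on the 2-h lattice: dimensional SI and NA regress
on their own and each other's previous bin plus a day trend, with all
coefficients person-specific (random effects).  Estimation is Gibbs
sampling with latent mean centering and missing-bin augmentation.
"""

import emadsem as em

records, _ = em.simulate_dataset(seed=1)
grid, binning = em.align_to_grid(records, delta_h=2.0)
print(f"lattice: {binning.n_observed} observed bins, "
      f"{binning.n_inserted_missing} inserted missing, "
      f"{binning.n_collisions} collisions")

result = em.fit_model_1a(grid, n_iter=800, n_chains=2, seed=1)
cols = ["std_mean", "std_ci_lower", "std_ci_upper", "pct_pos", "pct_neg", "psr"]
rows = ["si_dim~si_dim.l1", "si_dim~na.l1", "si_dim~days",
        "na~na.l1", "na~si_dim.l1", "na~days"]
print(result.summary.table.loc[rows, cols].round(3).to_string())
print(f"converged: {result.converged} (max PSR {result.summary.max_psr:.3f})")

# Both cross-lags are positive with 95% credibility intervals excluding
# zero: elevated NA predicts higher SI two hours later AND elevated SI
# predicts higher NA -- mutual escalation, not relief.  %Pos/%Neg show
# how many individual persons carry a significant effect of each sign.
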