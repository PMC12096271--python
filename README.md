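# emadsem

Momentary suicide-ideation/affect dynamics from ecological momentary
assessment (EMA) data: a synthetic EMA generator plus the two analytic
strategies whose disagreement this package exists to demonstrate —
full-data Bayesian dynamic structural equation models (DSEM) and the
selected-pairs "affect relief" procedure.

## The problem

The affect-regulation account of suicide ideation (SI) holds that SI is
followed by decreasing negative affect (NA) or increasing positive
affect (PA), making SI self-reinforcing.  EMA studies testing it have
often restricted analysis to consecutive assessment pairs where SI is
present and then resolves, contrasting affect "during" vs "after".
That selection conditions on the outcome of the process: under a
*maintenance* regime — SI and NA mutually escalating —
regression to the mean still produces an apparent post-SI relief
effect in the selected pairs, while models using all observations
recover the true escalation.  `emadsem` makes this contrast fully
reproducible with no external data: it simulates item-level EMA with
known dynamics, fits both pipelines, and reports whether they diverge.

## The models

Within person, on a 2-h discrete-time lattice, deviations from latent
person means follow a VAR(1) with random coefficients:

    SI_t = phi_SI,i SI_{t-1} + beta_NA->SI,i NA_{t-1} + delta_SI,i day_t + e_SI,t
    NA_t = phi_NA,i NA_{t-1} + beta_SI->NA,i SI_{t-1} + delta_NA,i day_t + e_NA,t

with (phi_i, beta_i, delta_i) ~ N(gamma, Omega) across persons,
correlated innovations, latent mean centering, and Bayesian MCMC
(blocked Gibbs) estimation with missing-bin augmentation.  Binary
active SI ("since my last survey") is modeled with a probit link via
latent-response augmentation, fixed slopes and a random intercept;
moderation variants test whether SI in the interval changes the
carryover (autoregression) of affect.  The selected-pairs procedure
fits a three-level mixed model (responses in events in participants)
of affect on event state (during = 0, after = 1) by REML.

## Worked example

```python
import emadsem as em

records, truth = em.simulate_dataset(seed=1)         # 140 persons x 21 days
grid, _ = em.align_to_grid(records, delta_h=2.0)     # 2-h lattice
fit = em.fit_model_1a(grid, n_iter=800, n_chains=2, seed=1)
print(fit.summary.table.loc[["na~si_dim.l1", "si_dim~na.l1"],
                            ["std_mean", "std_ci_lower", "std_ci_upper"]])

pairs = em.select_pairs(records, max_gap_h=4.0)
na = em.fit_state_mixed_model(pairs, "na")
print(na.B, na.se)
```

prints (abbreviated; see `examples/03_bidirectional_dsem.py` and
`examples/04_pairs_replication.py` for the full scripts):

```
              std_mean  std_ci_lower  std_ci_upper
na~si_dim.l1     0.063         0.046         0.081
si_dim~na.l1     0.175         0.159         0.191
-1.99 0.64
```

Both DSEM cross-lags are positive with 95% credibility intervals
excluding zero — elevated SI predicts *higher* NA two hours later and
vice versa — while the during/after contrast on the same dataset shows
NA dropping by about 2 scale points after SI resolves (an apparent
relief effect, p = 0.002).  `em.run_divergence_experiment()` repeats this across
replicate datasets and reports how often the joint contradiction
appears.

The command line mirrors the library
(`emadsem simulate | descriptives | reliability | fit-dsem | fit-pairs |
divergence | pipeline`), and `examples/` contains one narrative script
per capability.

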