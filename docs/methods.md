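# Methods

`emadsem` studies a methodological question in suicide research: does
momentary suicide ideation (SI) appear to *relieve* affective distress or
to *escalate* it — and how much of the answer is an artifact of the
analysis strategy?  The package pairs a synthetic ecological momentary
assessment (EMA) generator with two analytic pipelines run on the same
data: full-data two-level dynamic structural equation models (DSEM) and
the selected-pairs during/after-SI contrast used in earlier studies.

## The generative model

**Design.** Each of `n_persons` (default 140) receives
`prompts_per_day` (7) prompts on each of `n_days` (21), one per equal
block of the waking day (09:00–23:00), at the block center plus
Gaussian jitter (SD 0.4 h, clipped inside the block).  Each prompt is
answered independently with probability `compliance` (0.87).  These
defaults give 147 scheduled prompts per person and a median
inter-prompt gap of ≈2.2 h.

**Within-person dynamics.**  Standardized latent deviations
`s_t = (NA, PA, SI)` live on an exact 2-h lattice and follow a
person-specific VAR(1)

    s_t = A_i s_{t-1} + delta_i * day_c(t) + e_t,     e_t ~ N(0, Sigma_e)

with coupling NA↔SI and PA↔SI (no direct NA↔PA lags).  Fixed
coefficients default to the maintenance regime — AR (0.413, 0.398,
0.235), cross-lags NA→SI 0.143, SI→NA 0.075, PA→SI −0.142, SI→PA
−0.057 — with person deviations drawn from a diagonal covariance
(AR SDs 0.10–0.12, cross-lag SDs 0.08) and rejected until the lag
matrix has spectral radius < 0.97 (max 1000 retries).  Innovations are
correlated (NA–SI +0.40, PA–SI −0.30, NA–PA −0.35) and scaled so each
series has unit stationary variance at the fixed coefficients, which
makes the latent coefficients directly interpretable as within-person
standardized effects.  The day trend sits *inside* the recursion so
the generator's `delta` is exactly the estimand of the estimator's
"days" regression coefficient.  Burn-in of 50 steps is discarded.

**Observation layer.**  Person means are multivariate normal (means
34.8/39.7/17.6; SDs 14/13/10; correlations from the between-person
structure: NA–SI +0.59, PA–SI −0.46, NA–PA −0.27).  Composites are
`mu_i + within_sd * s_t` on the 0–100 scale.  Item responses are the
composite plus uniqueness noise *centered across the items of a
prompt*, so the stored composite equals the item mean exactly and
follows the VAR without measurement attenuation; the uniqueness SDs
(13.7/12.85/6.03) set the within-person reliabilities to ω ≈
0.74/0.80/0.73 through θ = m·V·(1−ω).  Items (and hence composites)
are clipped to [0, 100].  The between-person SDs are deliberately
somewhat tighter than a fully literal read of observed person-mean
spreads would suggest: they preserve the ICC targets (0.62/0.45/0.69)
while keeping floor effects modest (≈5% of SI observations at the
floor), so the composite dynamics stay essentially linear and the
VAR coefficients remain the estimand.

**Binary active SI.**  The retrospective item covering the interval
since the previous answered prompt follows a probit:

    P(SI_bin = 1) = Phi(tau_b + lambda_mu * z_i + lambda_b * max_s + phi_b * prev)

with `z_i` the standardized person SI mean, `max_s` the maximum latent
SI deviation over the lattice bins since the previous answered prompt
(max, not mean: the item asks whether active SI occurred at all), and
`prev` the previous report.  Defaults (−3.5, 1.15, 0.9, 0.5) were
calibrated by simulation to an occasion rate of ≈3.5% and an endorser
fraction of ≈58%; the person-level term is essential — a homogeneous
3.5% rate would make virtually everyone an endorser across ~128
answered prompts.  A person-level lifetime-attempt indicator is drawn
from a probit on `z_i` (prevalence ≈37%, r with the SI mean ≈0.15).

**What the generator does not emulate.**  No sleep/wake or weekday
covariates, no reactivity to assessment, no item-level missingness
within an answered prompt, no heavy-tailed or zero-inflated response
styles.  The average within-person correlation between dimensional and
binary SI is ≈0.2 here, lower than observed practice (~0.46): with a
4% base rate a point-biserial correlation is tightly bounded, and the
generator does not add shared occasion-level measurement artifacts
that would push it higher.  Passing tests therefore show that the
*estimators* behave correctly under the stated dynamics, not that real
EMA data satisfy those dynamics.

## Grid alignment

Prompts map to the 2-h lattice by nearest bin with half-up rounding;
skipped bins (overnight, unanswered prompts) are inserted as missing
occasions.  Two prompts in one bin is a collision: the default keeps
the earlier prompt (its report is closer to the bin's preceding
interval); `keep_later` is available because the reference behavior of
discrete-time alignment tools is not documented on this point.  The
suggested bin width is the median observed gap rounded to whole hours.

## Reliability

ICC uses the one-way random-effects ANOVA estimator with the standard
unbalanced `n_bar`; it is transparent and oracle-checkable, and agrees
with the variance-ratio definition exactly on balanced designs.
Within-person ω fits a single-factor model by ML directly to the
pooled person-mean-centered item covariance (L-BFGS on loadings and
log-uniquenesses, Heywood cases floored with a warning).  A full
two-level confirmatory factor model is not needed for the within-level
ω and is not implemented.

## The DSEM engine

A blocked Gibbs sampler estimates the two-level models:

1. *Latent mean centering*: person means of continuous outcomes are
   sampled as latent quantities; deviations are defined against the
   sampled mean.  Between level: means regress on optional person
   covariates (attempt history → SI mean) with an inverse-Wishart
   covariance.
2. *Person-specific coefficients* (random-effect models) are drawn from
   their joint conditional across equations given the between-level
   mean/covariance; the covariance is inverse-Wishart (dimension+1 df,
   identity scale).  Fixed-effect models pool one conditional-normal
   draw.
3. *Innovation covariance*: the continuous equations share a free
   innovation covariance (inverse-Wishart).  This matters: with ~half
   of lattice bins imputed, forcing a diagonal covariance pushes the
   contemporaneous NA–SI correlation into the cross-lags (biases of
   +0.03–0.04 were observed in development); with the free covariance
   the cross-lags are recovered to within ±0.01–0.02.
4. *Missing-data augmentation*: every missing lattice value is redrawn
   each sweep from its full conditional.  Because the system is
   first-order Markov, sites at even bins are conditionally independent
   given odd bins, so imputation runs as vectorized red-black
   (checkerboard) half-sweeps.  The first bin uses a stationary-variance
   prior `sigma^2 / (1 - phi^2)` (floored) in place of a nonexistent
   predecessor.
5. *Probit outcomes* (binary SI) use latent-response augmentation:
   truncated-normal draws given the observed report, a person-specific
   random intercept, and fixed slopes (the all-random binary models are
   too weakly identified, matching practice).  Missing binary bins are
   drawn by enumerating both states — probit orthant mass times the
   likelihood of every equation the value enters — then drawing the
   latent response on the realized side.
6. *Moderation models* add a binary-by-lagged-affect product to the
   affect equation (all affect-equation effects random).  An auxiliary
   probit equation for the binary series exists purely so missing SI
   bins have a coherent imputation model.

Priors are explicit: N(0, 1e6) for fixed effects and between means,
inverse-gamma(0.001, 0.001) for scalar variances, inverse-Wishart
(dim+1, identity) for covariance matrices.  Chains start from pooled
ridge-OLS pilots with chain-dependent jitter of 0.5 pilot-SD.
Defaults are 2 chains × 2,000 sweeps with 50% burn-in (a
`full_scale` option restores 50,000 × 2); convergence is summarized
by the classic Gelman–Rubin PSR per parameter, with PSR > 1.1 flagged
but never fatal.

**Standardization.**  Within-level standardized estimates are computed
per person per retained draw as raw coefficient × SD(predictor)/
SD(outcome), then averaged over persons (the convention used for
multilevel time-series reporting).  Pure VAR systems use model-implied
stationary SDs (a batched discrete-Lyapunov solve per person); systems
with binary or interaction regressors use empirical SDs of the
completed series, and probit outcomes use the latent-response
convention (residual variance 1).  %Pos/%Neg report the share of
persons whose person-specific 95% posterior interval excludes zero,
computed from the retained person-coefficient draws.

**Design choices worth flagging.**  Random coefficients, latent means
and the binary random intercept are modeled as independent blocks
rather than one joint covariance (the generator also draws them
independently).  Binary predictors enter as observed 0/1 values, not
latent-centered.  Random/fixed status is per equation, not per
coefficient.  Equation systems outside the six model families (more
than one probit outcome, random probit slopes, interactions in probit
equations) raise `NotImplementedError` rather than silently
approximating.

## Selected-pairs replication

SI presence at a prompt = nonzero desire-to-die rating AND binary
endorsement.  Pairs are adjacent *answered* prompts (unanswered
prompts carry no SI information) with presence then absence, ≤ 4 h
apart; runs of continued SI yield no pair until they resolve.  Each
pair is one "event"; the during/after contrast is a linear mixed model
with random intercepts for participant and event, fitted by REML
(statsmodels MixedLM) with Wald-z inference.  Pairs missing the
outcome on either member are dropped for that outcome.  Under the
maintenance regime the contrast is reliably negative for NA and
positive for PA — the regression-to-the-mean signature of selecting on
resolution — while the same data's DSEM cross-lags are positive; the
divergence experiment quantifies this across replicates, and an
affect-regulation regime (truth SI→NA < 0) shows the two methods
agreeing, i.e. the flip is regime-dependent, not mechanical.

## Problem sizes

Defaults are chosen for desk-scale reproducibility: recovery checks
run one full-size fit (140 persons, 2 chains × 2,000 sweeps, ~1–2 min)
plus a ten-replicate reduced-size coverage study (40 persons, 14
days); the divergence experiment runs 20 replicates at 400 sweeps and
one chain.  Larger MCMC settings change interval widths by little on
these data; the `full_scale` flag exists for users who want the
reference settings.

## Known limitations

- No continuous-time modeling; everything is discrete-time on the
  lattice, and alignment rounding is a stated convention rather than a
  reproduction of any particular software's internal rule.
- Probit standardization depends on the latent-variance convention;
  other conventions shift standardized (not raw) binary-model effects.
- The sampler's single-site (red-black) imputation mixes slowly if
  missing runs are very long (weeks); for the emulated design the
  longest runs are overnight (~5 bins).
- Cluster significance rates use empirical-Bayes posterior draws of
  person coefficients; software that integrates over the random-effect
  distribution differently will give somewhat different %Pos/%Neg.
- The ANOVA ICC applied to the raw 0/1 binary SI item is much smaller
  than a latent-scale (probit random-intercept) ICC for the same data
  — at a ~3% base rate the raw-scale within variance dominates.  The
  binary-model random-intercept variance `psi(alpha)/(psi(alpha)+1)`
  is the latent-scale analogue and lands far higher.
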