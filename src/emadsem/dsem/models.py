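"""Convenience builders for the six substantive model families.

* Models 1a/1b — bidirectional dimensional-SI models: dimensional SI and
  NA (or PA) as a two-variable VAR(1) with random autoregressive,
  cross-lagged and day-trend effects; optionally the latent SI mean is
  regressed on lifetime suicide-attempt history at the between level.
* Models 2a/2b — bidirectional binary-SI models: the retrospective
  binary SI report at t (covering the t-1 to t interval) is a probit
  outcome predicted by its own previous report, lagged affect and days;
  affect at t is predicted by its own lag, binary SI at t, and days.
  All regression parameters are fixed effects (the binary models'
  random-effect variants are too weakly identified); person differences
  enter through latent affect means and a random probit intercept.
* Models 3a/3b — moderation models: affect at t on its own lag, binary
  SI at t, their product (does SI in the interval dampen or amplify the
  carryover of affect?) and days, all random.  An auxiliary probit
  equation for binary SI supports imputation of missing SI bins.
"""

from __future__ import annotations

import pandas as pd

from .engine import DsemResult, fit_dsem
from .spec import DsemSpec, Equation

__all__ = [
    "model_1a", "model_1b", "model_2a", "model_2b", "model_3a", "model_3b",
    "fit_model_1a", "fit_model_1b", "fit_model_2a", "fit_model_2b",
    "fit_moderation_3a", "fit_moderation_3b",
]


def _dimensional_spec(affect: str, attempt_covariate: bool, **options) -> DsemSpec:
    eqs = (
        Equation(outcome="si_dim", lag_predictors=("si_dim", affect), random=True),
        Equation(outcome=affect, lag_predictors=(affect, "si_dim"), random=True),
    )
    cov = {"si_dim": ("attempt",)} if attempt_covariate else {}
    return DsemSpec(equations=eqs, between_covariates=cov, **options)


def _binary_spec(affect: str, **options) -> DsemSpec:
    eqs = (
        Equation(outcome="si_bin", link="probit",
                 lag_predictors=("si_bin", affect), random=False),
        Equation(outcome=affect, lag_predictors=(affect,),
                 con_predictors=("si_bin",), random=False),
    )
    return DsemSpec(equations=eqs, **options)


def _moderation_spec(affect: str, **options) -> DsemSpec:
    eqs = (
        Equation(outcome="si_bin", link="probit",
                 lag_predictors=("si_bin", affect), random=False),
        Equation(outcome=affect, lag_predictors=(affect,),
                 con_predictors=("si_bin",),
                 interactions=(("si_bin", affect),), random=True),
    )
    return DsemSpec(equations=eqs, **options)


def model_1a(attempt_covariate: bool = False, **options) -> DsemSpec:
    """Dimensional SI <-> negative affect, random effects."""
    return _dimensional_spec("na", attempt_covariate, **options)


def model_1b(attempt_covariate: bool = False, **options) -> DsemSpec:
    """Dimensional SI <-> positive affect, random effects."""
    return _dimensional_spec("pa", attempt_covariate, **options)


def model_2a(**options) -> DsemSpec:
    """Binary SI (probit) <-> negative affect, fixed effects."""
    return _binary_spec("na", **options)


def model_2b(**options) -> DsemSpec:
    """Binary SI (probit) <-> positive affect, fixed effects."""
    return _binary_spec("pa", **options)


def model_3a(**options) -> DsemSpec:
    """Binary SI moderating the carryover of negative affect, random effects."""
    return _moderation_spec("na", **options)


def model_3b(**options) -> DsemSpec:
    """Binary SI moderating the carryover of positive affect, random effects."""
    return _moderation_spec("pa", **options)


def _endorser_filter(lattice: pd.DataFrame) -> pd.DataFrame:
    endorsed = lattice.groupby("person_id")["si_bin"].max()
    keep = endorsed.index[endorsed > 0]
    return lattice[lattice["person_id"].isin(keep)]


def fit_model_1a(lattice: pd.DataFrame, attempt_covariate: bool = False,
                 **options) -> DsemResult:
    return fit_dsem(lattice, model_1a(attempt_covariate, **options))


def fit_model_1b(lattice: pd.DataFrame, attempt_covariate: bool = False,
                 **options) -> DsemResult:
    return fit_dsem(lattice, model_1b(attempt_covariate, **options))


def fit_model_2a(lattice: pd.DataFrame, endorsers_only: bool = False,
                 **options) -> DsemResult:
    """Endorsers-only reruns restrict to persons who reported binary SI at least once."""
    data = _endorser_filter(lattice) if endorsers_only else lattice
    return fit_dsem(data, model_2a(**options))


def fit_model_2b(lattice: pd.DataFrame, endorsers_only: bool = False,
                 **options) -> DsemResult:
    data = _endorser_filter(lattice) if endorsers_only else lattice
    return fit_dsem(data, model_2b(**options))


def fit_moderation_3a(lattice: pd.DataFrame, endorsers_only: bool = False,
                      **options) -> DsemResult:
    data = _endorser_filter(lattice) if endorsers_only else lattice
    return fit_dsem(data, model_3a(**options))


def fit_moderation_3b(lattice: pd.DataFrame, endorsers_only: bool = False,
                      **options) -> DsemResult:
    data = _endorser_filter(lattice) if endorsers_only else lattice
    return fit_dsem(data, model_3b(**options))
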