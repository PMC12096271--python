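"""Model specifications for the two-level dynamic SEM engine.

A :class:`DsemSpec` lists the within-person equations (outcome, link,
lagged/contemporaneous/interaction predictors, random or fixed
coefficients), the between-level covariates on latent means, explicit
priors and the MCMC settings.  Convenience builders for the six
substantive model families live in :mod:`emadsem.dsem.models`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class Priors:
    """Noninformative defaults, approximating common Bayesian-SEM software.

    Fixed regression coefficients and between-level means: normal with
    mean 0 and variance ``fixed_var``.  Residual variances:
    inverse-gamma(``resid_a``, ``resid_b``) (a proper stand-in for the
    improper IG(-1, 0) default).  Random-effect and between-level
    covariance matrices: inverse-Wishart with dimension + 1 degrees of
    freedom and identity scale.
    """

    fixed_var: float = 1e6
    resid_a: float = 0.001
    resid_b: float = 0.001
    iw_scale: float = 1.0


@dataclass(frozen=True)
class Equation:
    """One within-person equation.

    ``lag_predictors`` are variables entering at t-1;
    ``con_predictors`` enter contemporaneously (used for the binary SI
    report covering the (t-1, t] interval); ``interactions`` are
    (contemporaneous binary, lagged variable) products.  ``days``
    appends the person-centered day covariate.  ``random`` makes every
    regression coefficient of the equation person-specific.
    """

    outcome: str
    link: str = "identity"                      # "identity" | "probit"
    lag_predictors: tuple = ()
    con_predictors: tuple = ()
    interactions: tuple = ()                    # of (con binary, lagged var)
    days: bool = True
    random: bool = True

    def __post_init__(self) -> None:
        if self.link not in ("identity", "probit"):
            raise ValueError(f"unknown link: {self.link!r}")

    @property
    def term_names(self) -> tuple:
        names = [f"{v}.l1" for v in self.lag_predictors]
        names += list(self.con_predictors)
        names += [f"{b}:{v}.l1" for b, v in self.interactions]
        if self.days:
            names.append("days")
        return tuple(names)

    @property
    def n_terms(self) -> int:
        return len(self.term_names)


@dataclass(frozen=True)
class DsemSpec:
    """Full model definition plus sampler settings.

    ``between_covariates`` maps a continuous outcome to person-level
    columns whose coefficients enter the regression of that outcome's
    latent mean (e.g. suicide-attempt history on the SI mean).
    ``latent_means`` can be disabled for raw-deviation submodels (used
    by oracle checks); ``known_resid_sd`` fixes residual SDs instead of
    sampling them.
    """

    equations: tuple
    between_covariates: dict = field(default_factory=dict)
    latent_means: bool = True
    n_chains: int = 2
    n_iter: int = 2000
    burn_frac: float = 0.5
    thin: int = 1
    seed: int = 0
    psr_threshold: float = 1.1
    known_resid_sd: dict = field(default_factory=dict)
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self) -> None:
        if not self.equations:
            raise ValueError("at least one equation is required")
        outs = [e.outcome for e in self.equations]
        if len(set(outs)) != len(outs):
            raise ValueError("duplicate outcome equations")
        known = set(outs)
        for eq in self.equations:
            for v in eq.lag_predictors + eq.con_predictors:
                if v not in known:
                    raise ValueError(f"predictor {v!r} is not a declared outcome")
            for b, v in eq.interactions:
                if b not in known or v not in known:
                    raise ValueError(f"interaction ({b}, {v}) references undeclared variables")
        if not (0.0 <= self.burn_frac < 1.0):
            raise ValueError("burn_frac must be in [0, 1)")
        if self.n_iter < 2 or self.thin < 1:
            raise ValueError("n_iter must be >= 2 and thin >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def outcomes(self) -> tuple:
        return tuple(e.outcome for e in self.equations)

    def with_options(self, **changes) -> "DsemSpec":
        return replace(self, **changes)
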