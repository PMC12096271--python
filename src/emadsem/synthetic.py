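"""Synthetic ecological momentary assessment (EMA) generator.

Emulates a 21-day EMA protocol in which participants receive seven
semi-random prompts per day and rate momentary negative affect (NA),
positive affect (PA) and dimensional suicide ideation (SI) on 0-100
scales, plus a retrospective binary active-SI item covering the interval
since the previous answered prompt.

The within-person dynamics live on an equally spaced 2-h lattice: each
person's standardized latent deviations follow a VAR(1) with
person-specific autoregressive and cross-lagged coefficients (drawn
around fixed population values, truncated to the stationary region) and
a linear day trend inside the recursion.  Observed prompts sample the
nearest lattice state, so the generator's truth coincides with the
discrete-time estimator's model.

Item responses are built around the composite: item = composite +
centered residual, so the stored composite (the mean of the items)
follows the specified VAR exactly while the items carry the uniqueness
noise that determines within-person reliability (omega).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov
from scipy.special import ndtr

__all__ = [
    "GenDesign",
    "GenParams",
    "GroundTruth",
    "NA_ITEMS",
    "PA_ITEMS",
    "SI_ITEMS",
    "simulate_schedule",
    "simulate_latent_panel",
    "render_observations",
    "export_ground_truth",
    "simulate_dataset",
]

#: composite order used throughout: negative affect, positive affect, dimensional SI
VARIABLES = ("na", "pa", "si_dim")

NA_ITEMS = ("sad", "depressed", "anxious", "angry", "tired", "ashamed")
PA_ITEMS = ("happy", "excited", "relaxed", "satisfied")
#: wish_live is stored pre-reversal (high = wish to live); reverse-scored when scoring
SI_ITEMS = ("wish_live", "wish_die", "desire_die")

#: person-specific coefficient names, latent (standardized) scale, equation-major order
COEF_NAMES = (
    "phi_na", "b_si_to_na", "d_na",
    "phi_pa", "b_si_to_pa", "d_pa",
    "phi_si", "b_na_to_si", "b_pa_to_si", "d_si",
)

_STATIONARY_RADIUS = 0.97
_MAX_COEF_RETRIES = 1000
_BURN_IN = 50


class ConfigurationError(ValueError):
    """Raised for generator designs/parameters that cannot be realized."""


@dataclass(frozen=True)
class GenDesign:
    """Sampling design of the EMA protocol.

    Seven prompts/day over 21 days gives the protocol maximum of 147
    scheduled prompts per person.  Each waking day is partitioned into
    ``prompts_per_day`` equal blocks between ``wake_hour`` and
    ``sleep_hour``; one prompt lands at the block center plus Gaussian
    jitter (SD ``jitter_sd`` hours), clipped inside its block.
    """

    n_persons: int = 140
    n_days: int = 21
    prompts_per_day: int = 7
    wake_hour: float = 9.0
    sleep_hour: float = 23.0
    compliance: float = 0.87
    jitter_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prompts_per_day < 1:
            raise ConfigurationError("prompts_per_day must be >= 1")
        if not (0.0 < self.compliance <= 1.0):
            raise ConfigurationError("compliance must be in (0, 1]")
        if not self.wake_hour < self.sleep_hour:
            raise ConfigurationError("wake_hour must precede sleep_hour")
        if self.n_persons < 1 or self.n_days < 1:
            raise ConfigurationError("n_persons and n_days must be >= 1")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")

    @property
    def n_prompts(self) -> int:
        return self.n_days * self.prompts_per_day

    @property
    def block_width(self) -> float:
        return (self.sleep_hour - self.wake_hour) / self.prompts_per_day


def _default_between_corr() -> tuple:
    # person-mean correlations: NA-PA negative, NA-SI positive, PA-SI negative
    return (
        (1.00, -0.27, 0.59),
        (-0.27, 1.00, -0.46),
        (0.59, -0.46, 1.00),
    )


def _default_innovation_corr() -> tuple:
    return (
        (1.00, -0.35, 0.40),
        (-0.35, 1.00, -0.30),
        (0.40, -0.30, 1.00),
    )


def _default_coef_sd() -> tuple:
    # heterogeneity SDs for (phi_na, b_si_to_na, d_na, phi_pa, b_si_to_pa, d_pa,
    #                        phi_si, b_na_to_si, b_pa_to_si, d_si), latent scale
    return (0.12, 0.08, 0.00825, 0.12, 0.08, 0.00825, 0.10, 0.08, 0.08, 0.00825)


@dataclass(frozen=True)
class GenParams:
    """Full generative specification for the latent dynamics and measurement.

    Fixed within-person coefficients are on the standardized latent
    scale (innovations scaled so each series has unit stationary SD at
    the population coefficients), which makes them directly comparable
    to within-level standardized estimates.  ``within_sd`` converts
    latent deviations to 0-100 scale points; ``between_sd`` scales the
    person means.  Day-trend slopes ``delta_days`` are per day of study
    on the latent scale.
    """

    # between level
    grand_means: tuple = (34.8, 39.7, 17.6)           # NA, PA, SI scale points
    between_sd: tuple = (14.0, 13.0, 10.0)
    between_corr: tuple = field(default_factory=_default_between_corr)
    # within level, fixed coefficients (latent scale)
    phi: tuple = (0.413, 0.398, 0.235)                # AR for NA, PA, SI
    b_si_to_na: float = 0.075
    b_si_to_pa: float = -0.057
    b_na_to_si: float = 0.143
    b_pa_to_si: float = -0.142
    delta_days: tuple = (-0.0038, -0.00083, -0.00512)  # per-day trend, latent scale
    coef_sd: tuple = field(default_factory=_default_coef_sd)
    innovation_corr: tuple = field(default_factory=_default_innovation_corr)
    within_sd: tuple = (10.96, 14.37, 6.70)           # scale points per latent SD
    # binary active-SI probit link
    tau_b: float = -3.5                               # intercept
    lambda_b: float = 0.9                             # slope on max latent SI deviation
    lambda_mu_b: float = 1.15                         # slope on standardized person SI mean
    phi_b: float = 0.5                                # weight on previous answered binary report
    # item measurement: uniqueness SDs (scale points) per composite
    item_uniq_sd: tuple = (13.7, 12.85, 6.03)
    # person-level lifetime-attempt covariate (probit on standardized SI mean)
    attempt_a0: float = -0.344
    attempt_a1: float = 0.3
    # analysis lattice the latent process lives on
    grid_delta_h: float = 2.0

    def __post_init__(self) -> None:
        for name in ("between_corr", "innovation_corr"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (3, 3) or not np.allclose(m, m.T):
                raise ConfigurationError(f"{name} must be a symmetric 3x3 matrix")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ConfigurationError(f"{name} must be positive semi-definite")
        if np.any(np.asarray(self.within_sd) <= 0):
            raise ConfigurationError("within_sd entries must be positive")
        if np.any(np.asarray(self.coef_sd) < 0):
            raise ConfigurationError("coef_sd entries must be non-negative")
        A = self.lag_matrix()
        if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
            raise ConfigurationError("fixed coefficients are not stationary")

    # -- convenience constructors for the regimes the experiments use ----------

    @classmethod
    def maintenance(cls, **overrides) -> "GenParams":
        """Default regime: mutually escalating SI and affect (Table-4-sign truth)."""
        return cls(**overrides)

    @classmethod
    def null(cls, **overrides) -> "GenParams":
        """All cross-effects zero and binary SI independent of affect/latent SI."""
        base = dict(
            b_si_to_na=0.0, b_si_to_pa=0.0, b_na_to_si=0.0, b_pa_to_si=0.0,
            innovation_corr=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
            lambda_b=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def affect_regulation(cls, **overrides) -> "GenParams":
        """Relief regime: SI is followed by decreasing NA and increasing PA."""
        base = dict(b_si_to_na=-0.12, b_si_to_pa=0.10)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def bivariate_na_si(cls, **overrides) -> "GenParams":
        """NA-SI regime with PA decoupled (for clean two-variable recovery)."""
        base = dict(
            b_pa_to_si=0.0, b_si_to_pa=0.0,
            innovation_corr=((1.0, 0.0, 0.40), (0.0, 1.0, 0.0), (0.40, 0.0, 1.0)),
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "GenParams":
        return dataclasses.replace(self, **changes)

    # -- derived matrices ------------------------------------------------------

    def lag_matrix(self) -> np.ndarray:
        """Population 3x3 VAR(1) coefficient matrix (rows = NA, PA, SI equations)."""
        return np.array([
            [self.phi[0], 0.0, self.b_si_to_na],
            [0.0, self.phi[1], self.b_si_to_pa],
            [self.b_na_to_si, self.b_pa_to_si, self.phi[2]],
        ])

    def coef_mean(self) -> np.ndarray:
        """Fixed coefficient vector in COEF_NAMES order (latent scale)."""
        return np.array([
            self.phi[0], self.b_si_to_na, self.delta_days[0],
            self.phi[1], self.b_si_to_pa, self.delta_days[1],
            self.phi[2], self.b_na_to_si, self.b_pa_to_si, self.delta_days[2],
        ])

    def between_cov(self) -> np.ndarray:
        sd = np.asarray(self.between_sd)
        return np.asarray(self.between_corr) * np.outer(sd, sd)

    def innovation_cov(self) -> np.ndarray:
        """Innovation covariance scaled so stationary variances are 1 at the fixed A."""
        A = self.lag_matrix()
        R = np.asarray(self.innovation_corr, dtype=float)
        d = np.ones(3)
        for _ in range(200):
            sig = R * np.outer(d, d)
            V = solve_discrete_lyapunov(A, sig)
            adj = 1.0 / np.sqrt(np.diag(V))
            d = d * adj
            if np.max(np.abs(adj - 1.0)) < 1e-12:
                break
        return R * np.outer(d, d)


def _coefs_to_lag_matrix(coefs: np.ndarray) -> np.ndarray:
    """Person coefficient vectors (P, 10) -> lag matrices (P, 3, 3)."""
    P = coefs.shape[0]
    A = np.zeros((P, 3, 3))
    A[:, 0, 0] = coefs[:, 0]
    A[:, 0, 2] = coefs[:, 1]
    A[:, 1, 1] = coefs[:, 3]
    A[:, 1, 2] = coefs[:, 4]
    A[:, 2, 2] = coefs[:, 6]
    A[:, 2, 0] = coefs[:, 7]
    A[:, 2, 1] = coefs[:, 8]
    return A


@dataclass
class GroundTruth:
    """Realized person-level parameters plus the fixed generative parameters."""

    person: pd.DataFrame       # one row per person: means, coefficients, attempt, binary intercept
    params: GenParams
    design: GenDesign


def simulate_schedule(design: GenDesign, rng: np.random.Generator | None = None) -> np.ndarray:
    """Scheduled prompt times, hours since study start, shape (n_persons, n_prompts).

    Each day is split into equal blocks between wake and sleep; the
    prompt sits at the block center plus clipped Gaussian jitter, so
    times are strictly increasing within person by construction.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    width = design.block_width
    if width <= 0:
        raise ConfigurationError("non-positive prompt block width")
    P, D, K = design.n_persons, design.n_days, design.prompts_per_day
    centers = design.wake_hour + (np.arange(K) + 0.5) * width      # within-day hours
    jitter = rng.normal(0.0, design.jitter_sd, size=(P, D, K)) if design.jitter_sd > 0 \
        else np.zeros((P, D, K))
    margin = min(0.05, 0.25 * width)
    # clip each prompt inside its own block
    lo = design.wake_hour + np.arange(K) * width + margin
    hi = design.wake_hour + (np.arange(K) + 1) * width - margin
    offsets = np.clip(centers + jitter, lo, hi)
    times = (np.arange(D) * 24.0)[None, :, None] + offsets
    return times.reshape(P, D * K)


def draw_person_effects(params: GenParams, n_persons: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw person means (P, 3) and coefficient vectors (P, 10).

    Coefficient deviations are rejected until the person's companion
    (lag) matrix has spectral radius < 0.97; after ``_MAX_COEF_RETRIES``
    failures an error is raised.
    """
    mu = rng.multivariate_normal(np.asarray(params.grand_means), params.between_cov(),
                                 size=n_persons, method="cholesky")
    mean = params.coef_mean()
    sd = np.asarray(params.coef_sd)
    coefs = np.empty((n_persons, len(mean)))
    pending = np.ones(n_persons, dtype=bool)
    for _ in range(_MAX_COEF_RETRIES):
        n = int(pending.sum())
        if n == 0:
            break
        draw = mean + rng.normal(size=(n, len(mean))) * sd
        A = _coefs_to_lag_matrix(draw)
        radius = np.max(np.abs(np.linalg.eigvals(A)), axis=1)
        ok = radius < _STATIONARY_RADIUS
        idx = np.flatnonzero(pending)
        coefs[idx[ok]] = draw[ok]
        pending[idx[ok]] = False
    else:
        raise ConfigurationError("could not draw stationary person coefficients")
    return mu, coefs


def simulate_latent_panel(params: GenParams, schedule: np.ndarray,
                          coefs: np.ndarray, rng: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterate the person-specific VAR(1) on the 2-h lattice spanning the schedule.

    Returns ``(s, bins, day_c)`` where ``s`` has shape (P, T, 3) holding
    standardized latent deviations on lattice bins ``bins`` (global bin
    indices, ``time = bin * grid_delta_h``), and ``day_c`` is the
    centered day covariate per bin.  A burn-in of 50 steps (without the
    day trend) is discarded.
    """
    delta = params.grid_delta_h
    b0 = int(np.floor(schedule.min() / delta + 0.5))
    b1 = int(np.floor(schedule.max() / delta + 0.5))
    bins = np.arange(b0, b1 + 1)
    T = len(bins)
    P = coefs.shape[0]
    A = _coefs_to_lag_matrix(coefs)
    sig = params.innovation_cov()
    L = np.linalg.cholesky(sig)
    deltas = coefs[:, [2, 5, 9]]                       # per-person day slopes
    day = bins * delta / 24.0
    day_c = day - day.mean()

    s = np.empty((P, T, 3))
    x = rng.standard_normal((P, 3)) @ L.T
    for _ in range(_BURN_IN):
        x = np.einsum("pij,pj->pi", A, x) + rng.standard_normal((P, 3)) @ L.T
    for t in range(T):
        x = (np.einsum("pij,pj->pi", A, x) + deltas * day_c[t]
             + rng.standard_normal((P, 3)) @ L.T)
        s[:, t] = x
    return s, bins, day_c


def _render_items(comp: np.ndarray, uniq_sd: float, n_items: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Item responses around a composite; residuals centered so mean(items) == comp."""
    eps = rng.normal(0.0, uniq_sd, size=comp.shape + (n_items,))
    eps -= eps.mean(axis=-1, keepdims=True)
    return comp[..., None] + eps


def render_observations(params: GenParams, design: GenDesign, schedule: np.ndarray,
                        s: np.ndarray, bins: np.ndarray, mu: np.ndarray,
                        rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Turn the latent panel into the long-format EMA record table.

    Returns the records (one row per scheduled prompt; unanswered
    prompts have missing responses) and the per-person binary-SI probit
    intercepts actually used (for the ground-truth export).
    """
    P, N = schedule.shape
    delta = params.grid_delta_h
    prompt_bins = np.floor(schedule / delta + 0.5).astype(int) - bins[0]
    observed = rng.random((P, N)) < design.compliance

    wsd = np.asarray(params.within_sd)
    comp = mu[:, None, :] + s[np.arange(P)[:, None], prompt_bins] * wsd  # (P, N, 3)

    # items (centered residuals), clipped to the response scale
    na_items = np.clip(_render_items(comp[..., 0], params.item_uniq_sd[0], len(NA_ITEMS), rng), 0, 100)
    pa_items = np.clip(_render_items(comp[..., 1], params.item_uniq_sd[1], len(PA_ITEMS), rng), 0, 100)
    si_items = np.clip(_render_items(comp[..., 2], params.item_uniq_sd[2], len(SI_ITEMS), rng), 0, 100)
    wish_live = 100.0 - si_items[..., 0]              # stored pre-reversal

    na = na_items.mean(axis=-1)
    pa = pa_items.mean(axis=-1)
    si_dim = si_items.mean(axis=-1)                   # == mean(100-wish_live, wish_die, desire)

    # binary active SI: probit on the max latent SI deviation since the previous
    # answered prompt, the standardized person SI mean, and the previous report
    z_mu = (mu[:, 2] - params.grand_means[2]) / params.between_sd[2]
    tau_person = params.tau_b + params.lambda_mu_b * z_mu
    si_bin = np.full((P, N), np.nan)
    for p in range(P):
        prev_bin = -1
        prev_rep = 0.0
        for j in range(N):
            if not observed[p, j]:
                continue
            b = prompt_bins[p, j]
            lo = max(prev_bin + 1, 0) if prev_bin >= 0 else max(b - 1, 0)
            peak = s[p, lo:b + 1, 2].max() if b >= lo else s[p, b, 2]
            prob = ndtr(tau_person[p] + params.lambda_b * peak + params.phi_b * prev_rep)
            rep = float(rng.random() < prob)
            si_bin[p, j] = rep
            prev_bin = b
            prev_rep = rep

    attempt = (rng.random(P) < ndtr(params.attempt_a0 + params.attempt_a1 * z_mu)).astype(int)

    person_id = np.repeat(np.arange(P), N)
    frame = {
        "person_id": person_id,
        "prompt_index": np.tile(np.arange(N), P),
        "time_h": schedule.reshape(-1),
        "day": (schedule.reshape(-1) // 24).astype(int),
        "observed": observed.reshape(-1),
    }
    obs = observed.reshape(-1)

    def masked(arr):
        out = arr.reshape(-1).astype(float).copy()
        out[~obs] = np.nan
        return out

    for i, name in enumerate(NA_ITEMS):
        frame[name] = masked(na_items[..., i])
    for i, name in enumerate(PA_ITEMS):
        frame[name] = masked(pa_items[..., i])
    frame["wish_live"] = masked(wish_live)
    frame["wish_die"] = masked(si_items[..., 1])
    frame["desire_die"] = masked(si_items[..., 2])
    frame["na"] = masked(na)
    frame["pa"] = masked(pa)
    frame["si_dim"] = masked(si_dim)
    frame["si_bin"] = si_bin.reshape(-1)
    frame["attempt"] = attempt[person_id]
    records = pd.DataFrame(frame)
    return records, tau_person


def export_ground_truth(truth: GroundTruth) -> tuple[pd.DataFrame, dict]:
    """Serializable truth: per-person realized parameters and all fixed parameters.

    The person table carries coefficients on both the latent
    (standardized) scale (``lat_*``) and the composite 0-100 scale
    (``raw_*``); raw cross-lags are latent coefficients rescaled by the
    ratio of outcome to predictor within-person SDs.
    """
    params = truth.params
    person = truth.person.copy()
    wsd = np.asarray(params.within_sd)
    scale = {  # outcome index, predictor index (None = days covariate)
        "phi_na": (0, 0), "b_si_to_na": (0, 2), "d_na": (0, None),
        "phi_pa": (1, 1), "b_si_to_pa": (1, 2), "d_pa": (1, None),
        "phi_si": (2, 2), "b_na_to_si": (2, 0), "b_pa_to_si": (2, 1), "d_si": (2, None),
    }
    for name, (k, j) in scale.items():
        factor = wsd[k] if j is None else wsd[k] / wsd[j]
        person[f"raw_{name}"] = person[f"lat_{name}"] * factor
    fixed = {
        "grand_means": list(params.grand_means),
        "between_sd": list(params.between_sd),
        "within_sd": list(params.within_sd),
        "coef_mean_latent": {n: v for n, v in zip(COEF_NAMES, params.coef_mean())},
        "coef_sd_latent": {n: v for n, v in zip(COEF_NAMES, params.coef_sd)},
        "innovation_corr": np.asarray(params.innovation_corr).tolist(),
        "tau_b": params.tau_b, "lambda_b": params.lambda_b,
        "lambda_mu_b": params.lambda_mu_b, "phi_b": params.phi_b,
        "item_uniq_sd": list(params.item_uniq_sd),
        "grid_delta_h": params.grid_delta_h,
        "design": dataclasses.asdict(truth.design),
    }
    return person, fixed


def simulate_dataset(design: GenDesign | None = None,
                     params: GenParams | None = None,
                     seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Full pipeline: schedule -> latent panel -> rendered EMA records.

    Deterministic in ``(design, params, seed)``; ``seed`` overrides
    ``design.seed`` when given.
    """
    design = design or GenDesign()
    params = params or GenParams()
    if seed is not None:
        design = dataclasses.replace(design, seed=int(seed))
    rng = np.random.default_rng(design.seed)
    schedule = simulate_schedule(design, rng)
    mu, coefs = draw_person_effects(params, design.n_persons, rng)
    s, bins, _ = simulate_latent_panel(params, schedule, coefs, rng)
    records, tau_person = render_observations(params, design, schedule, s, bins, mu, rng)

    person = pd.DataFrame({"person_id": np.arange(design.n_persons)})
    person["mu_na"], person["mu_pa"], person["mu_si"] = mu[:, 0], mu[:, 1], mu[:, 2]
    for i, name in enumerate(COEF_NAMES):
        person[f"lat_{name}"] = coefs[:, i]
    person["tau_b_person"] = tau_person
    person["attempt"] = records.groupby("person_id")["attempt"].first().values
    truth = GroundTruth(person=person, params=params, design=design)
    return records, truth
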