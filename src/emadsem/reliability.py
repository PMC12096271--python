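"""Scale construction and multilevel internal consistency.

Composites are the mean of available items after reverse-scoring
(``x -> 100 - x``).  Within-person internal consistency is McDonald's
omega computed from a single-factor maximum-likelihood fit to the
pooled within-person (person-mean-centered) item covariance matrix:

    omega = (sum lambda_j)^2 / ((sum lambda_j)^2 + sum theta_j)

with loadings lambda_j and uniquenesses theta_j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["ScaleDefinition", "SI_SCALE", "NA_SCALE", "PA_SCALE",
           "score_composite", "multilevel_omega", "fit_one_factor_ml"]


@dataclass(frozen=True)
class ScaleDefinition:
    """A named composite: items, reversed items and a scoring threshold.

    ``minimum`` is the number of item responses needed to score a
    prompt; the default (half the items, rounded up) keeps scores
    comparable across occasions with occasional item-level gaps.
    """

    name: str
    items: tuple
    reversed_items: tuple = ()
    response_range: tuple = (0.0, 100.0)
    minimum: int | None = None

    def __post_init__(self) -> None:
        if not set(self.reversed_items) <= set(self.items):
            raise ValueError("reversed_items must be a subset of items")
        k = self.min_items
        if k < 1:
            raise ValueError("minimum items to score must be >= 1")

    @property
    def min_items(self) -> int:
        return self.minimum if self.minimum is not None else ceil(len(self.items) / 2)


SI_SCALE = ScaleDefinition("si_dim", ("wish_live", "wish_die", "desire_die"),
                           reversed_items=("wish_live",))
NA_SCALE = ScaleDefinition("na", ("sad", "depressed", "anxious", "angry", "tired", "ashamed"))
PA_SCALE = ScaleDefinition("pa", ("happy", "excited", "relaxed", "satisfied"))


def _reversed_items(records: pd.DataFrame, scale: ScaleDefinition) -> pd.DataFrame:
    missing = [c for c in scale.items if c not in records.columns]
    if missing:
        raise KeyError(f"unknown item(s) for scale {scale.name!r}: {missing}")
    items = records[list(scale.items)].astype(float).copy()
    hi = scale.response_range[1]
    for col in scale.reversed_items:
        items[col] = hi - items[col]
    return items


def score_composite(records: pd.DataFrame, scale: ScaleDefinition) -> pd.Series:
    """Composite per prompt: mean of available (reverse-scored) items.

    Prompts with fewer than ``scale.min_items`` item responses score
    missing.
    """
    items = _reversed_items(records, scale)
    n_present = items.notna().sum(axis=1)
    out = items.mean(axis=1)
    out[n_present < scale.min_items] = np.nan
    out.name = scale.name
    return out


def fit_one_factor_ml(cov: np.ndarray, n_obs: int, max_iter: int = 500) -> dict:
    """Single-factor model fitted to a covariance matrix by maximum likelihood.

    Minimizes the ML discrepancy F = log|Sigma| + tr(S Sigma^-1) over
    loadings and log-uniquenesses (Sigma = ll' + diag(theta)).  Returns
    loadings, uniquenesses, convergence info and whether any uniqueness
    hit the Heywood floor.
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    diag = np.diag(S)
    # principal-axis start
    w, v = np.linalg.eigh(S)
    lam0 = v[:, -1] * np.sqrt(max(w[-1], 1e-8))
    if lam0.sum() < 0:
        lam0 = -lam0
    theta0 = np.clip(diag - lam0 ** 2, 1e-4 * diag.mean(), None)
    x0 = np.concatenate([lam0, np.log(theta0)])

    def discrepancy(x):
        lam, ltheta = x[:k], x[k:]
        theta = np.exp(np.clip(ltheta, -30, 30))
        sigma = np.outer(lam, lam) + np.diag(theta)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2.0 * np.log(np.diag(L)).sum()
        inv = np.linalg.inv(sigma)
        return logdet + float(np.trace(S @ inv))

    res = optimize.minimize(discrepancy, x0, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10})
    lam = res.x[:k]
    theta = np.exp(res.x[k:])
    if lam.sum() < 0:
        lam = -lam
    heywood = bool(np.any(theta < 1e-6 * diag.mean()))
    if heywood:
        warnings.warn("Heywood case: uniqueness clipped at zero floor")
        theta = np.maximum(theta, 0.0)
    if not res.success and res.status != 2:  # status 2: precision-loss stop is acceptable
        raise RuntimeError(f"one-factor ML fit did not converge: {res.message} "
                           f"(fun={res.fun:.6g}, n_obs={n_obs})")
    return {"loadings": lam, "uniquenesses": theta, "discrepancy": float(res.fun),
            "converged": bool(res.success or res.status == 2), "heywood": heywood,
            "n_iter": int(res.nit)}


def multilevel_omega(records: pd.DataFrame, scale: ScaleDefinition) -> dict:
    """Within-person McDonald's omega for a scale.

    Items are reverse-scored, person-mean-centered, and their pooled
    within-person covariance is fitted with a one-factor ML model;
    omega follows from the fitted loadings and uniquenesses.
    """
    if len(scale.items) < 3:
        raise ValueError("omega requires >= 3 items")
    obs = records[records["observed"]] if "observed" in records else records
    items = _reversed_items(obs, scale)
    items["person_id"] = obs["person_id"].to_numpy()
    items = items.dropna()
    if items["person_id"].nunique() < 2:
        raise ValueError("omega requires >= 2 persons")
    centered = items.groupby("person_id")[list(scale.items)].transform(lambda x: x - x.mean())
    pooled_cov = centered.cov().to_numpy()
    fit = fit_one_factor_ml(pooled_cov, n_obs=len(centered))
    lam, theta = fit["loadings"], fit["uniquenesses"]
    omega = float(lam.sum() ** 2 / (lam.sum() ** 2 + theta.sum()))
    return {"omega": omega, "loadings": lam, "uniquenesses": theta,
            "pooled_cov": pooled_cov, "n_obs": len(centered),
            "converged": fit["converged"], "heywood": fit["heywood"]}
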