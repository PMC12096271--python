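"""Posterior summaries: credibility intervals, standardization, cluster rates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import psr

__all__ = ["PosteriorSummary", "standardize_within", "cluster_significance_rates",
           "summarize_scalar_draws"]


def standardize_within(coef_draws: np.ndarray, pred_sd: np.ndarray,
                       out_sd: np.ndarray) -> np.ndarray:
    """Within-level standardized estimates averaged over clusters.

    Per person, the standardized coefficient is the raw coefficient
    times SD(predictor deviations)/SD(outcome deviations); the result
    is the per-draw average across persons.

    Parameters
    ----------
    coef_draws
        Raw coefficient draws, shape (n_draws, P) for person-specific
        coefficients or (n_draws, 1) / (n_draws,) for fixed ones.
    pred_sd, out_sd
        Within-person SDs, shape (n_draws, P) or (P,); persons with
        zero outcome SD are skipped (with a warning upstream).

    Returns
    -------
    Array of shape (n_draws,): the averaged standardized draw.
    """
    coef = np.atleast_2d(np.asarray(coef_draws, dtype=float))
    pred = np.asarray(pred_sd, dtype=float)
    out = np.asarray(out_sd, dtype=float)
    if pred.ndim == 1:
        pred = pred[None, :]
    if out.ndim == 1:
        out = out[None, :]
    ok = out > 0
    ratio = np.where(ok, pred / np.where(ok, out, 1.0), np.nan)
    std = coef * ratio
    return np.nanmean(std, axis=1)


def cluster_significance_rates(person_draws: np.ndarray, level: float = 0.95
                               ) -> tuple[float, float]:
    """%Pos / %Neg of persons whose posterior interval excludes zero.

    ``person_draws`` has shape (n_draws, P); per person the central
    ``level`` interval of that person's coefficient draws is formed and
    counted as positive (negative) when it lies entirely above (below)
    zero.  Returns percentages of persons.
    """
    x = np.asarray(person_draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("person_draws must have shape (n_draws, n_persons)")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(x, alpha, axis=0)
    hi = np.quantile(x, 1.0 - alpha, axis=0)
    P = x.shape[1]
    pct_pos = 100.0 * float((lo > 0).sum()) / P
    pct_neg = 100.0 * float((hi < 0).sum()) / P
    return pct_pos, pct_neg


def summarize_scalar_draws(chains: np.ndarray) -> dict:
    """Mean, SD, central 95% interval and PSR for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws); PSR is reported as NaN
    for single-chain runs.
    """
    x = np.asarray(chains, dtype=float)
    flat = x.reshape(-1)
    out = {
        "mean": float(flat.mean()),
        "sd": float(flat.std(ddof=1)),
        "ci_lower": float(np.quantile(flat, 0.025)),
        "ci_upper": float(np.quantile(flat, 0.975)),
        "psr": psr(x) if x.shape[0] >= 2 else float("nan"),
    }
    return out


@dataclass
class PosteriorSummary:
    """Per-parameter posterior table plus convergence verdict.

    ``table`` is indexed by parameter name with columns: mean, sd,
    ci_lower, ci_upper, psr, std_mean, std_sd, std_ci_lower,
    std_ci_upper, pct_pos, pct_neg (NaN where not applicable, e.g.
    cluster rates for fixed-only coefficients).
    """

    table: pd.DataFrame
    psr_threshold: float = 1.1
    notes: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        vals = self.table["psr"].dropna()
        return bool((vals <= self.psr_threshold).all()) if len(vals) else True

    @property
    def max_psr(self) -> float:
        vals = self.table["psr"].dropna()
        return float(vals.max()) if len(vals) else float("nan")

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def significant(self, name: str, standardized: bool = True) -> bool:
        """True when the 95% credibility interval excludes zero."""
        row = self.table.loc[name]
        lo, hi = (row["std_ci_lower"], row["std_ci_upper"]) if standardized \
            else (row["ci_lower"], row["ci_upper"])
        return bool(lo > 0 or hi < 0)
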