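"""Discrete-time alignment of irregular EMA prompts and design descriptives.

Dynamic models for intensive longitudinal data assume equally spaced
occasions.  Prompts delivered semi-randomly are therefore snapped to an
equally spaced grid (default bin width 2 h, matching the median
inter-prompt gap of roughly 2.2 h): each prompt maps to its nearest bin
(half-up rounding) and skipped bins are inserted as missing occasions.
This module also computes the design statistics (compliance, gaps,
counts), person-level descriptives, intraclass correlations and mean
within-person correlations used to characterize such datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinningSummary",
    "align_to_grid",
    "suggest_delta",
    "compute_design_stats",
    "person_level_descriptives",
    "icc",
    "mean_within_person_correlation",
]

#: value columns carried onto the lattice when present in the input records
DEFAULT_VALUE_COLUMNS = ("na", "pa", "si_dim", "si_bin")


@dataclass
class BinningSummary:
    """Bookkeeping from grid alignment."""

    delta_h: float
    n_observed: int = 0
    n_bins: int = 0
    n_inserted_missing: int = 0
    collisions: list = field(default_factory=list)  # (person_id, kept_prompt, dropped_prompt)

    @property
    def n_collisions(self) -> int:
        return len(self.collisions)


def _to_bin(time_h: np.ndarray, delta_h: float) -> np.ndarray:
    """Nearest-bin assignment with half-up rounding (5.5 -> 6, not banker's 6->6)."""
    return np.floor(np.asarray(time_h, dtype=float) / delta_h + 0.5).astype(int)


def align_to_grid(records: pd.DataFrame, delta_h: float = 2.0,
                  value_columns: tuple = DEFAULT_VALUE_COLUMNS,
                  collision_policy: str = "keep_earlier",
                  ) -> tuple[pd.DataFrame, BinningSummary]:
    """Snap observed prompts to the equally spaced analysis grid.

    Parameters
    ----------
    records
        Long-format EMA table with ``person_id``, ``time_h`` and (if
        present) an ``observed`` flag; times must be sorted within
        person and non-negative.
    delta_h
        Bin width in hours (the TINTERVAL of the discrete-time model).
    collision_policy
        When two prompts map to the same bin: ``"keep_earlier"``
        (default; the earlier report is closer to the bin's preceding
        interval) or ``"keep_later"``.  The dropped prompt is logged.

    Returns
    -------
    lattice, summary
        ``lattice`` has one row per consecutive bin per person
        (``person_id``, ``bin_index`` 0-based per person, ``day_c``
        person-centered day covariate, value columns, and
        ``source_prompt_index`` = -1 for inserted missing bins).
    """
    if delta_h <= 0:
        raise ValueError("delta_h must be positive")
    if collision_policy not in ("keep_earlier", "keep_later"):
        raise ValueError(f"unknown collision_policy: {collision_policy!r}")
    if (records["time_h"] < 0).any():
        raise ValueError("negative prompt times")
    obs = records[records["observed"]] if "observed" in records else records
    value_columns = tuple(c for c in value_columns if c in records.columns)
    extra_person_cols = [c for c in ("attempt",) if c in records.columns]

    summary = BinningSummary(delta_h=delta_h)
    out_frames = []
    for pid, grp in obs.groupby("person_id", sort=True):
        t = grp["time_h"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError(f"records not time-sorted for person {pid}")
        bins = _to_bin(t, delta_h)
        keep = np.ones(len(bins), dtype=bool)
        # resolve collisions within person
        dup = np.flatnonzero(np.diff(bins) == 0)
        for i in dup:
            a, b = grp["prompt_index"].iloc[i], grp["prompt_index"].iloc[i + 1]
            if collision_policy == "keep_earlier":
                keep[i + 1] = False
                summary.collisions.append((pid, int(a), int(b)))
            else:
                keep[i] = False
                summary.collisions.append((pid, int(b), int(a)))
        g = grp[keep]
        bins = bins[keep]
        if len(bins) == 0:
            continue
        full = np.arange(bins[0], bins[-1] + 1)
        frame = pd.DataFrame({
            "person_id": pid,
            "bin_index": full - bins[0],
            "bin_global": full,
            "time_h": full * delta_h,
            "source_prompt_index": -1,
        })
        pos = bins - bins[0]
        frame.loc[pos, "source_prompt_index"] = g["prompt_index"].to_numpy()
        for col in value_columns:
            vals = np.full(len(full), np.nan)
            vals[pos] = g[col].to_numpy(dtype=float)
            frame[col] = vals
        day = full * delta_h / 24.0
        frame["day_c"] = day - day.mean()
        for col in extra_person_cols:
            frame[col] = g[col].iloc[0]
        summary.n_observed += len(bins)
        summary.n_inserted_missing += len(full) - len(bins)
        summary.n_bins += len(full)
        out_frames.append(frame)
    lattice = pd.concat(out_frames, ignore_index=True)
    return lattice, summary


def suggest_delta(records: pd.DataFrame) -> tuple[float, float]:
    """Recommend a bin width: the median inter-prompt gap rounded to whole hours.

    Returns ``(delta_h, median_gap_h)``; e.g. a median gap of 2.2 h
    yields a recommended bin width of 2 h.
    """
    stats = compute_design_stats(records)
    return float(max(1.0, np.floor(stats["median_gap_h"] + 0.5))), stats["median_gap_h"]


def compute_design_stats(records: pd.DataFrame) -> dict:
    """Compliance, median inter-prompt gap and observation counts.

    Compliance is observed/scheduled prompts; the gap is computed over
    consecutive observed prompts within person (all gaps pooled before
    taking the median, so densely sampled persons weigh more, matching
    a prompt-level median).
    """
    if len(records) == 0:
        raise ValueError("no scheduled prompts")
    observed = records["observed"] if "observed" in records else pd.Series(True, index=records.index)
    n_sched = len(records)
    obs = records[observed]
    gaps = obs.groupby("person_id")["time_h"].diff().dropna()
    per_person = obs.groupby("person_id").size()
    return {
        "n_scheduled": int(n_sched),
        "n_observed": int(len(obs)),
        "compliance": float(len(obs) / n_sched),
        "median_gap_h": float(gaps.median()) if len(gaps) else float("nan"),
        "n_persons": int(records["person_id"].nunique()),
        "observations_per_person": per_person.to_dict(),
    }


def person_level_descriptives(records: pd.DataFrame,
                              variables: tuple = ("na", "pa", "si_dim", "si_bin"),
                              ) -> dict:
    """Between-person descriptives: person means, their moments and correlations.

    Repeated measures are aggregated to person means (binary SI to the
    person's endorsement proportion); the correlation matrix is Pearson
    across persons.  Persons with no observed prompts are excluded with
    a warning; zero-variance variables yield NaN correlations and are
    flagged.
    """
    obs = records[records["observed"]] if "observed" in records else records
    n_all = records["person_id"].nunique()
    means = obs.groupby("person_id")[list(variables)].mean()
    if "attempt" in records.columns:
        means.insert(0, "attempt", records.groupby("person_id")["attempt"].first())
    if len(means) < 2:
        raise ValueError("person-level descriptives require >= 2 persons")
    if len(means) < n_all:
        warnings.warn(f"excluded {n_all - len(means)} person(s) with no observed prompts")
    sd = means.std(ddof=1)
    flagged = [c for c in means.columns if not sd[c] > 0]
    if flagged:
        warnings.warn(f"zero between-person variance, correlations undefined for: {flagged}")
    desc = pd.DataFrame({
        "mean": means.mean(),
        "sd": sd,
        "min": means.min(),
        "max": means.max(),
        "skewness": means.skew(),
        "kurtosis": means.kurt(),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = means.corr()
    return {"person_means": means, "descriptives": desc, "correlations": corr,
            "zero_variance": flagged}


def icc(records: pd.DataFrame, variable: str) -> dict:
    """Intraclass correlation by one-way random-effects ANOVA.

    ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2) with
    sigma_w^2 = MSW and sigma_b^2 = max(0, (MSB - MSW) / n_bar), where
    n_bar = (N - sum n_i^2 / N) / (k - 1) is the standard unbalanced
    correction.  Returns the ICC and its variance components.
    """
    obs = records[records["observed"]] if "observed" in records else records
    x = obs[["person_id", variable]].dropna()
    groups = x.groupby("person_id")[variable]
    n_i = groups.size()
    n_i = n_i[n_i >= 1]
    k = len(n_i)
    if k < 2:
        raise ValueError("ICC requires >= 2 persons with observations")
    N = int(n_i.sum())
    grand = x[variable].mean()
    gmeans = groups.mean()
    ssb = float((n_i * (gmeans - grand) ** 2).sum())
    ssw = float(((x[variable] - gmeans.reindex(x["person_id"]).to_numpy()) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n_bar = (N - (n_i ** 2).sum() / N) / (k - 1)
    var_b = max(0.0, (msb - msw) / n_bar)
    value = var_b / (var_b + msw) if (var_b + msw) > 0 else float("nan")
    return {"icc": value, "var_between": var_b, "var_within": msw,
            "msb": msb, "msw": msw, "n_persons": k, "n_obs": N}


def mean_within_person_correlation(records: pd.DataFrame, var1: str, var2: str,
                                   min_obs: int = 3) -> dict:
    """Unweighted average of per-person Pearson correlations.

    Persons contribute when they have at least ``min_obs`` paired
    observations and nonzero variance in both variables.
    """
    obs = records[records["observed"]] if "observed" in records else records
    rs = []
    for _, grp in obs.groupby("person_id"):
        pair = grp[[var1, var2]].dropna()
        if len(pair) < min_obs:
            continue
        a, b = pair[var1].to_numpy(), pair[var2].to_numpy()
        if a.std() == 0 or b.std() == 0:
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    if not rs:
        raise ValueError("no person contributes a defined within-person correlation")
    return {"mean_r": float(np.mean(rs)), "n_contributing": len(rs), "person_rs": rs}
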