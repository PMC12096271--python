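"""Selected-pairs replication: affect during vs. after resolved SI episodes.

Several EMA studies of the affect-regulation hypothesis restrict
analysis to consecutive assessment pairs in which SI is present and
then absent at the next answered prompt (within 4 h), and contrast
affect "during" vs "after".  This module reproduces that procedure: SI
presence at a prompt requires a nonzero momentary desire-to-die rating
AND endorsement of the binary active-SI item; qualifying during/after
pairs feed a three-level random-effects mixed model (responses within
events within participants) of affect on event state.  Because the
selection conditions on SI *resolving*, regression to the mean produces
an apparent post-SI affect improvement even under positive SI-affect
cross-lags; ``selection_footprint`` quantifies how little of the data
the procedure retains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["PairSet", "MixedFit", "flag_si_presence", "select_pairs",
           "fit_state_mixed_model", "selection_footprint"]


@dataclass
class PairSet:
    """Selected during/after response pairs plus the selection log."""

    pairs: pd.DataFrame          # person_id, event, during/after prompt ids, times, gap_h, outcomes
    selection_log: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_participants(self) -> int:
        return int(self.pairs["person_id"].nunique()) if len(self.pairs) else 0

    def long_format(self, outcome: str) -> pd.DataFrame:
        """Two rows per pair (state 0 = during, 1 = after); missing-outcome pairs dropped."""
        rows = []
        for _, r in self.pairs.iterrows():
            rows.append((r["person_id"], r["event"], 0, r[f"{outcome}_during"]))
            rows.append((r["person_id"], r["event"], 1, r[f"{outcome}_after"]))
        long = pd.DataFrame(rows, columns=["person_id", "event", "state", outcome])
        complete = long.groupby("event")[outcome].transform(lambda x: x.notna().all())
        return long[complete]


@dataclass
class MixedFit:
    """Fixed during->after contrast from the variance-components model."""

    B: float
    se: float
    ci_lower: float
    ci_upper: float
    p: float
    var_participant: float
    var_event: float
    var_residual: float
    n_pairs: int
    n_participants: int
    converged: bool = True


def flag_si_presence(records: pd.DataFrame,
                     desire_item: str = "desire_die") -> pd.Series:
    """SI presence at a prompt: momentary desire-to-die > 0 AND binary SI endorsed.

    Prompts missing either component are scored not-present (counted in
    the caller's selection log via ``select_pairs``).
    """
    if desire_item not in records.columns or "si_bin" not in records.columns:
        raise KeyError("records need desire item and si_bin columns")
    desire = records[desire_item]
    si = records["si_bin"]
    return ((desire > 0) & (si == 1)).fillna(False).astype(bool)


def select_pairs(records: pd.DataFrame, max_gap_h: float = 4.0,
                 desire_item: str = "desire_die") -> PairSet:
    """Select consecutive during-SI -> after-SI response pairs.

    A pair is an observed prompt with SI presence followed by the
    *next* observed prompt (adjacent in the person's answered sequence)
    without presence, at most ``max_gap_h`` hours later.  Runs of
    continued SI contribute no pair until (and unless) they resolve.
    """
    obs = records[records["observed"]] if "observed" in records else records
    obs = obs.sort_values(["person_id", "time_h"])
    present = flag_si_presence(obs, desire_item)
    log = {
        "n_observed": int(len(obs)),
        "n_present": int(present.sum()),
        "n_missing_presence_inputs": int(
            (obs[desire_item].isna() | obs["si_bin"].isna()).sum()),
        "n_continued_si": 0,
        "n_gap_excluded": 0,
    }
    rows = []
    event = 0
    for pid, grp in obs.groupby("person_id", sort=True):
        pres = present.loc[grp.index].to_numpy()
        t = grp["time_h"].to_numpy()
        for i in range(len(grp) - 1):
            if not pres[i]:
                continue
            if pres[i + 1]:
                log["n_continued_si"] += 1
                continue
            gap = t[i + 1] - t[i]
            if gap > max_gap_h:
                log["n_gap_excluded"] += 1
                continue
            r0, r1 = grp.iloc[i], grp.iloc[i + 1]
            rows.append({
                "person_id": pid, "event": event,
                "prompt_during": r0["prompt_index"], "prompt_after": r1["prompt_index"],
                "time_during": t[i], "time_after": t[i + 1], "gap_h": gap,
                "na_during": r0.get("na", np.nan), "na_after": r1.get("na", np.nan),
                "pa_during": r0.get("pa", np.nan), "pa_after": r1.get("pa", np.nan),
            })
            event += 1
    pairs = pd.DataFrame(rows, columns=[
        "person_id", "event", "prompt_during", "prompt_after",
        "time_during", "time_after", "gap_h",
        "na_during", "na_after", "pa_during", "pa_after"])
    log["n_pairs"] = len(pairs)
    log["n_participants"] = int(pairs["person_id"].nunique()) if len(pairs) else 0
    return PairSet(pairs=pairs, selection_log=log)


def fit_state_mixed_model(pairset: PairSet, outcome: str = "na") -> MixedFit:
    """Mixed model of affect on event state (0 = during SI, 1 = after SI).

    Random intercepts for participant and for event (the pair) are
    estimated by REML; inference on the state contrast B uses a Wald z
    with CI = B +/- 1.96 SE.  Negative variance-component estimates are
    floored at zero by the optimizer (boundary fits warn, not fail).
    """
    if outcome not in ("na", "pa"):
        raise ValueError("outcome must be 'na' or 'pa'")
    long = pairset.long_format(outcome)
    n_dropped = pairset.n_pairs - long["event"].nunique()
    if long["event"].nunique() < 2 or long["person_id"].nunique() < 2:
        raise ValueError("too few pairs/participants for the mixed model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{outcome} ~ state", data=long,
                            groups=long["person_id"],
                            re_formula="1",
                            vc_formula={"event": "0 + C(event)"})
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    B = float(fit.params["state"])
    se = float(fit.bse["state"])
    p = float(fit.pvalues["state"])
    var_participant = float(np.asarray(fit.cov_re)[0, 0])
    var_event = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    return MixedFit(
        B=B, se=se, ci_lower=B - 1.96 * se, ci_upper=B + 1.96 * se, p=p,
        var_participant=max(0.0, var_participant),
        var_event=max(0.0, var_event),
        var_residual=float(fit.scale),
        n_pairs=int(long["event"].nunique()),
        n_participants=int(long["person_id"].nunique()),
        converged=bool(fit.converged),
    )


def selection_footprint(pairset: PairSet, records: pd.DataFrame) -> dict:
    """Share of observations and participants the pairs procedure retains."""
    obs = records[records["observed"]] if "observed" in records else records
    n_obs = len(obs)
    n_persons = records["person_id"].nunique()
    return {
        "fraction_observations": (2.0 * pairset.n_pairs / n_obs) if n_obs else 0.0,
        "fraction_participants": (pairset.n_participants / n_persons) if n_persons else 0.0,
        "n_pairs": pairset.n_pairs,
        "n_observations": n_obs,
        "n_participants_retained": pairset.n_participants,
        "n_participants": int(n_persons),
    }
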