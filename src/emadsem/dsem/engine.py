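"""Blocked Gibbs sampler for two-level dynamic structural equation models.

The within-person model is a discrete-time VAR(1)-type system on the
analysis lattice: each continuous outcome is decomposed into a latent
person mean and within-person deviations (latent mean centering — the
deviation is defined against the *sampled* mean, not the observed one),
deviations regress on lagged deviations, contemporaneous binary
predictors, binary-by-lag interactions, and a person-centered day
trend.  Regression coefficients are person-specific draws from a
between-level multivariate normal (random effects, covariance sampled
from an inverse-Wishart) or pooled fixed effects.  Innovations of the
continuous equations carry a free covariance matrix (inverse-Wishart
step) so that contemporaneous correlation between outcomes is not
forced into the cross-lags — this matters for the missing-data
augmentation, where roughly half of the lattice bins (overnight gaps,
unanswered prompts) are imputed each sweep from their full
conditionals.  Binary outcomes use a probit link via latent-response
(truncated-normal) augmentation with a person-specific random
intercept; probit residuals are standard normal and independent of the
continuous innovations.

Chains run independently from dispersed starts; convergence is
summarized with the Gelman-Rubin potential scale reduction (PSR).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import wishart

from .spec import DsemSpec, Equation
from .summary import PosteriorSummary, cluster_significance_rates, summarize_scalar_draws

logger = logging.getLogger(__name__)

__all__ = ["DsemResult", "fit_dsem"]

_U_EPS = 1e-12


# --------------------------------------------------------------------------
# data container
# --------------------------------------------------------------------------

class _Panel:
    """Lattice data pivoted to (person, bin) arrays padded to a common length."""

    def __init__(self, lattice: pd.DataFrame, variables: tuple, covariate_cols: tuple):
        need = {"person_id", "bin_index"}
        if not need <= set(lattice.columns):
            raise ValueError(f"lattice must carry columns {sorted(need)}")
        for v in variables:
            if v not in lattice.columns:
                raise ValueError(f"lattice has no column for model variable {v!r}")
        any_obs = lattice.groupby("person_id")[list(variables)].count().sum(axis=1)
        dropped = any_obs.index[any_obs == 0]
        if len(dropped):
            warnings.warn(f"excluding {len(dropped)} person(s) with empty series")
            lattice = lattice[~lattice["person_id"].isin(dropped)]
        self.persons = np.sort(lattice["person_id"].unique())
        P = len(self.persons)
        sizes = lattice.groupby("person_id")["bin_index"].max() + 1
        T = int(sizes.max())
        self.P, self.T = P, T
        self.valid = np.zeros((P, T), dtype=bool)
        self.day = np.zeros((P, T))
        self.y = {v: np.full((P, T), np.nan) for v in variables}
        pos = {pid: i for i, pid in enumerate(self.persons)}
        pi = lattice["person_id"].map(pos).to_numpy()
        bi = lattice["bin_index"].to_numpy()
        self.valid[pi, bi] = True
        if "day_c" in lattice.columns:
            self.day[pi, bi] = lattice["day_c"].to_numpy(dtype=float)
        for v in variables:
            self.y[v][pi, bi] = lattice[v].to_numpy(dtype=float)
        self.obs = {v: ~np.isnan(self.y[v]) for v in variables}
        self.covariates = {}
        for col in covariate_cols:
            if col not in lattice.columns:
                raise ValueError(f"between-level covariate column {col!r} missing")
            firsts = lattice.groupby("person_id")[col].first()
            self.covariates[col] = firsts.reindex(self.persons).to_numpy(dtype=float)
        # lag-pair equations exist for t >= 1 within each person's span
        self.eqmask = self.valid & np.concatenate(
            [np.zeros((P, 1), dtype=bool), self.valid[:, :-1]], axis=1)


def _shift(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    out[:, 1:] = x[:, :-1]
    return out


# --------------------------------------------------------------------------
# result container
# --------------------------------------------------------------------------

@dataclass
class DsemResult:
    """Fitted model: posterior summary table, retained draws, diagnostics."""

    summary: PosteriorSummary
    draws: dict                       # name -> (n_chains, n_kept)
    std_draws: dict                   # name -> (n_chains, n_kept)
    person_draws: dict                # name -> (n_chains, n_kept, P), random terms only
    persons: np.ndarray
    spec: DsemSpec
    notes: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.summary.converged


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

class _Gibbs:
    def __init__(self, panel: _Panel, spec: DsemSpec):
        self.panel = panel
        self.spec = spec
        self.eqs = list(spec.equations)
        self.cvars = [e.outcome for e in self.eqs if e.link == "identity"]
        bvars = [e.outcome for e in self.eqs if e.link == "probit"]
        if len(bvars) > 1:
            raise NotImplementedError("at most one probit outcome is supported")
        self.bvar = bvars[0] if bvars else None
        for e in self.eqs:
            if e.link == "probit" and e.random:
                raise NotImplementedError(
                    "probit equations must use fixed regression coefficients")
            if e.link == "probit" and (e.con_predictors or e.interactions):
                raise NotImplementedError(
                    "contemporaneous/interaction terms are not supported in probit equations")
            for b, v in e.interactions:
                if b != self.bvar or v not in [x.outcome for x in self.eqs
                                               if x.link == "identity"]:
                    raise NotImplementedError(
                        "interactions must be (binary outcome) x (lagged continuous)")
            for v in e.con_predictors:
                if v != self.bvar:
                    raise NotImplementedError("contemporaneous predictors must be binary")
        self.cidx = {v: i for i, v in enumerate(self.cvars)}
        self.Kc = len(self.cvars)
        self.id_eqs = [e for e in self.eqs if e.link == "identity"]
        flags = {e.random for e in self.id_eqs}
        if self.Kc >= 2 and len(flags) > 1:
            raise NotImplementedError(
                "continuous equations must be all-random or all-fixed when the "
                "innovation covariance couples them")
        self.random_eqs = [e for e in self.eqs if e.random]
        self.qR = sum(e.n_terms for e in self.random_eqs)
        off = 0
        self.r_offsets = {}
        for e in self.random_eqs:
            self.r_offsets[e.outcome] = off
            off += e.n_terms
        self.pure_var = (self.bvar is None and
                         all(not e.con_predictors and not e.interactions for e in self.eqs))
        self.eq_by_out = {e.outcome: e for e in self.eqs}
        # appearances of each continuous var as a lag-level regressor (for imputation)
        self.appear = {v: [] for v in self.cvars}
        for e in self.eqs:
            for j, term in enumerate(self._terms(e)):
                kind = term[0]
                if kind == "lag" and term[1] in self.cidx:
                    self.appear[term[1]].append((e, j, None))
                elif kind == "inter":
                    self.appear[term[2]].append((e, j, term[1]))

    @staticmethod
    def _terms(eq: Equation):
        terms = [("lag", v) for v in eq.lag_predictors]
        terms += [("con", v) for v in eq.con_predictors]
        terms += [("inter", b, v) for b, v in eq.interactions]
        if eq.days:
            terms.append(("days",))
        return terms

    # -- state access -------------------------------------------------------

    def _term_values(self, eq: Equation) -> np.ndarray:
        """Regressor array (q, P, T) for an equation under the current state."""
        P, T = self.panel.P, self.panel.T
        feats = np.empty((eq.n_terms, P, T))
        for j, term in enumerate(self._terms(eq)):
            kind = term[0]
            if kind == "lag":
                src = self.w[term[1]] if term[1] in self.cidx else self.bval
                feats[j] = _shift(src)
            elif kind == "con":
                feats[j] = self.bval
            elif kind == "inter":
                feats[j] = self.bval * _shift(self.w[term[2]])
            else:
                feats[j] = self.panel.day
        return feats

    def _coef(self, eq: Equation) -> np.ndarray:
        """(P, q) person coefficients (fixed equations broadcast)."""
        c = self.coefs[eq.outcome]
        if c.ndim == 1:
            return np.broadcast_to(c, (self.panel.P, len(c)))
        return c

    def _term_value_at(self, term, t: int) -> np.ndarray:
        kind = term[0]
        if kind == "lag":
            src = self.w[term[1]] if term[1] in self.cidx else self.bval
            return src[:, t - 1] if t >= 1 else np.zeros(self.panel.P)
        if kind == "con":
            return self.bval[:, t]
        if kind == "inter":
            lag = self.w[term[2]][:, t - 1] if t >= 1 else np.zeros(self.panel.P)
            return self.bval[:, t] * lag
        return self.panel.day[:, t]

    def _eq_mean_at(self, eq: Equation, t: int) -> np.ndarray:
        coef = self._coef(eq)
        mean = np.zeros(self.panel.P)
        for j, term in enumerate(self._terms(eq)):
            mean += coef[:, j] * self._term_value_at(term, t)
        return mean

    def _resid(self, eq: Equation) -> np.ndarray:
        feats = self._term_values(eq)
        coef = self._coef(eq)
        pred = np.einsum("qpt,pq->pt", feats, coef)
        if eq.link == "probit":
            return self.ystar - self.alpha[:, None] - pred
        return self.w[eq.outcome] - pred

    # -- initialization -----------------------------------------------------

    def init_state(self, rng: np.random.Generator, chain: int) -> None:
        panel, spec = self.panel, self.spec
        P, T = panel.P, panel.T
        self.w = {}
        self.mu = np.zeros((P, self.Kc))
        for v in self.cvars:
            y = panel.y[v]
            if spec.latent_means:
                m = np.nanmean(np.where(panel.obs[v], y, np.nan), axis=1)
                m = np.where(np.isnan(m), np.nanmean(y), m)
            else:
                m = np.zeros(P)
            self.mu[:, self.cidx[v]] = m
            w = y - m[:, None]
            sd = np.nanstd(w[panel.obs[v]]) or 1.0
            w = np.where(panel.obs[v], w, rng.normal(0, 0.5 * sd, size=(P, T)))
            self.w[v] = np.where(panel.valid, w, 0.0)
        if self.bvar is not None:
            yb = panel.y[self.bvar]
            rate = np.nanmean(np.where(panel.obs[self.bvar], yb, np.nan), axis=1)
            rate = np.clip(np.where(np.isnan(rate), np.nanmean(yb), rate), 0.02, 0.98)
            fill = (rng.random((P, T)) < rate[:, None]).astype(float)
            self.bval = np.where(panel.obs[self.bvar], np.nan_to_num(yb), fill)
            self.bval = np.where(panel.valid, self.bval, 0.0)
            self.ystar = np.where(self.bval > 0, 0.5, -0.5) + 0.3 * rng.standard_normal((P, T))
            self.ystar = np.where(self.bval > 0, np.abs(self.ystar), -np.abs(self.ystar))
            self.alpha = ndtri(rate) if spec.latent_means else np.zeros(P)
        else:
            self.bval = np.zeros((P, T))
            self.ystar = np.zeros((P, T))
            self.alpha = np.zeros(P)

        # pilot per-person ridge OLS for coefficients and dispersed starts
        self.coefs = {}
        sigma2 = {}
        disp = 0.5 * (chain - (spec.n_chains - 1) / 2.0) if spec.n_chains > 1 else 0.0
        pilot_sds = {}
        for eq in self.eqs:
            feats = self._term_values(eq) * panel.eqmask
            target = (self.ystar if eq.link == "probit" else self.w[eq.outcome]) * panel.eqmask
            G = np.einsum("ipt,jpt->pij", feats, feats) + 1e-3 * np.eye(eq.n_terms)
            H = np.einsum("ipt,pt->pi", feats, target)
            b0 = np.linalg.solve(G, H[:, :, None])[:, :, 0]
            g0 = b0.mean(axis=0)
            sd0 = b0.std(axis=0) + 1e-3
            pilot_sds[eq.outcome] = sd0
            start = g0 + disp * sd0 * rng.standard_normal(eq.n_terms)
            if eq.random:
                self.coefs[eq.outcome] = np.tile(start, (P, 1))
            else:
                self.coefs[eq.outcome] = start
            if eq.link == "identity":
                if eq.outcome in spec.known_resid_sd:
                    sigma2[eq.outcome] = float(spec.known_resid_sd[eq.outcome]) ** 2
                else:
                    pred = np.einsum("ipt,pi->pt", feats, b0)
                    rr = (target - pred)[panel.eqmask]
                    sigma2[eq.outcome] = float(np.var(rr)) or 1.0
        self.Sig = np.diag([sigma2[v] for v in self.cvars]) if self.Kc \
            else np.zeros((0, 0))
        self.Sinv = np.linalg.inv(self.Sig) if self.Kc else np.zeros((0, 0))
        if self.random_eqs:
            self.gammaR = np.concatenate(
                [self.coefs[e.outcome][0] for e in self.random_eqs])
            om = np.concatenate([pilot_sds[e.outcome] for e in self.random_eqs]) ** 2
            self.Omega = np.diag(np.clip(om, 1e-4, None))
        else:
            self.gammaR = np.zeros(0)
            self.Omega = np.zeros((0, 0))
        # between level
        self.nu = self.mu.mean(axis=0)
        if self.Kc and P >= 2:
            self.Psi = np.cov(self.mu.T).reshape(self.Kc, self.Kc) + 1e-3 * np.eye(self.Kc)
        else:
            self.Psi = np.eye(max(self.Kc, 1))[:self.Kc, :self.Kc]
        self.kappa = {out: np.zeros(len(cols))
                      for out, cols in spec.between_covariates.items()}
        self.tau_a = float(self.alpha.mean()) if self.bvar is not None else 0.0
        self.psi_a = float(np.var(self.alpha) + 0.05) if self.bvar is not None else 1.0

    @property
    def sigma2(self) -> dict:
        return {v: float(self.Sig[self.cidx[v], self.cidx[v]]) for v in self.cvars}

    def _scale2(self, eq: Equation) -> float:
        if eq.link == "probit":
            return 1.0
        k = self.cidx[eq.outcome]
        return float(self.Sig[k, k])

    # -- sweep steps --------------------------------------------------------

    def _impute_continuous(self, rng: np.random.Generator) -> None:
        """Checkerboard Gibbs update of every missing continuous deviation.

        The full conditional of w_v[t] collects (i) the joint density of
        the time-t continuous innovations (with the full covariance
        Sigma), (ii) every equation at t+1 in which w_v[t] is a
        regressor (lag or interaction; probit equations enter through
        their latent response with unit variance), and (iii) a
        stationary-variance prior for the first bin.  Because the
        system is first-order Markov in time, sites of one variable at
        even bins are conditionally independent given the odd bins (and
        vice versa), so each half-sweep is drawn in one vectorized
        block (red-black Gibbs).
        """
        panel = self.panel
        P, T = panel.P, panel.T
        Sinv = self.Sinv
        parity_mask = {p: (np.arange(T) % 2) == p for p in (0, 1)}
        for v in self.cvars:
            k = self.cidx[v]
            own = self.eq_by_out[v]
            s2_own = float(self.Sig[k, k])
            miss = panel.valid & ~panel.obs[v]
            if not miss.any():
                continue
            coef_own = self._coef(own)
            try:
                jself = self._terms(own).index(("lag", v))
                phi_self = coef_own[:, jself]
            except ValueError:
                phi_self = np.zeros(P)
            v0 = (s2_own / np.clip(1.0 - phi_self ** 2, 0.05, None))[:, None]
            for parity in (0, 1):
                sites = miss & parity_mask[parity][None, :]
                if not sites.any():
                    continue
                # current predictions/residuals for every equation
                pred = {}
                resid = {}
                for eq in self.eqs:
                    f = self._term_values(eq)
                    pr = np.einsum("qpt,pq->pt", f, self._coef(eq))
                    pred[eq.outcome] = pr
                    if eq.link == "probit":
                        resid[eq.outcome] = self.ystar - self.alpha[:, None] - pr
                    else:
                        resid[eq.outcome] = self.w[eq.outcome] - pr
                em = panel.eqmask
                # (i) time-t innovation density
                prec = np.where(em, Sinv[k, k], 1.0 / v0)
                num = np.full((P, T), 0.0)
                num += Sinv[k, k] * pred[v]
                for u in self.cvars:
                    j = self.cidx[u]
                    if j != k:
                        num -= Sinv[k, j] * resid[u]
                num = np.where(em, num, 0.0)
                # (ii) equations at t+1 where w_v[t] is a regressor
                a_id = np.zeros((P, self.Kc, T))     # d(mean_m at t)/d(w_v at t-1)
                c_pro = np.zeros((P, T))
                for (eq, j, inter_b) in self.appear[v]:
                    coefj = self._coef(eq)[:, j, None]
                    c = coefj if inter_b is None else coefj * self.bval
                    if eq.link == "probit":
                        c_pro += c
                    else:
                        a_id[:, self.cidx[eq.outcome], :] += c
                if np.any(a_id):
                    rpart = np.stack([resid[u] for u in self.cvars], axis=1)
                    rpart = rpart + a_id * _shift(self.w[v])[:, None, :]
                    aS = np.einsum("pmt,ml->plt", a_id, Sinv)
                    aSa = np.einsum("plt,plt->pt", aS, a_id)
                    aSr = np.einsum("plt,plt->pt", aS, rpart)
                    prec[:, :-1] += np.where(em, aSa, 0.0)[:, 1:]
                    num[:, :-1] += np.where(em, aSr, 0.0)[:, 1:]
                if np.any(c_pro):
                    bv = self.bvar
                    rp = resid[bv] + c_pro * _shift(self.w[v])
                    prec[:, :-1] += np.where(em, c_pro ** 2, 0.0)[:, 1:]
                    num[:, :-1] += np.where(em, c_pro * rp, 0.0)[:, 1:]
                draw = num / prec + rng.standard_normal((P, T)) / np.sqrt(prec)
                self.w[v][sites] = draw[sites]

    def _trunc_normal(self, eta: np.ndarray, side: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
        """Draw from N(eta, 1) truncated to >0 (side=1) or <=0 (side=0)."""
        p0 = np.clip(ndtr(-eta), _U_EPS, 1 - _U_EPS)
        u = rng.random(eta.shape)
        u_pos = p0 + u * (1 - p0)
        u_neg = u * p0
        uu = np.clip(np.where(side > 0, u_pos, u_neg), _U_EPS, 1 - _U_EPS)
        return eta + ndtri(uu)

    def _update_binary(self, rng: np.random.Generator) -> None:
        """Latent-response augmentation and imputation of missing binary bins.

        Missing binary values are drawn by enumerating both states: the
        probit orthant mass at t (latent response integrated out) times
        the likelihood of every equation in which the binary value at t
        appears (affect equations contemporaneously/interactively; its
        own equation at t+1 through the lagged report).  The latent
        response is then drawn truncated to the realized side.  Sites
        are updated in a red-black (even/odd bin) pattern, each
        half-sweep as one vectorized block.
        """
        if self.bvar is None:
            return
        panel = self.panel
        P, T = panel.P, panel.T
        beq = self.eq_by_out[self.bvar]
        obs = panel.obs[self.bvar]
        miss = panel.valid & ~obs
        con_eqs = []
        for e in self.eqs:
            if e.link != "identity":
                continue
            terms = self._terms(e)
            cj = [j for j, tm in enumerate(terms) if tm[0] == "con"]
            ij = [(j, tm[2]) for j, tm in enumerate(terms) if tm[0] == "inter"]
            if cj or ij:
                con_eqs.append((e, cj, ij))
        try:
            jlag_self = self._terms(beq).index(("lag", self.bvar))
        except ValueError:
            jlag_self = None
        coef_b = self._coef(beq)
        parity_arr = (np.arange(T) % 2)
        for parity in (0, 1):
            pm = parity_arr == parity
            eta = self.alpha[:, None] + np.einsum(
                "qpt,pq->pt", self._term_values(beq), coef_b)
            sites = miss & pm[None, :]
            if sites.any():
                logw1 = np.log(np.clip(ndtr(eta), _U_EPS, None))
                logw0 = np.log(np.clip(ndtr(-eta), _U_EPS, None))
                for (e, cj, ij) in con_eqs:
                    coef = self._coef(e)
                    delta = np.zeros((P, T))
                    for j in cj:
                        delta += coef[:, j, None]
                    for j, cv in ij:
                        delta += coef[:, j, None] * _shift(self.w[cv])
                    pred = np.einsum("qpt,pq->pt", self._term_values(e), coef)
                    mean0 = pred - self.bval * delta
                    r0 = self.w[e.outcome] - mean0
                    r1 = r0 - delta
                    s2 = self._scale2(e)
                    em = panel.eqmask
                    logw0 += np.where(em, -0.5 * r0 ** 2 / s2, 0.0)
                    logw1 += np.where(em, -0.5 * r1 ** 2 / s2, 0.0)
                if jlag_self is not None:
                    cl = coef_b[:, jlag_self, None]
                    # coefficient of si[t] in eta at t+1 is cl; remove current value
                    eta0_next = eta[:, 1:] - _shift(self.bval)[:, 1:] * cl
                    r0n = self.ystar[:, 1:] - eta0_next
                    r1n = r0n - cl
                    em = panel.eqmask[:, 1:]
                    logw0[:, :-1] += np.where(em, -0.5 * r0n ** 2, 0.0)
                    logw1[:, :-1] += np.where(em, -0.5 * r1n ** 2, 0.0)
                p1 = 1.0 / (1.0 + np.exp(np.clip(logw0 - logw1, -500, 500)))
                snew = (rng.random((P, T)) < p1).astype(float)
                self.bval[sites] = snew[sites]
                # eta at the updated sites depends only on the previous bin's
                # report, so no refresh is needed before drawing ystar
            upd = panel.valid & pm[None, :]
            draw = self._trunc_normal(eta, self.bval, rng)
            self.ystar[upd] = draw[upd]

    def _update_random_coefs(self, rng: np.random.Generator) -> None:
        if not self.random_eqs:
            return
        panel, spec = self.panel, self.spec
        P = panel.P
        q = self.qR
        Oinv = np.linalg.inv(self.Omega)
        prec = np.broadcast_to(Oinv, (P, q, q)).copy()
        lin = np.broadcast_to(Oinv @ self.gammaR, (P, q)).copy()
        feats = {e.outcome: self._term_values(e) * panel.eqmask for e in self.random_eqs}
        for ek in self.random_eqs:
            ok = self.r_offsets[ek.outcome]
            qk = ek.n_terms
            kk = self.cidx[ek.outcome]
            for el in self.random_eqs:
                ol = self.r_offsets[el.outcome]
                ql = el.n_terms
                ll = self.cidx[el.outcome]
                sinv = self.Sinv[kk, ll]
                if sinv == 0.0:
                    continue
                cross = np.einsum("ipt,jpt->pij", feats[ek.outcome], feats[el.outcome])
                prec[:, ok:ok + qk, ol:ol + ql] += sinv * cross
                lin[:, ok:ok + qk] += sinv * np.einsum(
                    "ipt,pt->pi", feats[ek.outcome],
                    self.w[el.outcome] * panel.eqmask)
        mean = np.linalg.solve(prec, lin[:, :, None])[:, :, 0]
        L = np.linalg.cholesky(prec)
        z = rng.standard_normal((P, q))
        dev = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
        b = mean + dev
        for eq in self.random_eqs:
            o = self.r_offsets[eq.outcome]
            self.coefs[eq.outcome] = b[:, o:o + eq.n_terms]
        # hyperpriors: mean vector and covariance of the random coefficients
        prior_prec = 1.0 / spec.priors.fixed_var
        gprec = P * Oinv + prior_prec * np.eye(q)
        gnum = Oinv @ b.sum(axis=0)
        gmean = np.linalg.solve(gprec, gnum)
        Lg = np.linalg.cholesky(gprec)
        self.gammaR = gmean + np.linalg.solve(Lg.T, rng.standard_normal(q))
        dev = b - self.gammaR
        scale = spec.priors.iw_scale * np.eye(q) + dev.T @ dev
        df = q + 1 + P
        Winv = wishart.rvs(df, np.linalg.inv(scale), random_state=rng)
        self.Omega = np.linalg.inv(Winv)

    def _update_fixed_coefs(self, rng: np.random.Generator) -> None:
        panel, spec = self.panel, self.spec
        fixed_id = [e for e in self.id_eqs if not e.random]
        if fixed_id:
            # joint update across coupled continuous equations
            q_tot = sum(e.n_terms for e in fixed_id)
            offs = {}
            off = 0
            for e in fixed_id:
                offs[e.outcome] = off
                off += e.n_terms
            prec = np.eye(q_tot) / spec.priors.fixed_var
            lin = np.zeros(q_tot)
            feats = {e.outcome: self._term_values(e) * panel.eqmask for e in fixed_id}
            for ek in fixed_id:
                ok, qk, kk = offs[ek.outcome], ek.n_terms, self.cidx[ek.outcome]
                for el in fixed_id:
                    ol, ql, ll = offs[el.outcome], el.n_terms, self.cidx[el.outcome]
                    sinv = self.Sinv[kk, ll]
                    if sinv == 0.0:
                        continue
                    prec[ok:ok + qk, ol:ol + ql] += sinv * np.einsum(
                        "ipt,jpt->ij", feats[ek.outcome], feats[el.outcome])
                    lin[ok:ok + qk] += sinv * np.einsum(
                        "ipt,pt->i", feats[ek.outcome], self.w[el.outcome] * panel.eqmask)
                # cross terms with random continuous equations are excluded by
                # construction (all-random or all-fixed when Kc >= 2)
            mean = np.linalg.solve(prec, lin)
            L = np.linalg.cholesky(prec)
            theta = mean + np.linalg.solve(L.T, rng.standard_normal(q_tot))
            for e in fixed_id:
                o = offs[e.outcome]
                self.coefs[e.outcome] = theta[o:o + e.n_terms]
        for eq in self.eqs:
            if eq.random or eq.link != "probit":
                continue
            f = self._term_values(eq) * panel.eqmask
            target = (self.ystar - self.alpha[:, None]) * panel.eqmask
            G = np.einsum("ipt,jpt->ij", f, f)
            H = np.einsum("ipt,pt->i", f, target)
            prec = G + np.eye(eq.n_terms) / spec.priors.fixed_var
            mean = np.linalg.solve(prec, H)
            L = np.linalg.cholesky(prec)
            self.coefs[eq.outcome] = mean + np.linalg.solve(
                L.T, rng.standard_normal(eq.n_terms))

    def _update_innovation_cov(self, rng: np.random.Generator) -> None:
        if self.Kc == 0:
            return
        panel, spec = self.panel, self.spec
        known = spec.known_resid_sd
        if self.Kc == 1 or known:
            # diagonal: per-equation inverse-gamma (respecting known SDs)
            for v in self.cvars:
                k = self.cidx[v]
                if v in known:
                    self.Sig[k, k] = float(known[v]) ** 2
                    continue
                resid = self._resid(self.eq_by_out[v])[panel.eqmask]
                a = spec.priors.resid_a + 0.5 * resid.size
                b = spec.priors.resid_b + 0.5 * float(resid @ resid)
                self.Sig[k, k] = float(b / rng.gamma(a))
            self.Sig = np.diag(np.diag(self.Sig))
        else:
            E = np.stack([self._resid(self.eq_by_out[v])[panel.eqmask]
                          for v in self.cvars], axis=1)
            scale = spec.priors.iw_scale * np.eye(self.Kc) + E.T @ E
            df = self.Kc + 1 + E.shape[0]
            Winv = wishart.rvs(df, np.linalg.inv(scale), random_state=rng)
            self.Sig = np.linalg.inv(np.atleast_2d(Winv))
        self.Sinv = np.linalg.inv(self.Sig)

    def _update_latent_means(self, rng: np.random.Generator) -> None:
        if not self.spec.latent_means or self.Kc == 0:
            return
        panel, spec = self.panel, self.spec
        P, T, Kc = panel.P, panel.T, self.Kc
        prec = np.broadcast_to(np.linalg.inv(self.Psi), (P, Kc, Kc)).copy()
        m = np.broadcast_to(self.nu, (P, Kc)).copy()
        for out, cols in spec.between_covariates.items():
            k = self.cidx[out]
            for ci, col in enumerate(cols):
                m[:, k] += self.kappa[out][ci] * panel.covariates[col]
        num = np.einsum("pij,pj->pi", prec, m)
        # continuous equations: joint innovation density, gradients wrt mu
        grads = np.zeros((P, Kc, Kc, T))       # (person, equation, mu-component, time)
        resids = np.zeros((P, Kc, T))
        for v in self.cvars:
            eq = self.eq_by_out[v]
            kk = self.cidx[v]
            grads[:, kk, kk, :] -= 1.0
            coef = self._coef(eq)
            for j, term in enumerate(self._terms(eq)):
                if term[0] == "lag" and term[1] in self.cidx:
                    grads[:, kk, self.cidx[term[1]], :] += coef[:, j, None]
                elif term[0] == "inter":
                    grads[:, kk, self.cidx[term[2]], :] += coef[:, j, None] * self.bval
            resids[:, kk, :] = self._resid(eq)
        em = panel.eqmask[:, None, :]
        grads = grads * panel.eqmask[:, None, None, :]
        resids = resids * panel.eqmask[:, None, :]
        r = resids - np.einsum("pkit,pi->pkt", grads, self.mu)
        prec += np.einsum("pkit,kl,pljt->pij", grads, self.Sinv, grads)
        num += -np.einsum("pkit,kl,plt->pi", grads, self.Sinv, r)
        # probit equation: lagged continuous deviations as regressors
        if self.bvar is not None:
            beq = self.eq_by_out[self.bvar]
            g = np.zeros((P, Kc))
            coef = self._coef(beq)
            for j, term in enumerate(self._terms(beq)):
                if term[0] == "lag" and term[1] in self.cidx:
                    g[:, self.cidx[term[1]]] += coef[:, j]
            if np.any(g):
                rb = self._resid(beq) * panel.eqmask
                n = panel.eqmask.sum(axis=1)
                rbs = rb.sum(axis=1) - n * np.einsum("pi,pi->p", g, self.mu)
                prec += n[:, None, None] * np.einsum("pi,pj->pij", g, g)
                num += -g * rbs[:, None]
        mean = np.linalg.solve(prec, num[:, :, None])[:, :, 0]
        L = np.linalg.cholesky(prec)
        z = rng.standard_normal((P, Kc))
        mu_new = mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
        shift = self.mu - mu_new
        for v in self.cvars:
            self.w[v] = np.where(panel.valid, self.w[v] + shift[:, [self.cidx[v]]], 0.0)
        self.mu = mu_new

    def _update_alpha(self, rng: np.random.Generator) -> None:
        if self.bvar is None or not self.spec.latent_means:
            return
        panel = self.panel
        beq = self.eq_by_out[self.bvar]
        feats = self._term_values(beq) * panel.eqmask
        pred = np.einsum("qpt,pq->pt", feats, self._coef(beq))
        resid = (self.ystar - pred) * panel.eqmask
        n = panel.eqmask.sum(axis=1)
        prec = n + 1.0 / self.psi_a
        num = resid.sum(axis=1) + self.tau_a / self.psi_a
        self.alpha = num / prec + rng.standard_normal(panel.P) / np.sqrt(prec)
        P = panel.P
        pv = 1.0 / self.spec.priors.fixed_var
        tprec = P / self.psi_a + pv
        self.tau_a = float(self.alpha.sum() / self.psi_a / tprec
                           + rng.standard_normal() / np.sqrt(tprec))
        dev = self.alpha - self.tau_a
        a = self.spec.priors.resid_a + 0.5 * P
        b = self.spec.priors.resid_b + 0.5 * float(dev @ dev)
        self.psi_a = float(b / rng.gamma(a))

    def _update_between(self, rng: np.random.Generator) -> None:
        if not self.spec.latent_means or self.Kc == 0:
            return
        panel, spec = self.panel, self.spec
        P, Kc = panel.P, self.Kc
        cov_entries = [(out, ci, col) for out, cols in spec.between_covariates.items()
                       for ci, col in enumerate(cols)]
        d = Kc + len(cov_entries)
        M = np.zeros((P, Kc, d))
        M[:, np.arange(Kc), np.arange(Kc)] = 1.0
        for e_i, (out, ci, col) in enumerate(cov_entries):
            M[:, self.cidx[out], Kc + e_i] = panel.covariates[col]
        Pinv = np.linalg.inv(self.Psi)
        prec = np.einsum("pki,kl,plj->ij", M, Pinv, M) + np.eye(d) / spec.priors.fixed_var
        num = np.einsum("pki,kl,pl->i", M, Pinv, self.mu)
        mean = np.linalg.solve(prec, num)
        L = np.linalg.cholesky(prec)
        theta = mean + np.linalg.solve(L.T, rng.standard_normal(d))
        self.nu = theta[:Kc]
        for e_i, (out, ci, col) in enumerate(cov_entries):
            self.kappa[out][ci] = theta[Kc + e_i]
        mfit = np.einsum("pkd,d->pk", M, theta)
        dev = self.mu - mfit
        scale = spec.priors.iw_scale * np.eye(Kc) + dev.T @ dev
        Winv = wishart.rvs(Kc + 1 + P, np.linalg.inv(scale), random_state=rng)
        self.Psi = np.linalg.inv(np.atleast_2d(Winv))

    def sweep(self, rng: np.random.Generator) -> None:
        self._impute_continuous(rng)
        self._update_binary(rng)
        self._update_random_coefs(rng)
        self._update_fixed_coefs(rng)
        self._update_innovation_cov(rng)
        self._update_latent_means(rng)
        self._update_alpha(rng)
        self._update_between(rng)

    # -- standardization ----------------------------------------------------

    def _within_sds(self) -> dict:
        """Per-person within-level SDs for every variable/regressor role.

        Pure-VAR systems use the model-implied stationary covariance of
        the deviations; systems with binary/interaction regressors fall
        back on empirical SDs of the completed (augmented) series.
        """
        panel = self.panel
        em = panel.eqmask
        n = np.clip(em.sum(axis=1), 1, None)

        def emp_sd(x):
            s = (x * em).sum(axis=1) / n
            v = (x ** 2 * em).sum(axis=1) / n - s ** 2
            return np.sqrt(np.clip(v, 0.0, None))

        sds = {"days": emp_sd(self.panel.day)}
        if self.pure_var:
            Kc = self.Kc
            P = panel.P
            A = np.zeros((P, Kc, Kc))
            for eq in self.eqs:
                coef = self._coef(eq)
                k = self.cidx[eq.outcome]
                for j, term in enumerate(self._terms(eq)):
                    if term[0] == "lag":
                        A[:, k, self.cidx[term[1]]] = coef[:, j]
            kron = np.einsum("pik,pjl->pijkl", A, A).reshape(P, Kc * Kc, Kc * Kc)
            lhs = np.eye(Kc * Kc) - kron
            try:
                vecV = np.linalg.solve(
                    lhs, np.broadcast_to(self.Sig.reshape(-1), (P, Kc * Kc))
                    [:, :, None])[:, :, 0]
                V = vecV.reshape(P, Kc, Kc)
                diag = np.einsum("pkk->pk", V).copy()
                bad = (diag <= 0).any(axis=1)
            except np.linalg.LinAlgError:
                bad = np.ones(P, dtype=bool)
                diag = np.ones((P, Kc))
            for v in self.cvars:
                sd = np.sqrt(np.clip(diag[:, self.cidx[v]], 1e-12, None))
                if bad.any():
                    sd = np.where(bad, emp_sd(self.w[v]), sd)
                sds[v] = sd
        else:
            for v in self.cvars:
                sds[v] = emp_sd(self.w[v])
        if self.bvar is not None:
            sds[self.bvar] = emp_sd(self.bval)
            # latent-response SD for the probit outcome (residual variance 1)
            beq = self.eq_by_out[self.bvar]
            feats = self._term_values(beq)
            pred = np.einsum("qpt,pq->pt", feats, self._coef(beq))
            sds[f"latent({self.bvar})"] = np.sqrt(emp_sd(pred) ** 2 + 1.0)
            for eq in self.eqs:
                for term in self._terms(eq):
                    if term[0] == "inter":
                        key = f"{term[1]}:{term[2]}.l1"
                        sds[key] = emp_sd(self.bval * _shift(self.w[term[2]]))
        return sds

    def _pred_sd(self, term, sds: dict) -> np.ndarray:
        kind = term[0]
        if kind in ("lag", "con"):
            return sds[term[1]]
        if kind == "inter":
            return sds[f"{term[1]}:{term[2]}.l1"]
        return sds["days"]

    def _out_sd(self, eq: Equation, sds: dict) -> np.ndarray:
        if eq.link == "probit":
            return sds[f"latent({eq.outcome})"]
        return sds[eq.outcome]

    def record(self, store: dict, pstore: dict, chain: int, idx: int) -> None:
        sds = self._within_sds()
        for eq in self.eqs:
            coef = self._coef(eq)
            out_sd = self._out_sd(eq, sds)
            ok = out_sd > 0
            for j, (term, name) in enumerate(zip(self._terms(eq), eq.term_names)):
                key = f"{eq.outcome}~{name}"
                raw = self.coefs[eq.outcome]
                if eq.random:
                    o = self.r_offsets[eq.outcome]
                    store[key][chain, idx] = self.gammaR[o + j]
                    pstore[key][chain, idx] = raw[:, j]
                else:
                    store[key][chain, idx] = raw[j]
                ratio = np.where(ok, self._pred_sd(term, sds) / np.where(ok, out_sd, 1),
                                 np.nan)
                store["std:" + key][chain, idx] = float(np.nanmean(coef[:, j] * ratio))
        for v in self.cvars:
            k = self.cidx[v]
            store[f"sigma({v})"][chain, idx] = np.sqrt(self.Sig[k, k])
            if self.spec.latent_means:
                store[f"mu({v})"][chain, idx] = self.nu[k]
                store[f"psi({v})"][chain, idx] = self.Psi[k, k]
        for i, v1 in enumerate(self.cvars):
            for v2 in self.cvars[i + 1:]:
                k, l = self.cidx[v1], self.cidx[v2]
                store[f"rho({v1},{v2})"][chain, idx] = \
                    self.Sig[k, l] / np.sqrt(self.Sig[k, k] * self.Sig[l, l])
        for out, cols in self.spec.between_covariates.items():
            for ci, col in enumerate(cols):
                store[f"mu({out})~{col}"][chain, idx] = self.kappa[out][ci]
        if self.bvar is not None and self.spec.latent_means:
            store[f"alpha({self.bvar})"][chain, idx] = self.tau_a
            store["psi(alpha)"][chain, idx] = self.psi_a
        for eq in self.random_eqs:
            o = self.r_offsets[eq.outcome]
            for j, name in enumerate(eq.term_names):
                store[f"omega({eq.outcome}~{name})"][chain, idx] = \
                    self.Omega[o + j, o + j]

    def scalar_names(self) -> tuple[list, list]:
        names, pnames = [], []
        for eq in self.eqs:
            for name in eq.term_names:
                key = f"{eq.outcome}~{name}"
                names.append(key)
                names.append("std:" + key)
                if eq.random:
                    pnames.append(key)
        for v in self.cvars:
            names.append(f"sigma({v})")
            if self.spec.latent_means:
                names += [f"mu({v})", f"psi({v})"]
        for i, v1 in enumerate(self.cvars):
            for v2 in self.cvars[i + 1:]:
                names.append(f"rho({v1},{v2})")
        for out, cols in self.spec.between_covariates.items():
            for col in cols:
                names.append(f"mu({out})~{col}")
        if self.bvar is not None and self.spec.latent_means:
            names += [f"alpha({self.bvar})", "psi(alpha)"]
        for eq in self.random_eqs:
            for name in eq.term_names:
                names.append(f"omega({eq.outcome}~{name})")
        return names, pnames


# --------------------------------------------------------------------------
# public entry point
# --------------------------------------------------------------------------

def fit_dsem(lattice: pd.DataFrame, spec: DsemSpec) -> DsemResult:
    """Fit a two-level dynamic SEM to grid-aligned data by Gibbs sampling.

    Parameters
    ----------
    lattice
        Output of :func:`emadsem.lattice.align_to_grid` (columns
        ``person_id``, ``bin_index``, ``day_c``, model variables, and
        any between-level covariate columns).
    spec
        Model definition and sampler settings.

    Returns
    -------
    :class:`DsemResult` with the posterior summary (raw and
    within-standardized estimates, 95% credibility intervals, PSR,
    %Pos/%Neg cluster rates for random coefficients) and retained
    draws.  Non-convergence (PSR above the threshold) is flagged in
    ``result.summary.notes`` and via ``result.converged``, never fatal.
    """
    cov_cols = tuple({c for cols in spec.between_covariates.values() for c in cols})
    panel = _Panel(lattice, spec.outcomes, cov_cols)
    sampler = _Gibbs(panel, spec)
    n_burn = int(spec.n_iter * spec.burn_frac)
    kept_iters = range(n_burn, spec.n_iter, spec.thin)
    n_keep = len(kept_iters)
    if n_keep < 2:
        raise ValueError("retained draws < 2; increase n_iter or reduce burn_frac")
    names, pnames = sampler.scalar_names()
    store = {n: np.empty((spec.n_chains, n_keep)) for n in names}
    pstore = {n: np.empty((spec.n_chains, n_keep, panel.P)) for n in pnames}
    kept_set = {it: i for i, it in enumerate(kept_iters)}

    for chain in range(spec.n_chains):
        rng = np.random.default_rng([int(spec.seed) % (2 ** 31), chain])
        sampler.init_state(rng, chain)
        for it in range(spec.n_iter):
            sampler.sweep(rng)
            if it in kept_set:
                sampler.record(store, pstore, chain, kept_set[it])
            if (it + 1) % 500 == 0:
                logger.info("chain %d sweep %d/%d", chain + 1, it + 1, spec.n_iter)

    rows = {}
    raw_names = [n for n in names if not n.startswith("std:")]
    for name in raw_names:
        row = summarize_scalar_draws(store[name])
        skey = "std:" + name
        if skey in store:
            s = summarize_scalar_draws(store[skey])
            row.update(std_mean=s["mean"], std_sd=s["sd"],
                       std_ci_lower=s["ci_lower"], std_ci_upper=s["ci_upper"])
        else:
            row.update(std_mean=np.nan, std_sd=np.nan,
                       std_ci_lower=np.nan, std_ci_upper=np.nan)
        if name in pstore:
            flat = pstore[name].reshape(-1, panel.P)
            pos, neg = cluster_significance_rates(flat)
            row.update(pct_pos=pos, pct_neg=neg)
        else:
            row.update(pct_pos=np.nan, pct_neg=np.nan)
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    summary = PosteriorSummary(table=table, psr_threshold=spec.psr_threshold)
    if not summary.converged:
        summary.notes["psr_warning"] = (
            f"max PSR {summary.max_psr:.3f} exceeds threshold {spec.psr_threshold}")
        logger.warning(summary.notes["psr_warning"])
    std_draws = {n[4:]: store[n] for n in names if n.startswith("std:")}
    draws = {n: store[n] for n in raw_names}
    return DsemResult(summary=summary, draws=draws, std_draws=std_draws,
                      person_draws=pstore, persons=panel.persons, spec=spec,
                      notes={"n_persons": panel.P, "n_bins": panel.T})
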