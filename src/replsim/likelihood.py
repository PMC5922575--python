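"""Simulated likelihood of observed birth histories.

For a mother with births t = 1..T, conditional on her heterogeneity triple
alpha = (a_m, a_b, a_f), the log-likelihood contribution is the sum of

* the first-born mortality probit term (loading theta on a_m),
* for t >= 2: the later-born mortality probit term and the log-interval
  normal density term,
* for t < T: the continuation term log Phi(mu_f),
* for t = T: the partial-observability term
  log[ Phi(-mu_f) + Phi(mu_f) * (1 - Phi((log c - mu_b') / sigma_b)) ],
  where c is the censoring bound (months from the last birth to the earlier
  of the window end and the mother's 45th birthday) and mu_b' the index of
  the unobserved next interval: "no further birth" is a mixture of stopping
  and an interval extending beyond c.

Mortality terms of children whose 12-month follow-up extends beyond the
window (``death_observed == 0``) are skipped.  The marginal likelihood
integrates alpha over N(0, Sigma) by quasi-Monte-Carlo: shifted Halton
triples (bases 2, 3, 5) mapped through the Cholesky factor of Sigma, with
antithetic pairing; draws are fixed per mother across optimizer iterations
(common random numbers), with mother-specific streams derived from
``(seed, mother_id)`` so the dataset likelihood is order-independent.

The :class:`SimulatedLikelihood` evaluator vectorizes the computation over
mothers and draws and supplies the analytic score (validated against finite
differences in the test suite); :func:`conditional_loglik` is a deliberately
plain scalar implementation of the same contribution, used as an internal
cross-check.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import expit, log_ndtr, ndtri
from scipy.stats import qmc

from .datamodel import MotherHistory, build_state
from .model import (
    N_MORT_FIRST,
    N_MORT_LATER,
    N_SPACING,
    VARIANTS,
    ParameterSet,
    decision_row,
    mortality_first_row,
    mortality_later_row,
    psd_cholesky,
)

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _norm_logpdf(x):
    return -0.5 * np.square(x) - _LOG_SQRT_2PI


@lru_cache(maxsize=8)
def _halton_base(m: int) -> np.ndarray:
    """First m unscrambled Halton points in bases (2, 3, 5)."""
    sampler = qmc.Halton(d=3, scramble=False)
    pts = sampler.random(m + 1)[1:]  # drop the origin
    pts.setflags(write=False)
    return pts


def _mother_shift(seed: int, mother_id: str) -> np.ndarray:
    """Deterministic random shift in [0,1)^3 for one mother's Halton stream."""
    h = zlib.crc32(str(mother_id).encode("utf-8"))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), h]))
    return rng.random(3)


def mother_normal_draws(R: int, seed: int, mother_id: str,
                        antithetic: bool = True) -> np.ndarray:
    """R quasi-random standard-normal triples for one mother."""
    if R < 1:
        raise ValueError("R must be >= 1")
    m = (R + 1) // 2 if antithetic else R
    u = (_halton_base(m) + _mother_shift(seed, mother_id)) % 1.0
    u = np.clip(u, 1e-12, 1 - 1e-12)
    z = ndtri(u)
    if antithetic:
        z = np.concatenate([z, -z], axis=0)[:R]
    return z


@dataclass(frozen=True)
class HeterogeneityDraws:
    """Quasi-random standard-normal triples z; the heterogeneity draws are
    alpha = z @ L' with L the Cholesky factor of Sigma_alpha, recomputed at
    each parameter value so the z stream is common across iterations."""

    z: np.ndarray        # (R, 3)
    antithetic: bool
    seed: int

    @property
    def R(self) -> int:
        return self.z.shape[0]

    @classmethod
    def for_mother(cls, R: int, seed: int, mother_id: str,
                   antithetic: bool = True) -> "HeterogeneityDraws":
        return cls(z=mother_normal_draws(R, seed, mother_id, antithetic),
                   antithetic=antithetic, seed=seed)

    def alphas(self, params: ParameterSet) -> np.ndarray:
        return self.z @ params.chol_alpha().T


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def conditional_loglik(history: MotherHistory, params: ParameterSet,
                       alpha, variant: str = "benchmark",
                       interval_age: str = "decision") -> float:
    """Log-likelihood of one history conditional on alpha = (a_m, a_b, a_f).

    Scalar reference implementation (the vectorized evaluator is cross-checked
    against it).  ``interval_age`` selects which birth's maternal age enters
    the interval equation: the decision epoch (birth t-1, default) or the
    birth ending the interval.
    """
    _check_variant(variant)
    if params.sigma_b <= 0:
        raise ValueError("sigma_b must be > 0")
    c = history.censor_bound()
    if c <= 0:
        raise ValueError(
            f"mother {history.mother_id}: last birth at or after the censor "
            "bound (c <= 0)")
    am, ab, af = (float(a) for a in alpha)
    logistic = variant == "logistic_mortality"

    def log_g(x: float) -> float:
        if logistic:
            return -np.logaddexp(0.0, -x)
        return float(log_ndtr(x))

    cov = history.covariates
    T = history.n_births
    sig = params.sigma_b
    ll = 0.0
    for t in range(1, T + 1):
        ev = history.births[t - 1]
        if ev.death_observed:
            if t == 1:
                z = float(
                    mortality_first_row(cov, history.age_at_first_birth, ev.male)
                    @ params.beta_first) + params.theta * am
            else:
                z = float(mortality_later_row(cov, build_state(history, t),
                                              ev.male) @ params.beta_mort) + am
            s = 1.0 if ev.infant_death else -1.0
            ll += log_g(s * z)
        if t >= 2:
            st_prev = build_state(history, t - 1)
            age = (history.age_at_birth(t) if interval_age == "at_birth"
                   else None)
            mu = float(decision_row(cov, st_prev, age=age)
                       @ params.beta_interval) + ab
            r = (math.log(history.interval_before(t)) - mu) / sig
            ll += float(_norm_logpdf(r)) - math.log(sig)
        if variant != "no_fertility_eq" and t < T:
            mu_f = float(decision_row(cov, build_state(history, t))
                         @ params.beta_fert) + af
            ll += float(log_ndtr(mu_f))
    st_T = build_state(history, T)
    mu_b_next = float(decision_row(cov, st_T) @ params.beta_interval) + ab
    q = (math.log(c) - mu_b_next) / sig
    if variant == "no_fertility_eq":
        ll += float(log_ndtr(-q))
    else:
        mu_f = float(decision_row(cov, st_T) @ params.beta_fert) + af
        ll += float(np.logaddexp(log_ndtr(-mu_f),
                                 log_ndtr(mu_f) + log_ndtr(-q)))
    return ll


def simulated_loglik(history: MotherHistory, params: ParameterSet,
                     draws: HeterogeneityDraws,
                     variant: str = "benchmark",
                     interval_age: str = "decision") -> float:
    """Log of the draw-average of exp(conditional log-likelihood), via
    log-sum-exp.  With Sigma_alpha = 0 every draw collapses to alpha = 0 and
    the result equals the conditional log-likelihood exactly, for any R."""
    ev = SimulatedLikelihood([history], variant=variant, R=draws.R,
                             seed=draws.seed, antithetic=draws.antithetic,
                             interval_age=interval_age)
    ev._Z = draws.z[np.newaxis, :, :]
    return float(ev.loglik_by_mother(params)[0])


def dataset_loglik(histories, params: ParameterSet, R: int = 100,
                   seed: int = 0, variant: str = "benchmark",
                   antithetic: bool = True, interval_age: str = "decision"):
    """Total simulated log-likelihood and the per-mother vector (retained for
    OPG standard errors).  Mother draw streams depend only on
    ``(seed, mother_id)``, so the total is invariant to mother order."""
    ev = SimulatedLikelihood(histories, variant=variant, R=R, seed=seed,
                             antithetic=antithetic, interval_age=interval_age)
    per_mother = ev.loglik_by_mother(params)
    # sum in canonical id order so the total is bit-identical under any
    # permutation of the input histories
    order = np.argsort([str(h.mother_id) for h in histories], kind="stable")
    return float(per_mother[order].sum()), per_mother


def _segment_sum(x: np.ndarray, starts: np.ndarray, ends: np.ndarray
                 ) -> np.ndarray:
    """Sum contiguous row segments of x; empty segments yield zero.

    Summation stays within each segment (no running total across segments),
    so a mother's value is bit-identical under any permutation of mothers."""
    if x.shape[0] == 0:
        return np.zeros((len(starts),) + x.shape[1:])
    idx = np.minimum(starts, x.shape[0] - 1)
    out = np.add.reduceat(x, idx, axis=0)
    out[starts == ends] = 0.0
    return out


class SimulatedLikelihood:
    """Vectorized simulated log-likelihood over a dataset of histories.

    Precomputes all design matrices and quasi-random draw streams once, then
    evaluates the log-likelihood (and its analytic score) as a function of
    the parameters.  Also owns the packed free-parameter vector for each
    model variant:

    * benchmark / logistic_mortality: 15 + 1 + 21 + 22 + 1 + 22 + 6 = 88
    * no_heterogeneity:               15 + 21 + 22 + 1 + 22        = 81
    * no_fertility_eq:                15 + 1 + 21 + 22 + 1 + 3     = 63

    The covariance of (a_m, a_b, a_f) is parameterized by its Cholesky factor
    with log-diagonal (order: log L00, L10, log L11, L20, L21, log L22), which
    keeps it positive semi-definite throughout optimization.
    """

    def __init__(self, histories, variant: str = "benchmark", R: int = 100,
                 seed: int = 0, antithetic: bool = True,
                 interval_age: str = "decision"):
        _check_variant(variant)
        if interval_age not in ("decision", "at_birth"):
            raise ValueError("interval_age must be 'decision' or 'at_birth'")
        if not histories:
            raise ValueError("no histories")
        self.variant = variant
        self.interval_age = interval_age
        self.R = 1 if variant == "no_heterogeneity" else int(R)
        self.seed = int(seed)
        self.antithetic = antithetic
        self.n = len(histories)
        self._build_designs(histories)
        if variant == "no_heterogeneity":
            self._Z = np.zeros((self.n, 1, 3))
        else:
            self._Z = np.stack([
                mother_normal_draws(self.R, seed, h.mother_id, antithetic)
                for h in histories
            ])

    # -- design construction -------------------------------------------------

    def _build_designs(self, histories) -> None:
        D1, M1, obs1, logc, Dlast = [], [], [], [], []
        Dm, Db, Df, Ml, obsl, logb, midx = [], [], [], [], [], [], []
        counts = np.zeros(self.n, dtype=int)
        for i, h in enumerate(histories):
            c = h.censor_bound()
            if c <= 0:
                raise ValueError(
                    f"mother {h.mother_id}: last birth at or after the censor "
                    "bound (c <= 0)")
            cov = h.covariates
            first = h.births[0]
            D1.append(mortality_first_row(cov, h.age_at_first_birth, first.male))
            M1.append(first.infant_death)
            obs1.append(first.death_observed)
            logc.append(math.log(c))
            T = h.n_births
            counts[i] = T - 1
            for t in range(2, T + 1):
                ev = h.births[t - 1]
                st = build_state(history=h, t=t)
                st_prev = build_state(history=h, t=t - 1)
                Dm.append(mortality_later_row(cov, st, ev.male))
                age = (h.age_at_birth(t) if self.interval_age == "at_birth"
                       else None)
                Db.append(decision_row(cov, st_prev, age=age))
                Df.append(decision_row(cov, st_prev))
                Ml.append(ev.infant_death)
                obsl.append(ev.death_observed)
                logb.append(math.log(h.interval_before(t)))
                midx.append(i)
            Dlast.append(decision_row(cov, build_state(h, T)))
        self.D1 = np.asarray(D1)
        self.M1 = np.asarray(M1, dtype=float)
        self.s1 = 2.0 * self.M1 - 1.0
        self.obs1 = np.asarray(obs1, dtype=float)
        self.logc = np.asarray(logc)
        self.Dlast = np.asarray(Dlast)
        nb = len(Dm)
        self.nb = nb
        shape = (nb, N_MORT_LATER) if nb else (0, N_MORT_LATER)
        self.Dm = np.asarray(Dm).reshape(shape)
        self.Db = np.asarray(Db).reshape((nb, N_SPACING))
        self.Df = np.asarray(Df).reshape((nb, N_SPACING))
        self.Ml = np.asarray(Ml, dtype=float)
        self.sl = 2.0 * self.Ml - 1.0
        self.obsl = np.asarray(obsl, dtype=float)
        self.logb = np.asarray(logb, dtype=float)
        self.midx = np.asarray(midx, dtype=int)
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.ends = self.starts + counts
        self.n_obs = self.n + nb  # total children

    # -- packing -------------------------------------------------------------

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    @property
    def param_names(self) -> list[str]:
        b1 = [f"first:{i}" for i in range(N_MORT_FIRST)]
        bm = [f"mort:{i}" for i in range(N_MORT_LATER)]
        bb = [f"interval:{i}" for i in range(N_SPACING)]
        bf = [f"fert:{i}" for i in range(N_SPACING)]
        chol6 = ["chol:log_l00", "chol:l10", "chol:log_l11",
                 "chol:l20", "chol:l21", "chol:log_l22"]
        if self.variant == "no_heterogeneity":
            return b1 + bm + bb + ["log_sigma_b"] + bf
        if self.variant == "no_fertility_eq":
            return b1 + ["theta"] + bm + bb + ["log_sigma_b"] + chol6[:3]
        return b1 + ["theta"] + bm + bb + ["log_sigma_b"] + bf + chol6

    def pack(self, params: ParameterSet) -> np.ndarray:
        L = params.chol_alpha()
        def logd(x):
            return math.log(max(x, 1e-8))
        chol6 = [logd(L[0, 0]), L[1, 0], logd(L[1, 1]),
                 L[2, 0], L[2, 1], logd(L[2, 2])]
        ls = math.log(params.sigma_b)
        if self.variant == "no_heterogeneity":
            return np.concatenate([params.beta_first, params.beta_mort,
                                   params.beta_interval, [ls], params.beta_fert])
        if self.variant == "no_fertility_eq":
            return np.concatenate([params.beta_first, [params.theta],
                                   params.beta_mort, params.beta_interval,
                                   [ls], chol6[:3]])
        return np.concatenate([params.beta_first, [params.theta],
                               params.beta_mort, params.beta_interval, [ls],
                               params.beta_fert, chol6])

    def unpack(self, x: np.ndarray) -> ParameterSet:
        x = np.asarray(x, dtype=float)
        i = 0
        b1 = x[i:i + N_MORT_FIRST]; i += N_MORT_FIRST
        if self.variant == "no_heterogeneity":
            theta = 0.0
        else:
            theta = float(x[i]); i += 1
        bm = x[i:i + N_MORT_LATER]; i += N_MORT_LATER
        bb = x[i:i + N_SPACING]; i += N_SPACING
        sig = math.exp(float(x[i])); i += 1
        if self.variant == "no_fertility_eq":
            bf = np.zeros(N_SPACING)
        else:
            bf = x[i:i + N_SPACING]; i += N_SPACING
        L = np.zeros((3, 3))
        if self.variant == "no_fertility_eq":
            L[0, 0] = math.exp(float(x[i]))
            L[1, 0] = float(x[i + 1])
            L[1, 1] = math.exp(float(x[i + 2]))
            i += 3
        elif self.variant != "no_heterogeneity":
            L[0, 0] = math.exp(float(x[i]))
            L[1, 0] = float(x[i + 1])
            L[1, 1] = math.exp(float(x[i + 2]))
            L[2, 0] = float(x[i + 3])
            L[2, 1] = float(x[i + 4])
            L[2, 2] = math.exp(float(x[i + 5]))
            i += 6
        assert i == len(x), "parameter vector length mismatch"
        return ParameterSet(beta_first=b1, theta=theta, beta_mort=bm,
                            beta_interval=bb, sigma_b=sig, beta_fert=bf,
                            cov_alpha=L @ L.T)

    def _chol_from(self, params: ParameterSet) -> np.ndarray:
        return psd_cholesky(params.cov_alpha)

    def param_scale(self) -> np.ndarray:
        """Per-parameter scale factors (RMS of the matching design column) for
        preconditioning the optimizer; auxiliary parameters get scale 1."""
        def rms(D):
            if D.shape[0] == 0:
                return np.ones(D.shape[1])
            return np.sqrt(np.maximum(np.mean(np.square(D), axis=0), 1e-4))

        parts = [rms(self.D1)]
        if self.variant != "no_heterogeneity":
            parts.append(np.ones(1))          # theta
        parts.append(rms(self.Dm))
        parts.append(rms(np.vstack([self.Db, self.Dlast])))
        parts.append(np.ones(1))              # log sigma_b
        if self.variant != "no_fertility_eq":
            parts.append(rms(np.vstack([self.Df, self.Dlast])))
        if self.variant == "no_fertility_eq":
            parts.append(np.ones(3))
        elif self.variant != "no_heterogeneity":
            parts.append(np.ones(6))
        return np.concatenate(parts)

    # -- evaluation ----------------------------------------------------------

    def _terms(self, params: ParameterSet):
        """Conditional log-likelihood matrix C (n, R) and the intermediates
        needed for the score."""
        L = self._chol_from(params)
        A = self._Z @ L.T                      # (n, R, 3)
        am, ab, af = A[..., 0], A[..., 1], A[..., 2]
        sig = params.sigma_b
        logistic = self.variant == "logistic_mortality"

        if logistic:
            def log_g(x):
                return -np.logaddexp(0.0, -x)
        else:
            log_g = log_ndtr

        z1 = (self.D1 @ params.beta_first)[:, None] + params.theta * am
        ll1 = self.obs1[:, None] * log_g(self.s1[:, None] * z1)

        mi = self.midx
        zm = (self.Dm @ params.beta_mort)[:, None] + am[mi]
        llm = self.obsl[:, None] * log_g(self.sl[:, None] * zm)
        mu_b = (self.Db @ params.beta_interval)[:, None] + ab[mi]
        r = (self.logb[:, None] - mu_b) / sig
        llb = _norm_logpdf(r) - math.log(sig)
        if self.variant == "no_fertility_eq":
            zf = np.zeros_like(zm)
            llf = 0.0
        else:
            zf = (self.Df @ params.beta_fert)[:, None] + af[mi]
            llf = log_ndtr(zf)

        mu_bl = (self.Dlast @ params.beta_interval)[:, None] + ab
        q = (self.logc[:, None] - mu_bl) / sig
        if self.variant == "no_fertility_eq":
            mu_fl = np.zeros_like(q)
            ll_last = log_ndtr(-q)
        else:
            mu_fl = (self.Dlast @ params.beta_fert)[:, None] + af
            ll_last = np.logaddexp(log_ndtr(-mu_fl),
                                   log_ndtr(mu_fl) + log_ndtr(-q))

        C = ll1 + _segment_sum(llm + llb + llf, self.starts, self.ends) + ll_last
        return C, dict(z1=z1, zm=zm, r=r, zf=zf, q=q, mu_fl=mu_fl,
                       ll_last=ll_last, am=am, sig=sig, L=L)

    def conditional_matrix(self, params: ParameterSet) -> np.ndarray:
        return self._terms(params)[0]

    def loglik_by_mother(self, params: ParameterSet) -> np.ndarray:
        C = self.conditional_matrix(params)
        cmax = C.max(axis=1)
        with np.errstate(divide="ignore"):
            out = cmax + np.log(np.mean(np.exp(C - cmax[:, None]), axis=1))
        return np.where(np.isfinite(cmax), out, -np.inf)

    def loglik(self, params: ParameterSet) -> float:
        return float(self.loglik_by_mother(params).sum())

    def loglik_and_scores(self, params: ParameterSet):
        """Total log-likelihood, gradient, and per-mother score matrix on the
        packed parameter scale."""
        C, t = self._terms(params)
        cmax = C.max(axis=1, keepdims=True)
        E = np.exp(C - cmax)
        denom = E.sum(axis=1, keepdims=True)
        w = E / denom                                     # softmax over draws
        ll_i = (cmax[:, 0] + np.log(denom[:, 0] / self.R))

        sig = t["sig"]
        logistic = self.variant == "logistic_mortality"
        mi = self.midx

        def probit_mills(s, z):
            sz = s * z
            return s * np.exp(_norm_logpdf(sz) - log_ndtr(sz))

        def mort_mills(s, z):
            # d/dz of the mortality term's log CDF (probit or logistic link)
            if logistic:
                return s * expit(-s * z)
            return probit_mills(s, z)

        lam1 = self.obs1[:, None] * mort_mills(self.s1[:, None], t["z1"])
        lamm = self.obsl[:, None] * mort_mills(self.sl[:, None], t["zm"])
        lamb = t["r"] / sig
        no_fert = self.variant == "no_fertility_eq"
        lamf = 0.0 if no_fert else probit_mills(1.0, t["zf"])

        q, mu_fl, ll_last = t["q"], t["mu_fl"], t["ll_last"]
        if no_fert:
            d_mu_f = np.zeros_like(q)
            base = np.exp(_norm_logpdf(q) - ll_last)
            d_mu_bl = base / sig
            d_sig_last = base * q / sig
        else:
            d_mu_f = -np.exp(_norm_logpdf(mu_fl) + log_ndtr(q) - ll_last)
            base = np.exp(log_ndtr(mu_fl) + _norm_logpdf(q) - ll_last)
            d_mu_bl = base / sig
            d_sig_last = base * q / sig

        n, k = self.n, self.n_free
        S = np.empty((n, k))
        wm = w[mi]

        def seg_rows(coefs, D):
            # per-mother sum over births of coefs_b * D_b
            return _segment_sum(coefs[:, None] * D, self.starts, self.ends)

        c1 = (w * lam1).sum(axis=1)
        s_b1 = c1[:, None] * self.D1
        s_theta = (w * lam1 * t["am"]).sum(axis=1)
        s_bm = seg_rows((wm * lamm).sum(axis=1), self.Dm)
        cb = (wm * lamb).sum(axis=1)
        s_bb = seg_rows(cb, self.Db) + (w * d_mu_bl).sum(axis=1)[:, None] * self.Dlast
        # log sigma score: interval densities plus the censored last term
        seg_r2 = _segment_sum(np.square(t["r"]) - 1.0, self.starts, self.ends)
        s_lsig = (w * seg_r2).sum(axis=1) + sig * (w * d_sig_last).sum(axis=1)
        if not no_fert:
            cf = (wm * lamf).sum(axis=1)
            s_bf = seg_rows(cf, self.Df) + (w * d_mu_f).sum(axis=1)[:, None] * self.Dlast

        # heterogeneity directions: dC/d alpha_j per (mother, draw)
        g_m = params.theta * lam1 + _segment_sum(lamm, self.starts, self.ends)
        g_b = _segment_sum(lamb, self.starts, self.ends) + d_mu_bl
        if no_fert:
            g_f = np.zeros_like(g_b)
        else:
            g_f = _segment_sum(lamf, self.starts, self.ends) + d_mu_f

        L = t["L"]
        Z = self._Z

        def chol_score(j, kk, log_scale):
            s = (w * [g_m, g_b, g_f][j] * Z[:, :, kk]).sum(axis=1)
            return s * L[j, kk] if log_scale else s

        i = 0
        S[:, i:i + N_MORT_FIRST] = s_b1; i += N_MORT_FIRST
        if self.variant != "no_heterogeneity":
            S[:, i] = s_theta; i += 1
        S[:, i:i + N_MORT_LATER] = s_bm; i += N_MORT_LATER
        S[:, i:i + N_SPACING] = s_bb; i += N_SPACING
        S[:, i] = s_lsig; i += 1
        if not no_fert:
            S[:, i:i + N_SPACING] = s_bf; i += N_SPACING
        if self.variant == "no_fertility_eq":
            S[:, i] = chol_score(0, 0, True)
            S[:, i + 1] = chol_score(1, 0, False)
            S[:, i + 2] = chol_score(1, 1, True)
            i += 3
        elif self.variant != "no_heterogeneity":
            S[:, i] = chol_score(0, 0, True)
            S[:, i + 1] = chol_score(1, 0, False)
            S[:, i + 2] = chol_score(1, 1, True)
            S[:, i + 3] = chol_score(2, 0, False)
            S[:, i + 4] = chol_score(2, 1, False)
            S[:, i + 5] = chol_score(2, 2, True)
            i += 6
        assert i == k
        return float(ll_i.sum()), S.sum(axis=0), S
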