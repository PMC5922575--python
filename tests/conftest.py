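"""Shared fixtures: small synthetic populations, toy parameter sets, and the
moderate-heterogeneity covariance used in numerical-integration checks."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import replsim
from replsim.datamodel import BirthEvent, CovariateVector, MotherHistory
from replsim.model import ParameterSet

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Moderate, correlated heterogeneity: variances on the scale the model
#: estimates for its mortality/interval equations.
TOY_COV = np.array([
    [0.3, 0.1, -0.1],
    [0.1, 0.2, 0.05],
    [-0.1, 0.05, 0.5],
])


@pytest.fixture(scope="session")
def preset() -> ParameterSet:
    return replsim.comparison_area_params()


@pytest.fixture()
def toy_cov() -> CovariateVector:
    return CovariateVector(muslim=1, cohort=2, mother_edu=1, father_edu=0,
                           day_labourer=0, hygienic_water=1, distance_km=5.0)


def moderate_params(cov_alpha=None, sigma_b: float = 0.45) -> ParameterSet:
    """Constants-only parameter set with moderate event probabilities:
    ~10% first-born mortality, ~7% later mortality, 30-month median interval,
    69% continuation."""
    p = ParameterSet.zeros(sigma_b=sigma_b)
    p.beta_first[-1] = -1.3
    p.beta_mort[-1] = -1.5
    p.beta_interval[-1] = math.log(30.0)
    p.beta_fert[-1] = 0.5
    if cov_alpha is not None:
        p.cov_alpha = np.asarray(cov_alpha, dtype=float)
    p.__post_init__()
    return p


@pytest.fixture()
def toy_params() -> ParameterSet:
    return moderate_params(TOY_COV)


@pytest.fixture()
def two_birth_history(toy_cov) -> MotherHistory:
    return MotherHistory(
        mother_id="toy", covariates=toy_cov, age_at_first_birth=21.0,
        births=[BirthEvent(1, 30.0, "M", 1), BirthEvent(2, 60.0, "F", 0)],
    )


@pytest.fixture(scope="session")
def small_mothers():
    cfg = replsim.default_config("comparison", n_mothers=60, seed=0)
    return replsim.generate_mothers(cfg), cfg


@pytest.fixture(scope="session")
def small_histories(small_mothers, preset):
    mothers, cfg = small_mothers
    params = replsim.calibrated_dgp(mothers, params=preset)
    return replsim.simulate_histories(mothers, params, seed=0,
                                      male_p=cfg.male_p)


def outcome_space_total(params, cov, age_fb: float = 21.0,
                        first: float = 100.0, n_grid: int = 4001) -> float:
    """Total model probability over every observable outcome of a
    2-birth-maximum discretized toy: first-born death/survival, stop/censor
    vs continue, the second interval on a fine log grid plus its censored
    mass, second-born death/survival, and (as a lump) the probability of
    continuing beyond the second birth.  Should be 1 up to grid error and the
    negligible interval mass below the 9-month floor."""
    from scipy.special import log_ndtr, ndtr

    from replsim.datamodel import BirthEvent, MotherHistory, build_state
    from replsim.likelihood import conditional_loglik
    from replsim.model import decision_row

    p = params
    total = 0.0
    for m1 in (0, 1):
        h1 = MotherHistory("t", cov, age_fb, [BirthEvent(1, first, "M", m1)])
        total += math.exp(conditional_loglik(h1, p, (0, 0, 0)))
        c1 = h1.censor_bound()
        lo = max(math.log(9.0), p.beta_interval[-1] - 9 * p.sigma_b)
        hi = min(math.log(c1) - 1e-9, p.beta_interval[-1] + 9 * p.sigma_b)
        logb = np.linspace(lo, hi, n_grid)
        dlog = logb[1] - logb[0]
        trap = np.full(len(logb), dlog)
        trap[0] = trap[-1] = dlog / 2.0
        for lb, wcell in zip(logb, trap):
            b = math.exp(lb)
            for m2 in (0, 1):
                h2 = MotherHistory(
                    "t", cov, age_fb,
                    [BirthEvent(1, first, "M", m1),
                     BirthEvent(2, first + b, "F", m2)])
                mass = math.exp(conditional_loglik(h2, p, (0, 0, 0))) * wcell
                st = build_state(h2, 2)
                mu_f = float(decision_row(cov, st) @ p.beta_fert)
                mu_b = float(decision_row(cov, st) @ p.beta_interval)
                c2 = h2.censor_bound()
                q = (math.log(c2) - mu_b) / p.sigma_b
                beyond = ndtr(mu_f) * ndtr(q)
                final = math.exp(np.logaddexp(
                    log_ndtr(-mu_f), log_ndtr(mu_f) + log_ndtr(-q)))
                total += mass + mass / final * beyond
    return total


def gauss_hermite_loglik(history, params, n_nodes: int = 15,
                         variant: str = "benchmark") -> float:
    """Independent oracle: marginal log-likelihood by tensor-product
    Gauss-Hermite quadrature over the heterogeneity triple."""
    from replsim.likelihood import conditional_loglik

    L = params.chol_alpha()
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    Z = np.stack(np.meshgrid(nodes, nodes, nodes, indexing="ij"), -1
                 ).reshape(-1, 3)
    W = (wts[:, None, None] * wts[None, :, None] * wts[None, None, :]
         ).ravel() / np.pi ** 1.5
    A = np.sqrt(2.0) * Z @ L.T
    vals = np.array([conditional_loglik(history, params, a, variant=variant)
                     for a in A])
    m = vals.max()
    return float(m + np.log(np.sum(W * np.exp(vals - m))))
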