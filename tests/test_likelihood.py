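"""Likelihood: closed forms, outcome-space coherence, quadrature agreement,
draw-stream contracts and the analytic score."""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

import replsim
from replsim.datamodel import BirthEvent, MotherHistory, build_state
from replsim.likelihood import (
    HeterogeneityDraws,
    SimulatedLikelihood,
    conditional_loglik,
    dataset_loglik,
    mother_normal_draws,
    simulated_loglik,
)
from replsim.model import ParameterSet, decision_row

from conftest import TOY_COV, gauss_hermite_loglik, moderate_params


def _single_birth(toy_cov, died=0, first=100.0, age_fb=21.0):
    return MotherHistory("s", toy_cov, age_fb,
                         [BirthEvent(1, first, "M", died)])


class TestConditional:
    def test_single_birth_closed_form(self, toy_cov):
        """All coefficients zero, sigma_b = 1: the contribution is
        log Phi(0) + log[Phi(0) + Phi(0)(1 - Phi(log c))]."""
        p = ParameterSet.zeros(sigma_b=1.0)
        h = _single_birth(toy_cov)
        c = h.censor_bound()
        expect = math.log(0.5) + math.log(0.5 + 0.5 * (1 - ndtr(math.log(c))))
        assert conditional_loglik(h, p, (0, 0, 0)) == pytest.approx(expect)

    def test_logistic_equals_probit_at_zero_index(self, toy_cov):
        """Both CDFs are 1/2 at index 0, so the mortality term agrees."""
        p = ParameterSet.zeros(sigma_b=1.0)
        h = _single_birth(toy_cov, died=1)
        lp = conditional_loglik(h, p, (0, 0, 0), variant="benchmark")
        ll = conditional_loglik(h, p, (0, 0, 0), variant="logistic_mortality")
        assert lp == pytest.approx(ll)

    def test_unobserved_death_contributes_no_mortality_term(self, toy_cov):
        p = moderate_params()
        h1 = MotherHistory("u", toy_cov, 21.0,
                           [BirthEvent(1, 275.0, "M", 0, death_observed=0)])
        h2 = MotherHistory("u", toy_cov, 21.0,
                           [BirthEvent(1, 275.0, "M", 1, death_observed=0)])
        assert conditional_loglik(h1, p, (0, 0, 0)) == \
            pytest.approx(conditional_loglik(h2, p, (0, 0, 0)))

    def test_censor_bound_error(self, toy_cov):
        # a mother giving birth exactly at the reproductive limit leaves no
        # observable window for the continuation outcome
        h = _single_birth(toy_cov, age_fb=45.0, first=100.0)
        with pytest.raises(ValueError, match="censor"):
            conditional_loglik(h, moderate_params(), (0, 0, 0))

    def test_probability_terms_bounded(self, toy_params, two_birth_history):
        """Each history's conditional likelihood is a product of probabilities
        and densities; the discrete part (dropping the interval density) is a
        probability, so the total minus the density term is <= 0."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(0, 1.5, size=3)
            ll = conditional_loglik(two_birth_history, toy_params, a)
            logb = math.log(30.0)
            mu = toy_params.beta_interval[-1] + a[1]
            dens = norm.logpdf(logb, mu, toy_params.sigma_b)
            assert ll - dens <= 1e-12

    def test_outcome_space_sums_to_one(self, toy_cov):
        """Enumerating every observable outcome of a 2-birth-maximum
        discretized toy -- death or survival, stop/censor vs continue, the
        interval on a fine grid plus its censored mass, and the probability of
        continuing beyond the second birth -- the model probabilities sum
        to 1 (sigma small enough that interval mass below the 9-month floor
        is ~3e-5)."""
        from conftest import outcome_space_total
        total = outcome_space_total(moderate_params(sigma_b=0.3), toy_cov)
        assert total == pytest.approx(1.0, abs=1e-4)


class TestSimulated:
    def test_zero_covariance_collapses_to_conditional(self, toy_cov):
        p = moderate_params()  # cov_alpha = 0
        h = _single_birth(toy_cov)
        cond = conditional_loglik(h, p, (0.0, 0.0, 0.0))
        for R in (1, 7, 32):
            d = HeterogeneityDraws.for_mother(R, 5, h.mother_id)
            # identical up to float summation order in the vectorized path
            assert simulated_loglik(h, p, d) == pytest.approx(cond, abs=1e-12)

    def test_matches_gauss_hermite_quadrature(self, toy_params,
                                              two_birth_history):
        gh = gauss_hermite_loglik(two_birth_history, toy_params)
        d = HeterogeneityDraws.for_mother(20_000, 0, "toy")
        sl = simulated_loglik(two_birth_history, toy_params, d)
        assert sl == pytest.approx(gh, abs=5e-4)

    def test_antithetic_pairs_sum_to_zero_and_reproduce(self):
        z = mother_normal_draws(64, 3, "abc")
        assert np.allclose(z[:32] + z[32:], 0.0)
        z2 = mother_normal_draws(64, 3, "abc")
        assert np.array_equal(z, z2)
        assert not np.array_equal(z, mother_normal_draws(64, 4, "abc"))

    def test_antithetic_consistent_with_raw_stream(self, toy_params,
                                                   two_birth_history):
        """Antithetic on vs off converge to the same marginal likelihood
        within the Monte-Carlo error implied by the draw variance."""
        h, p = two_birth_history, toy_params
        R = 40_000
        d_on = HeterogeneityDraws.for_mother(R, 1, h.mother_id, True)
        d_off = HeterogeneityDraws.for_mother(R, 2, h.mother_id, False)
        ll_on = simulated_loglik(h, p, d_on)
        ll_off = simulated_loglik(h, p, d_off)
        # draw-variance error estimate for the raw stream
        ev = SimulatedLikelihood([h], R=R, seed=2, antithetic=False)
        C = ev.conditional_matrix(p)[0]
        wts = np.exp(C - C.max())
        se = wts.std() / wts.mean() / math.sqrt(R)
        assert abs(ll_on - ll_off) <= 3 * max(se, 1e-5)

    def test_extreme_tail_stays_finite(self, toy_cov):
        """log-space evaluation survives events of probability ~exp(-1800):
        the draw average is computed via log-sum-exp, so no exp() underflow
        corrupts the result."""
        p = moderate_params()
        p.beta_first[-1] = -60.0  # died=1 outcome has probability ~1e-785
        h = _single_birth(toy_cov, died=1)
        d = HeterogeneityDraws.for_mother(8, 0, h.mother_id)
        ll = simulated_loglik(h, p, d)
        assert np.isfinite(ll) and ll < -1500


class TestDataset:
    def test_order_independence_and_additivity(self, small_histories, preset):
        ll, per = dataset_loglik(small_histories, preset, R=16, seed=3)
        perm = list(reversed(small_histories))
        ll2, per2 = dataset_loglik(perm, preset, R=16, seed=3)
        assert ll == ll2
        assert np.allclose(sorted(per), sorted(per2))
        # doubling the dataset doubles the log-likelihood (fresh ids so the
        # duplicated mothers keep their draw streams)
        doubled = small_histories + [
            dataclasses.replace(h) for h in small_histories]
        ll3, _ = dataset_loglik(doubled, preset, R=16, seed=3)
        assert ll3 == pytest.approx(2 * ll, rel=1e-12)

    def test_evaluator_matches_scalar_reference(self, small_histories, preset):
        """Dual route: the vectorized conditional matrix equals the plain
        scalar implementation draw for draw, for every variant."""
        hs = small_histories[:12]
        for variant in ("benchmark", "logistic_mortality", "no_fertility_eq"):
            ev = SimulatedLikelihood(hs, variant=variant, R=6, seed=9)
            C = ev.conditional_matrix(preset)
            L = preset.chol_alpha()
            for i, h in enumerate(hs):
                alphas = ev._Z[i] @ L.T
                for r in range(6):
                    assert C[i, r] == pytest.approx(
                        conditional_loglik(h, preset, alphas[r],
                                           variant=variant), abs=1e-10)

    def test_analytic_score_matches_finite_differences(self, small_histories,
                                                       preset):
        """The simulated log-likelihood is smooth in the parameters and its
        analytic score agrees with central finite differences."""
        hs = small_histories[:25]
        for variant in ("benchmark", "no_heterogeneity", "no_fertility_eq",
                        "logistic_mortality"):
            ev = SimulatedLikelihood(hs, variant=variant, R=6, seed=1)
            x0 = ev.pack(preset)
            ll, g, S = ev.loglik_and_scores(ev.unpack(x0))
            assert np.allclose(S.sum(axis=0), g)
            step = 1e-6
            for j in range(0, len(x0), 7):  # spot-check every 7th direction
                xp, xm = x0.copy(), x0.copy()
                xp[j] += step
                xm[j] -= step
                fd = (ev.loglik(ev.unpack(xp)) - ev.loglik(ev.unpack(xm))) \
                    / (2 * step)
                assert g[j] == pytest.approx(fd, rel=5e-4, abs=5e-4)

    def test_pack_unpack_round_trip(self, small_histories, preset):
        for variant in ("benchmark", "no_heterogeneity", "no_fertility_eq"):
            ev = SimulatedLikelihood(small_histories[:5], variant=variant, R=2)
            q = ev.unpack(ev.pack(preset))
            assert np.allclose(q.beta_first, preset.beta_first)
            assert np.allclose(q.beta_interval, preset.beta_interval)
            assert q.sigma_b == pytest.approx(preset.sigma_b)
            if variant == "benchmark":
                assert np.allclose(q.cov_alpha, preset.cov_alpha, atol=1e-12)
                assert np.allclose(q.beta_fert, preset.beta_fert)
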