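"""Group index, linear predictor, and log-density kernels vs closed forms."""

import numpy as np
import pytest
from scipy.linalg import cholesky
from scipy.special import gammaln

from svcmix import Parameters, PriorSpec, quantize_components
from svcmix.data import QuantizedComponents
from svcmix.likelihood import (
    dirichlet_logpdf,
    group_index,
    linear_predictor,
    linear_predictors,
    log_likelihood,
    log_posterior,
    log_prior,
    mvn_field_logpdf,
)
from svcmix.spatial import correlation_matrix


def _quantized(scores: dict, q=4):
    return QuantizedComponents({k: np.asarray(v, dtype=np.int64) for k, v in scores.items()}, q)


def _params(n, omega, beta0=None, beta=None, theta=(), rho=0.5, tau=None, sigma_theta=()):
    c = len(omega)
    return Parameters(
        beta0=np.zeros(n) if beta0 is None else beta0,
        beta=np.zeros((n, c)) if beta is None else beta,
        omega=omega,
        theta=np.asarray(theta, dtype=float),
        rho=rho,
        tau_beta=np.ones(1 + c) if tau is None else np.asarray(tau, float),
        sigma_theta=np.asarray(sigma_theta, dtype=float),
    )


class TestGroupIndex:
    def test_point_mass_and_saturation(self):
        assert group_index([2, 0, 1], [1 - 2e-10, 1e-10, 1e-10]) == pytest.approx(2.0)
        w = np.array([0.2, 0.5, 0.3])
        assert group_index([3, 3, 3], w) == pytest.approx(3.0)

    def test_hand_dot_product_with_study_weights(self):
        omega = [0.30, 0.20, 0.20, 0.13, 0.10, 0.07]
        q = [3, 2, 1, 0, 3, 3]
        assert group_index(q, omega) == pytest.approx(2.01)

    def test_monotone_in_scores(self):
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(4))
        q = np.array([1, 2, 0, 3], dtype=float)
        base = group_index(q, w)
        for k in range(4):
            bumped = q.copy()
            bumped[k] += 1
            assert group_index(bumped, w) >= base

    def test_range(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            w = rng.dirichlet(np.ones(6))
            q = rng.integers(0, 4, size=6)
            assert 0.0 <= group_index(q, w) <= 3.0


class TestLinearPredictor:
    def test_zero_state_gives_even_odds(self):
        qz = _quantized({"m": [[1, 2], [0, 3]]})
        p = _params(2, {"m": np.array([0.5, 0.5])})
        eta = linear_predictors(p, qz, None)
        np.testing.assert_allclose(eta, 0.0)

    def test_simple_arithmetic(self):
        qz = _quantized({"m": [[2, 2]]})
        p = _params(
            1, {"m": np.array([0.5, 0.5])}, beta0=np.array([1.0]),
            beta=np.array([[0.5]]),
        )
        assert linear_predictor(p, qz, None, 0) == pytest.approx(1.0 + 0.5 * 2.0)

    def test_vector_form_equals_subject_loop(self):
        rng = np.random.default_rng(7)
        n = 25
        qz = quantize_components(
            {"a": rng.normal(size=(n, 3)), "b": rng.normal(size=(n, 4))}, 4
        )
        omega = {"a": rng.dirichlet(np.ones(3)), "b": rng.dirichlet(np.ones(4))}
        x = rng.normal(size=(n, 2))
        p = _params(
            n, omega, beta0=rng.normal(size=n), beta=rng.normal(size=(n, 2)),
            theta=rng.normal(size=2), sigma_theta=np.ones(2),
        )
        vec = linear_predictors(p, qz, x)
        loop = np.array([linear_predictor(p, qz, x, i) for i in range(n)])
        np.testing.assert_allclose(vec, loop, atol=1e-12)


class TestLogLikelihood:
    def test_closed_forms(self):
        p = Parameters(
            beta0=np.zeros(4), beta=np.zeros((4, 1)),
            omega={"m": np.array([0.5, 0.5])}, theta=np.array([]),
            rho=0.5, tau_beta=np.ones(2), sigma_theta=np.array([]),
        )
        y = np.array([0, 1, 0, 1])
        # all eta = 0 -> each term log(1/2)
        ll = log_likelihood(p, y, _quantized({"m": [[0, 0]] * 4}), None)
        assert ll == pytest.approx(-4 * np.log(2))

    def test_single_observation_sigmoid(self):
        p = Parameters(
            beta0=np.array([np.log(3.0)]), beta=np.zeros((1, 1)),
            omega={"m": np.array([0.6, 0.4])}, theta=np.array([]),
            rho=0.5, tau_beta=np.ones(2), sigma_theta=np.array([]),
        )
        ll = log_likelihood(p, np.array([1]), _quantized({"m": [[0, 0]]}), None)
        assert ll == pytest.approx(np.log(0.75))

    def test_matches_naive_sum(self):
        rng = np.random.default_rng(9)
        n = 40
        qz = quantize_components({"m": rng.normal(size=(n, 3))}, 4)
        p = _params(
            n, {"m": rng.dirichlet(np.ones(3))}, beta0=rng.normal(size=n),
            beta=rng.normal(size=(n, 1)),
        )
        y = rng.integers(0, 2, size=n)
        eta = linear_predictors(p, qz, None)
        naive = sum(
            np.log(1 / (1 + np.exp(-e))) if yi else np.log(1 - 1 / (1 + np.exp(-e)))
            for yi, e in zip(y, eta)
        )
        assert log_likelihood(p, y, qz, None) == pytest.approx(naive, abs=1e-10)

    def test_concave_in_eta(self):
        # second differences of the per-observation log likelihood are negative
        eta = np.linspace(-4, 4, 101)
        for y in (0.0, 1.0):
            ll = y * eta - np.logaddexp(0, eta)
            assert np.all(np.diff(ll, 2) < 0)

    def test_nonfinite_eta_raises(self):
        p = Parameters(
            beta0=np.array([np.inf]), beta=np.zeros((1, 1)),
            omega={"m": np.array([0.5, 0.5])}, theta=np.array([]),
            rho=0.5, tau_beta=np.ones(2), sigma_theta=np.array([]),
        )
        with pytest.raises(FloatingPointError):
            log_likelihood(p, np.array([1]), _quantized({"m": [[0, 0]]}), None)


class TestLogPrior:
    def _setup(self, n=5, seed=3):
        rng = np.random.default_rng(seed)
        locs = rng.uniform(size=(n, 2))
        priors = PriorSpec(
            alpha={"m": np.ones(3)}, rho_bounds=(0.05, 1.4), jitter=1e-6
        )
        p = _params(
            n, {"m": rng.dirichlet(np.ones(3))}, beta0=rng.normal(size=n),
            beta=rng.normal(size=(n, 1)), rho=0.5,
        )
        return p, priors, locs

    def test_out_of_support_rho_is_minus_inf(self):
        p, priors, locs = self._setup()
        p.rho = 5.0
        assert log_prior(p, priors, locs) == -np.inf

    def test_single_location_field_reduces_to_standard_normal(self):
        val = 0.83
        chol = cholesky(np.array([[1.0]]), lower=True)
        expected = -0.5 * np.log(2 * np.pi) - 0.5 * val**2
        assert mvn_field_logpdf(np.array([val]), chol, tau=1.0) == pytest.approx(expected)

    def test_dirichlet_normalizer_at_uniform_simplex(self):
        c = 4
        w = np.full(c, 1.0 / c)
        import math

        assert dirichlet_logpdf(w, np.ones(c)) == pytest.approx(gammaln(c))
        assert gammaln(c) == pytest.approx(np.log(math.factorial(c - 1)))

    def test_mvn_term_matches_scipy(self):
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(13)
        locs = rng.uniform(size=(6, 2))
        omega = correlation_matrix(locs, 0.4, 1e-6)
        f = rng.normal(size=6)
        tau = 2.3
        expected = multivariate_normal(mean=np.zeros(6), cov=omega / tau).logpdf(f)
        chol = cholesky(omega, lower=True)
        assert mvn_field_logpdf(f, chol, tau) == pytest.approx(expected, abs=1e-9)


class TestLogPosterior:
    def test_additivity_and_support(self):
        rng = np.random.default_rng(17)
        n = 12
        locs = rng.uniform(size=(n, 2))
        qz = quantize_components({"m": rng.normal(size=(n, 3))}, 4)
        y = rng.integers(0, 2, size=n)
        priors = PriorSpec(alpha={"m": np.ones(3)}, rho_bounds=(0.05, 1.4))
        p = _params(
            n, {"m": rng.dirichlet(np.ones(3))}, beta0=rng.normal(size=n),
            beta=rng.normal(size=(n, 1)), rho=0.4,
        )
        lp = log_posterior(p, y, qz, priors, locs)
        assert lp == pytest.approx(
            log_prior(p, priors, locs) + log_likelihood(p, y, qz, None)
        )
        p.rho = 99.0
        assert log_posterior(p, y, qz, priors, locs) == -np.inf

    def test_invariant_to_subject_permutation(self):
        rng = np.random.default_rng(19)
        n = 15
        locs = rng.uniform(size=(n, 2))
        raw = rng.normal(size=(n, 3))
        y = rng.integers(0, 2, size=n)
        priors = PriorSpec(alpha={"m": np.ones(3)}, rho_bounds=(0.01, 1.5))
        omega = {"m": rng.dirichlet(np.ones(3))}
        beta0, beta = rng.normal(size=n), rng.normal(size=(n, 1))

        def lp(order):
            qz = quantize_components({"m": raw[order]}, 4)
            p = _params(n, omega, beta0=beta0[order], beta=beta[order], rho=0.4)
            return log_posterior(p, y[order], qz, priors, locs[order])

        ident = np.arange(n)
        perm = rng.permutation(n)
        # Cholesky pivot order changes with the permutation, so agreement is
        # to relative rounding, not exact
        assert lp(ident) == pytest.approx(lp(perm), rel=1e-9)
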