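"""The 4PNO response function, likelihood, posteriors and direct gradients."""

import math

import numpy as np
import pytest
from scipy.special import ndtr

from nuts4pno import (
    ItemParameters,
    PriorSpec,
    ResponseMatrix,
    ability_gradient,
    ability_log_posterior,
    constrain_submodel,
    irf,
    item_gradient,
    item_log_posterior,
    log_likelihood,
    n_free_parameters,
)

from conftest import finite_difference


def _item(alpha=1.0, beta=0.0, g=0.0, s=0.0):
    return ItemParameters(alpha=[alpha], beta=[beta], g=[g], s=[s])


class TestResponseFunction:
    @pytest.mark.parametrize("g, s, expected", [
        (0.0, 0.0, 0.5),          # Phi(0) = 0.5 with no asymptotes
        (0.2, 0.1, 0.55),         # 0.2 + 0.7 * 0.5
    ])
    def test_midpoint_values(self, g, s, expected):
        item = _item(alpha=2.0, beta=1.0, g=g, s=s)
        assert irf(0.5, item)[0] == pytest.approx(expected, abs=1e-12)

    def test_general_point_matches_erf_oracle(self):
        item = _item(alpha=2.0, beta=0.5, g=0.1, s=0.05)
        expected = 0.1 + 0.85 * 0.5 * (1.0 + math.erf(1.5 / math.sqrt(2.0)))
        assert irf(1.0, item)[0] == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_theta_rejected(self):
        with pytest.raises(ValueError):
            irf(np.nan, _item())

    def test_monotone_in_theta_and_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            item = _item(alpha=rng.uniform(0.3, 3), beta=rng.normal(),
                         g=rng.uniform(0.01, 0.4), s=rng.uniform(0.01, 0.4))
            grid = np.linspace(-6, 6, 201)
            p = np.array([irf(t, item)[0] for t in grid])
            assert (np.diff(p) >= 0).all()
            # bounds are strict wherever Phi is numerically interior
            assert (p >= item.g[0]).all() and (p <= 1 - item.s[0]).all()
            mid = p[80:121]
            assert (mid > item.g[0]).all() and (mid < 1 - item.s[0]).all()


class TestResponseMatrix:
    def test_accepts_binary(self):
        Y = ResponseMatrix([[0, 1], [1, 0], [1, 1]])
        assert Y.n_examinees == 3 and Y.n_items == 2

    @pytest.mark.parametrize("data", [
        [[0, 2], [1, 0]],                 # non-binary
        [[0.5, 1], [1, 0]],               # fractional
        [[np.nan, 1], [1, 0]],            # missing
        [[0, 1]],                         # single examinee
    ])
    def test_rejects_invalid(self, data):
        with pytest.raises(ValueError):
            ResponseMatrix(data)


class TestLogLikelihood:
    def test_single_cell(self):
        item = _item(alpha=2.0, beta=1.0, g=0.2, s=0.1)  # P(0.5) = 0.55
        Y = ResponseMatrix([[1], [1]])
        ll = log_likelihood(Y, [0.5, 0.5], item)
        assert ll == pytest.approx(2 * np.log(0.55), rel=1e-12)

    def test_perfect_fit_limit_is_near_zero_from_below(self):
        item = _item(alpha=1.0, beta=-40.0)   # P essentially 1
        Y = ResponseMatrix([[1], [1], [1]])
        ll = log_likelihood(Y, [0.0, 0.0, 0.0], item)
        assert -1e-9 < ll <= 0.0

    def test_matches_cellwise_hand_sum(self, rng):
        items = ItemParameters(alpha=rng.uniform(0.5, 2, 3),
                               beta=rng.normal(size=3),
                               g=rng.uniform(0.05, 0.3, 3),
                               s=rng.uniform(0.05, 0.3, 3))
        theta = rng.normal(size=5)
        y = rng.integers(0, 2, size=(5, 3))
        expected = 0.0
        for i in range(5):
            for j in range(3):
                p = (items.g[j] + (1 - items.s[j] - items.g[j])
                     * ndtr(items.alpha[j] * theta[i] - items.beta[j]))
                expected += y[i, j] * np.log(p) + (1 - y[i, j]) * np.log(1 - p)
        assert log_likelihood(ResponseMatrix(y), theta, items) == \
            pytest.approx(expected, rel=1e-12)


class TestLogPosterior:
    def test_flat_prior_limit_equals_loglik_plus_constant(self, rng):
        theta = rng.normal(size=10)
        y = rng.integers(0, 2, size=10)
        w = np.array([0.2, -0.3, -1.0, -1.5])
        wide = PriorSpec(alpha_star=(0, 1e12), beta=(0, 1e12),
                         gamma=(0, 1e12), varsigma=(0, 1e12))
        lp1 = item_log_posterior(y, theta, w, wide)
        lp2 = item_log_posterior(y, theta, w + [0.1, 0.1, 0.1, 0.1], wide)
        items1 = ItemParameters.from_unconstrained(w)
        items2 = ItemParameters.from_unconstrained(w + np.array([0.1] * 4))
        ll1 = _block_ll(y, theta, items1)
        ll2 = _block_ll(y, theta, items2)
        # prior contribution is (numerically) constant => differences agree
        assert lp1 - lp2 == pytest.approx(ll1 - ll2, abs=1e-6)

    def test_prior_only_for_empty_items(self, prior):
        empty = ItemParameters(alpha=np.empty(0), beta=np.empty(0),
                               g=np.empty(0), s=np.empty(0))
        lp = ability_log_posterior(np.empty(0), 0.7, empty, prior)
        mu, var = prior.theta
        expected = -0.5 * np.log(2 * np.pi * var) - 0.5 * (0.7 - mu) ** 2 / var
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_matches_sum_of_terms_oracle(self, rng, prior):
        theta = rng.normal(size=5)
        y = rng.integers(0, 2, size=5)
        w = rng.normal(size=4)
        items = ItemParameters.from_unconstrained(w)
        expected = _block_ll(y, theta, items)
        mus, vars_ = prior.item_means(), prior.item_variances()
        for d in range(4):
            expected += (-0.5 * np.log(2 * np.pi * vars_[d])
                         - 0.5 * (w[d] - mus[d]) ** 2 / vars_[d])
        assert item_log_posterior(y, theta, w, prior) == \
            pytest.approx(expected, rel=1e-10)


def _block_ll(y, theta, items):
    out = 0.0
    for i in range(len(theta)):
        p = irf(theta[i], items)[0]
        out += y[i] * np.log(p) + (1 - y[i]) * np.log(1 - p)
    return out


class TestDirectGradients:
    def test_prior_only_with_no_data(self, prior):
        w = np.array([0.5, -0.2, -1.0, -2.0])
        grad = item_gradient(np.empty(0), np.empty(0), w, prior)
        mus, vars_ = prior.item_means(), prior.item_variances()
        np.testing.assert_allclose(grad, -(w - mus) / vars_, rtol=1e-12)

    def test_matches_finite_differences_at_random_points(self, prior):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = 12
            theta = rng.normal(size=n)
            y = rng.integers(0, 2, size=n)
            w = rng.normal(size=4) * [0.5, 1.0, 1.0, 1.0] + [0, 0, -1.2, -1.2]
            grad = item_gradient(y, theta, w, prior)
            fd = finite_difference(
                lambda x: item_log_posterior(y, theta, x, prior), w)
            np.testing.assert_allclose(grad, fd, rtol=1e-6, atol=1e-6)
            i = rng.integers(n)
            items = ItemParameters.from_unconstrained(
                rng.normal(size=(3, 4)) * 0.5 + [0, 0, -1.5, -1.5])
            th = rng.normal()
            ga = ability_gradient(y[:3], th, items, prior)
            fda = finite_difference(
                lambda x: ability_log_posterior(y[:3], x[0], items, prior),
                [th])[0]
            assert ga == pytest.approx(fda, rel=1e-6, abs=1e-6)

    def test_symmetry_flips_beta_gradient(self, rng, prior):
        theta = rng.normal(size=15)
        y = rng.integers(0, 2, size=15)
        w = np.array([0.3, 0.4, -1.1, -1.7])
        g1 = item_gradient(y, theta, w, prior)
        # flip: y -> 1-y, theta -> -theta, beta -> -beta, g <-> s
        w_flip = np.array([w[0], -w[1], w[3], w[2]])
        g2 = item_gradient(1 - y, -theta, w_flip, prior)
        assert g2[1] == pytest.approx(-g1[1], rel=1e-10)


class TestTransformsAndSubmodels:
    def test_round_trip_natural_unconstrained_natural(self, rng):
        items = ItemParameters(alpha=rng.uniform(0.2, 4, 50),
                               beta=rng.normal(size=50),
                               g=rng.uniform(0.001, 0.5, 50),
                               s=rng.uniform(0.001, 0.5, 50))
        back = ItemParameters.from_unconstrained(items.unconstrained())
        for name in ("alpha", "beta", "g", "s"):
            np.testing.assert_allclose(getattr(back, name),
                                       getattr(items, name), rtol=1e-12)

    @pytest.mark.parametrize("tag, npar", [("2pno", 2), ("3pno", 3), ("4pno", 4)])
    def test_free_parameter_counts(self, tag, npar):
        assert n_free_parameters(tag) == npar
        assert n_free_parameters(tag) * 12 == {2: 24, 3: 36, 4: 48}[npar]

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            n_free_parameters("5pno")

    def test_constraints_zero_the_asymptotes(self):
        item = _item(alpha=1.5, beta=0.2, g=0.25, s=0.15)
        two = constrain_submodel("2pno", item)
        three = constrain_submodel("3pno", item)
        assert two.g[0] == two.s[0] == 0.0
        assert three.s[0] == 0.0 and three.g[0] == 0.25
        assert irf(0.8, two)[0] == pytest.approx(
            ndtr(1.5 * 0.8 - 0.2), rel=1e-12)

    def test_4pno_with_zero_asymptotes_reproduces_2pno_likelihood(self, rng):
        alpha, beta = rng.uniform(0.5, 2, 4), rng.normal(size=4)
        zero = np.zeros(4)
        items4 = ItemParameters(alpha=alpha, beta=beta, g=zero, s=zero)
        items2 = constrain_submodel(
            "2pno", ItemParameters(alpha=alpha, beta=beta,
                                   g=np.full(4, 0.3), s=np.full(4, 0.2)))
        theta = rng.normal(size=9)
        y = rng.integers(0, 2, size=(9, 4))
        Y = ResponseMatrix(y)
        assert log_likelihood(Y, theta, items4) == \
            pytest.approx(log_likelihood(Y, theta, items2), rel=1e-14)
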