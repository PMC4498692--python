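"""Bayesian core: kernels, the superiority functional, and the posterior.

The independent oracles live here: brute-force 2-D quadrature of the
(mean, sigma) marginalization for the kernel exponent, and an exact
gamma-normal posterior sampler for the superiority probability.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from trialadapt._errors import (
    AnalysisError,
    DegenerateDataError,
    DomainError,
    EligibilityError,
)
from trialadapt.posterior import (
    MatchedPair,
    OutcomeSample,
    complete_square,
    make_sample,
    map_estimate,
    marginal_integral,
    mean_posterior,
    posterior_differential,
    predictive,
    rho_star,
    PosteriorDensity,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_kernel(x, values):
    """Direct 2-D quadrature of the (m, sigma) marginalization, integrating
    over log-sigma so the slowly decaying sigma tail is captured."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    center = values.mean()

    # substitutions: sigma = exp(s) (slow tail), m = center + sigma*u (the
    # inner integrand then has O(1) width at every sigma); the Jacobian is
    # sigma^2.  Still a direct 2-D quadrature of the raw integrand.
    def integrand(u, s_log):
        s = math.exp(s_log)
        m = center + s * u
        expo = -((x - m) ** 2 + np.sum((values - m) ** 2)) / (2 * s**2)
        return math.exp(expo) / s ** (n + 1) * s * s

    val, _ = integrate.dblquad(
        integrand, -12.0, 16.0, -40.0, 40.0, epsabs=1e-13, epsrel=1e-9
    )
    return val


def posterior_sampler_superiority(ctrl, trt, n_draws, seed):
    """P(X_t > X_c) by exact sampling from each arm's flat-prior posterior:
    1/sigma^2 ~ Gamma((n-2)/2, rate SS/2), m | sigma ~ N(xbar, sigma^2/n),
    then one predictive draw per posterior draw."""
    rng = np.random.default_rng(seed)

    def draw(sample):
        z = rng.gamma((sample.n - 2) / 2.0, 2.0 / sample.ss, n_draws)
        sigma = 1.0 / np.sqrt(z)
        m = rng.normal(sample.mean, sigma / math.sqrt(sample.n))
        return rng.normal(m, sigma)

    return float(np.mean(draw(trt) > draw(ctrl)))


# ---------------------------------------------------------------------------
# samples and completed squares
# ---------------------------------------------------------------------------

class TestMakeSample:
    def test_log_transform_exact(self):
        s = make_sample([1.0, math.e, math.e**2], transform="log")
        np.testing.assert_allclose(s.values, [0.0, 1.0, 2.0], atol=1e-12)
        assert s.n == 3
        assert s.s1 == pytest.approx(3.0)
        assert s.s2 == pytest.approx(5.0)

    def test_identity(self):
        s = make_sample([0.5])
        assert (s.n, s.s1, s.s2) == (1, 0.5, 0.25)

    def test_log_rejects_non_positive(self):
        with pytest.raises(DomainError):
            make_sample([2.0, -1.0], transform="log")

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=20))
    def test_sufficient_statistics_consistent(self, values):
        s = make_sample(values)
        assert s.s2 + 1e-9 >= s.s1**2 / s.n  # Cauchy-Schwarz
        assert s.ss >= 0


class TestCompleteSquare:
    def test_all_zero_data(self):
        sq = complete_square(0.0, make_sample([0.0]))
        assert sq.a == pytest.approx(math.sqrt(2))
        assert sq.b == 0.0
        assert sq.c == 0.0

    def test_single_point(self):
        sq = complete_square(1.0, make_sample([0.0]))
        assert sq.c == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None)
    @given(
        x=st.floats(-5, 5),
        values=st.lists(st.floats(-5, 5), min_size=1, max_size=8),
        m=st.floats(-5, 5),
    )
    def test_quadratic_identity(self, x, values, m):
        """(x-m)^2 + sum (x_i-m)^2 == (a m + b)^2 + c for every m."""
        sample = make_sample(values)
        sq = complete_square(x, sample)
        lhs = (x - m) ** 2 + sum((v - m) ** 2 for v in sample.values)
        rhs = (sq.a * m + sq.b) ** 2 + sq.c
        assert lhs == pytest.approx(rhs, abs=1e-8, rel=1e-8)
        assert sq.c >= -1e-12


# ---------------------------------------------------------------------------
# marginal kernel
# ---------------------------------------------------------------------------

class TestMarginalKernel:
    @pytest.mark.parametrize("n", [2, 3, 5, 10])
    def test_ratio_matches_brute_force_quadrature(self, n):
        """Kernel ratios across test points agree with direct 2-D quadrature
        of the (m, sigma) integral to relative error < 1e-3."""
        rng = np.random.default_rng(n)
        values = rng.normal(0.3, 0.8, n)
        sample = make_sample(values)
        x1, x2 = 0.4, 1.6
        oracle = brute_force_kernel(x1, values) / brute_force_kernel(x2, values)
        ours = marginal_integral(x1, sample) / marginal_integral(x2, sample)
        assert ours == pytest.approx(oracle, rel=1e-3)

    def test_symmetric_sample_symmetric_kernel(self):
        sample = make_sample([-0.4, 0.0, 0.4])
        for delta in (0.1, 0.7, 2.0):
            assert marginal_integral(delta, sample) == pytest.approx(
                marginal_integral(-delta, sample), rel=1e-12
            )

    def test_decreasing_away_from_mean(self):
        sample = make_sample([0.0, 0.1, -0.1])
        assert marginal_integral(0.0, sample) > marginal_integral(1.0, sample)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            marginal_integral(1.0, make_sample([1.0, 1.0]))

    def test_n1_rejected(self):
        with pytest.raises(EligibilityError):
            marginal_integral(0.0, make_sample([1.0]))

    def test_predictive_is_normalized_kernel(self):
        """The predictive t density is proportional to the kernel."""
        sample = make_sample([0.1, -0.3, 0.5, 0.2, -0.1])
        xs = np.linspace(-2, 2, 7)
        ratio = predictive(sample).pdf(xs) / marginal_integral(xs, sample)
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)


# ---------------------------------------------------------------------------
# superiority functional
# ---------------------------------------------------------------------------

class TestRhoStar:
    def test_identical_arms_give_half(self, symmetric_pair):
        assert rho_star(symmetric_pair) == pytest.approx(0.5, abs=1e-6)

    def test_large_shift_saturates(self, rng):
        ctrl = make_sample(rng.normal(0.0, 1.0, 30))
        trt = make_sample(ctrl.values + 10.0)
        assert rho_star(MatchedPair(0, ctrl, trt)) > 0.99

    def test_swap_complementarity(self, rng):
        """rho*(pair) + rho*(arm-swapped pair) = 1: ties have measure zero."""
        for _ in range(5):
            from conftest import random_pair
            pair = random_pair(rng)
            swapped = MatchedPair(0, pair.treatment, pair.control)
            assert rho_star(pair) + rho_star(swapped) == pytest.approx(1.0, abs=1e-4)

    def test_translation_invariance(self, rng):
        ctrl = rng.normal(0.0, 1.0, 6)
        trt = rng.normal(0.5, 1.2, 8)
        a = rho_star(MatchedPair(0, make_sample(ctrl), make_sample(trt)))
        b = rho_star(MatchedPair(0, make_sample(ctrl + 7.0), make_sample(trt + 7.0)))
        assert a == pytest.approx(b, abs=1e-9)

    def test_matches_posterior_sampler(self):
        """Agreement with the exact gamma-normal posterior sampling oracle."""
        ctrl = make_sample([0.1, -0.2, 0.3])
        trt = make_sample([0.5, 0.9, 0.2])
        ours = rho_star(MatchedPair(0, ctrl, trt))
        mc = posterior_sampler_superiority(ctrl, trt, n_draws=4_000_000, seed=42)
        assert ours == pytest.approx(mc, abs=1e-3)

    def test_n2_nonnormalizable(self):
        pair = MatchedPair(0, make_sample([0.0, 1.0]), make_sample([0.5, 1.5]))
        with pytest.raises(EligibilityError):
            rho_star(pair)


# ---------------------------------------------------------------------------
# posterior of the differential effect
# ---------------------------------------------------------------------------

class TestPosteriorDifferential:
    def test_recovers_simulated_shift(self, rng):
        """Large-sample recovery of a known differential of 0.19."""
        ctrl = make_sample(rng.normal(0.0, 0.05, 200))
        trt = make_sample(rng.normal(0.19, 0.05, 200))
        post = posterior_differential([MatchedPair(0, ctrl, trt)])
        se = math.sqrt(0.05**2 / 200 + 0.05**2 / 200)
        assert abs(post.map_estimate - 0.19) < 3 * se
        assert post.sd == pytest.approx(se, rel=0.25)

    def test_density_normalized(self, rng):
        from conftest import random_pair
        post = posterior_differential([random_pair(rng, 8, 9)])
        mass = np.trapezoid(post.density, post.grid)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_duplicate_pairs_equal_single(self, rng):
        from conftest import random_pair
        pair = random_pair(rng, 10, 10)
        one = posterior_differential([pair])
        two = posterior_differential([pair, pair])
        np.testing.assert_allclose(one.density, two.density, rtol=1e-9)

    def test_swapped_pair_mirrors_posterior(self, rng):
        from conftest import random_pair
        pair = random_pair(rng, 12, 12)
        swapped = MatchedPair(0, pair.treatment, pair.control)
        post = posterior_differential([pair], grid_points=801)
        anti = posterior_differential([swapped], grid_points=801)
        f = np.interp(-anti.grid[::-1], post.grid, post.density)
        np.testing.assert_allclose(anti.density[::-1], f, atol=1e-6 * post.density.max() * 50)
        assert anti.map_estimate == pytest.approx(-post.map_estimate, abs=1e-3)

    def test_small_pairs_skipped_with_warning(self, rng):
        from conftest import random_pair
        ok = random_pair(rng, 10, 10)
        tiny = MatchedPair(1, make_sample([0.1, 0.2]), make_sample([0.3, 0.1]))
        with pytest.warns(RuntimeWarning):
            post = posterior_differential([ok, tiny])
        assert set(post.weights) == {0}

    def test_no_eligible_pair_is_analysis_error(self):
        tiny = MatchedPair(1, make_sample([0.1, 0.2]), make_sample([0.3, 0.1]))
        with pytest.raises(AnalysisError), pytest.warns(RuntimeWarning):
            posterior_differential([tiny])


class TestMapEstimate:
    def test_uniform_density_ties_break_low(self):
        grid = np.linspace(0.0, 1.0, 11)
        post = PosteriorDensity(grid=grid, density=np.ones(11) / 1.0,
                                map_estimate=0.0, sd=0.0)
        assert map_estimate(post) == 0.0

    def test_peak_located(self):
        grid = np.linspace(-1.0, 1.0, 2001)
        dens = np.exp(-0.5 * ((grid - 0.19) / 0.05) ** 2)
        post = PosteriorDensity(grid=grid, density=dens, map_estimate=0.0, sd=0.0)
        assert map_estimate(post) == pytest.approx(0.19, abs=1e-3)
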