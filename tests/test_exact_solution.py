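"""Hypoexponential closed forms, spectral solution, and master-equation oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import poisson

from purebirth import (
    DegenerateRatesError,
    GrowthModel,
    RateSequence,
    deterministic_trajectory,
    distribution_from_rates,
    distribution_moments,
    exact_distribution,
    hypoexponential_cdf,
    hypoexponential_pdf,
    master_equation_oracle,
    population_birth_rate,
    relative_error,
    spectral_distribution,
)

# frozen oracle: convolution of Erlang(2, rate 1) with Exp(2) at t=1,
# computed by quadrature of u exp(-u) * 2 exp(-2(1-u)) over [0, 1]
CONV_112_AT_1 = 0.27067056647322535


class TestHypoexponential:
    def test_single_rate_is_exponential(self):
        t = np.linspace(0, 5, 20)
        np.testing.assert_allclose(hypoexponential_pdf([2.5], t), 2.5 * np.exp(-2.5 * t))

    def test_two_distinct_rates_closed_form(self):
        # rates (1, 2): H_t = 2(e^-t - e^-2t); at t = ln 2 this is 0.5
        assert hypoexponential_pdf([1.0, 2.0], math.log(2)) == pytest.approx(0.5, rel=1e-12)

    def test_degenerate_rates_vs_convolution_oracle(self):
        assert hypoexponential_pdf([1.0, 1.0, 2.0], 1.0) == pytest.approx(
            CONV_112_AT_1, abs=1e-8)

    def test_order_invariance(self):
        t = np.linspace(0.1, 4, 7)
        np.testing.assert_allclose(hypoexponential_pdf([3.0, 1.0, 1.0], t),
                                   hypoexponential_pdf([1.0, 3.0, 1.0], t), rtol=1e-10)

    def test_erlang_case(self):
        # all rates equal: Erlang(n=3, lam=2)
        t = 0.7
        expected = 2.0**3 / math.factorial(2) * t**2 * math.exp(-2 * t)
        assert hypoexponential_pdf([2.0, 2.0, 2.0], t) == pytest.approx(expected, rel=1e-12)

    def test_partial_fraction_coefficients_vs_symbolic(self):
        # the log-derivative recursion for C_{i,k} against sympy derivatives
        # of prod_{j != i} (s + lam_j)^(-n_j) at s = -lam_i
        import sympy
        from purebirth.exact_solution import _case3_coefficients

        lam = np.array([1.0, 3.0, 5.0])
        mult = np.array([2, 1, 3])
        C = _case3_coefficients(lam, mult)
        s = sympy.symbols("s")
        for i in range(3):
            f = sympy.prod([(s + sympy.Rational(int(lam[j]))) ** (-int(mult[j]))
                            for j in range(3) if j != i])
            for k in range(int(mult[i])):
                ref = float(sympy.diff(f, s, k).subs(s, -sympy.Rational(int(lam[i]))))
                assert C[i][k] == pytest.approx(ref, rel=1e-10)

    def test_empty_rate_list_rejected(self):
        with pytest.raises(ValueError):
            hypoexponential_pdf([], 1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(rates=st.lists(st.floats(0.2, 5.0), min_size=1, max_size=5))
    def test_integrates_to_one(self, rates):
        total, _ = quad(lambda t: hypoexponential_pdf(rates, t), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_cdf_derivative_matches_pdf(self):
        # independent route: the uniformization-based CDF differentiated
        # numerically recovers the closed-form density
        rates = [1.0, 0.5, 2.0, 1.5]
        for t in (0.5, 1.5, 3.0):
            h = 1e-5
            num = (hypoexponential_cdf(rates, t + h) - hypoexponential_cdf(rates, t - h)) / (2 * h)
            assert num == pytest.approx(hypoexponential_pdf(rates, t), rel=1e-5)


class TestRateSequence:
    def test_grouping_partitions_and_is_order_invariant(self):
        seq = RateSequence(N0=1, K=6, rates=(2.0, 1.0, 2.0, 3.0, 1.0))
        lam, mult = seq.groups
        assert mult.sum() == 5
        np.testing.assert_allclose(lam, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(mult, [2, 2, 1])
        assert seq.is_degenerate

    def test_logistic_mirror_symmetry_detected(self):
        seq = RateSequence.from_model(GrowthModel(family="logistic", K=100), 1)
        assert seq.is_degenerate  # B(N) = B(K - N)

    def test_positive_rates_required(self):
        with pytest.raises(ValueError):
            RateSequence(N0=1, K=3, rates=(1.0, 0.0))


class TestExactDistribution:
    def test_initial_condition_point_mass(self, models_k30):
        for m in models_k30.values():
            d = exact_distribution(m, 3, [0.0])
            assert d.probs[0, 0] == pytest.approx(1.0, abs=1e-12)
            assert d.probs[0, 1:].max() < 1e-12

    def test_yule_closed_form(self):
        # linear birth rates: P_{1,N}(t) = e^-t (1 - e^-t)^(N-1)
        t = math.log(2)
        d = distribution_from_rates(np.arange(1.0, 50.0), 1, 50, [t], method="hypoexp")
        N = np.arange(1, 50)
        yule = math.exp(-t) * (1 - math.exp(-t)) ** (N - 1)
        np.testing.assert_allclose(d.probs[0, :49], yule, atol=1e-12)
        assert d.probs[0, 1] == pytest.approx(0.25)

    def test_constant_rates_give_poisson_occupation(self):
        # all rates lam: P_{N0,N}(t) = Poisson pmf at N - N0 with mean lam t
        lam, n = 0.8, 12
        d = distribution_from_rates(np.full(n, lam), 2, 2 + n, [1.7], method="hypoexp")
        expected = poisson.pmf(np.arange(n), lam * 1.7)
        np.testing.assert_allclose(d.probs[0, :n], expected, atol=1e-10)

    def test_absorbing_state_reached(self):
        m = GrowthModel(family="logistic", K=100)
        d = exact_distribution(m, 1, [60.0], method="uniformization")
        assert d.probs[0, -1] == pytest.approx(1.0, abs=1e-6)

    def test_absorbing_mass_monotone(self, grid, models_k30):
        # up to the round-off floor of the clamped/renormalized table
        for m in models_k30.values():
            d = exact_distribution(m, 1, grid)
            assert np.all(np.diff(d.probs[:, -1]) >= -1e-9)

    def test_rejects_death_and_alpha(self):
        with pytest.raises(ValueError):
            exact_distribution(GrowthModel(family="logistic", K=50, d=0.1), 1, [1.0])
        with pytest.raises(ValueError):
            exact_distribution(GrowthModel(family="blumberg", alpha=2.0, K=50), 1, [1.0])

    @pytest.mark.parametrize("K", [10, 30, 100])
    def test_rows_sum_to_one(self, K, grid):
        for m in (GrowthModel(family="logistic", K=K),
                  GrowthModel(family="gompertz", K=K)):
            d = exact_distribution(m, 1, grid)
            assert d.max_rowsum_dev < 1e-9
            np.testing.assert_allclose(d.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_convolution_identity(self):
        # P_{N0,N}(t) * B_N is the hitting-time density of N+1
        m = GrowthModel(family="richards", beta=2.0, K=15)
        rates = np.asarray(RateSequence.from_model(m, 1).rates)
        d = exact_distribution(m, 1, [2.0], method="ode")
        for j in (0, 4, 9):
            assert d.probs[0, j] * rates[j] == pytest.approx(
                hypoexponential_pdf(rates[: j + 1], 2.0), rel=1e-6, abs=1e-9)


class TestOracleEquivalence:
    def test_hypoexp_vs_master_equation_all_families(self, grid, models_k30):
        for name, m in models_k30.items():
            a = exact_distribution(m, 1, grid, method="hypoexp")
            b = master_equation_oracle(m, 1, grid)
            assert np.abs(a.probs - b.probs).max() < 1e-6, name

    def test_uniformization_vs_master_equation(self, grid, models_k30):
        for name, m in models_k30.items():
            a = exact_distribution(m, 1, grid, method="uniformization")
            b = master_equation_oracle(m, 1, grid)
            assert np.abs(a.probs - b.probs).max() < 1e-6, name

    def test_spectral_matches_exact_where_defined(self, coarse_grid):
        m = GrowthModel(family="richards", beta=2.0, K=20)
        a = spectral_distribution(m, 1, coarse_grid)
        b = exact_distribution(m, 1, coarse_grid, method="hypoexp")
        assert np.abs(a.probs - b.probs).max() < 1e-8

    def test_spectral_rejects_degenerate_logistic(self):
        with pytest.raises(DegenerateRatesError):
            spectral_distribution(GrowthModel(family="logistic", K=100), 1, [1.0])

    def test_hypoexp_precision_fallback_long_chain(self):
        # K = 100 Richards chains trigger the arbitrary-precision path;
        # result must still match uniformization
        m = GrowthModel(family="richards", beta=2.0, K=100)
        t = np.array([2.0, 5.0, 10.0])
        a = exact_distribution(m, 1, t, method="hypoexp")
        b = exact_distribution(m, 1, t, method="uniformization")
        assert np.abs(a.probs - b.probs).max() < 1e-8


class TestMoments:
    def test_point_mass_moments(self):
        m = GrowthModel(family="logistic", K=30)
        d = exact_distribution(m, 4, [0.0])
        mom = distribution_moments(d, orders=(1, 2))
        assert mom[1][0] == pytest.approx(4.0)
        assert mom[2][0] == pytest.approx(16.0)

    def test_exponential_mean_is_exp_t(self):
        # Yule process: <N>(t) = e^t (truncated far from saturation)
        t = np.linspace(0, 2, 9)
        d = distribution_from_rates(np.arange(1.0, 200.0), 1, 200, t, method="uniformization")
        np.testing.assert_allclose(d.mean(), np.exp(t), rtol=1e-7)

    def test_mean_ode_identity(self, models_k30):
        # d<N>/dt = <B(N)> on the grid (finite differences)
        t = np.arange(0, 10.0, 0.01)
        m = models_k30["gompertz"]
        d = exact_distribution(m, 1, t)
        mean = d.mean()
        B = np.asarray(population_birth_rate(m, d.sizes))
        mean_rate = d.probs @ B
        dmean = np.gradient(mean, t)
        assert np.abs(dmean[2:-2] - mean_rate[2:-2]).max() < 5e-3

    def test_variance_nonnegative(self, grid, models_k30):
        for m in models_k30.values():
            d = exact_distribution(m, 1, grid)
            mom = distribution_moments(d, orders=(1, 2))
            assert np.all(mom[2] - mom[1] ** 2 >= -1e-9)

    def test_deterministic_overestimates_exact_mean(self, grid, models_k100):
        # deterministic prediction sits above the stochastic mean at all times
        for name, m in models_k100.items():
            d = exact_distribution(m, 1, grid, method="uniformization")
            det = deterministic_trajectory(m, 1, grid)
            eta = relative_error(det, d.mean())
            assert eta.min() > -1e-9, name
            assert eta.max() > 0.05, name


class TestRelativeError:
    def test_zero_when_equal(self):
        x = np.linspace(1, 5, 10)
        np.testing.assert_array_equal(relative_error(x, x), np.zeros(10))

    def test_arithmetic(self):
        assert relative_error([1.3], [1.0])[0] == pytest.approx(0.3)

    def test_positive_mean_required(self):
        with pytest.raises(ZeroDivisionError):
            relative_error([1.0], [0.0])
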