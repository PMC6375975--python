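"""Beta-Binomial null: oracle equivalence, limits, approximations, moments."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyafilter as pf
from polyafilter.errors import DomainError

from _oracles import binom_survival, urn_pmf, urn_survival


class TestPmfOracle:
    @pytest.mark.parametrize("a", [Fraction(1, 2), Fraction(1), Fraction(2)])
    def test_pmf_matches_urn_enumeration(self, a):
        """The pmf equals exact rational enumeration of Pólya draw sequences
        for every k <= 5, s <= 8."""
        for k in range(1, 6):
            for s in range(1, 9):
                oracle = urn_pmf(k, s, a)
                for x in range(s + 1):
                    expected = float(oracle.get(x, Fraction(0)))
                    got = pf.polya_pmf(x, k, s, float(a))
                    assert got == pytest.approx(expected, abs=1e-12), (k, s, x)

    @pytest.mark.parametrize("a", [Fraction(1, 2), Fraction(1), Fraction(2)])
    def test_pvalue_matches_urn_enumeration(self, a):
        for k in range(1, 6):
            for s in range(1, 9):
                for w in range(s + 1):
                    expected = float(urn_survival(w, k, s, a))
                    got = pf.polya_pvalue(w, k, s, float(a))
                    assert got == pytest.approx(expected, abs=1e-12), (k, s, w)

    def test_pmf_binomial_at_a0(self):
        """a = 0 reduces to Binomial(s, 1/k), checked against exact rationals."""
        for k, s in [(2, 2), (3, 7), (5, 12), (7, 30)]:
            for x in range(s + 1):
                from _oracles import binom_pmf

                assert pf.polya_pmf(x, k, s, 0.0) == pytest.approx(
                    float(binom_pmf(x, s, k)), abs=1e-12
                )

    def test_pvalue_binomial_at_a0(self):
        for k, s, w in [(2, 2, 1), (3, 7, 4), (5, 12, 6), (7, 30, 12)]:
            assert pf.polya_pvalue(w, k, s, 0.0) == pytest.approx(
                float(binom_survival(w, s, k)), abs=1e-12
            )

    def test_normalization_on_grid(self):
        for k in (2, 3, 5, 10):
            for s in (1, 7, 50, 400):
                for a in (0.0, 0.3, 1.0, 4.7):
                    xs = np.arange(s + 1)
                    assert pf.polya_pmf(xs, k, s, a).sum() == pytest.approx(1.0, abs=1e-12)

    def test_point_mass_at_degree_one(self):
        assert pf.polya_pmf(5, 1, 5, 2.0) == 1.0
        assert pf.polya_pmf(3, 1, 5, 2.0) == 0.0
        assert pf.polya_pvalue(4, 1, 5, 2.0) == 1.0


class TestPvalue:
    def test_worked_example(self):
        """Hub with k=3, s=4 at a=1: P(X >= 2) is exactly 2/5."""
        assert pf.polya_pvalue(2, 3, 4, 1.0) == pytest.approx(0.4, abs=1e-12)
        assert pf.polya_pvalue(1, 3, 4, 1.0) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_whole_support_is_one(self):
        assert pf.polya_pvalue(0, 7, 50, 2.3) == 1.0

    def test_infinite_reinforcement_limit(self):
        """As a -> inf the p-value of any w >= 1 tends to 1/k (the first draw
        decides everything)."""
        assert pf.polya_pvalue(5, 4, 10, 1e8) == pytest.approx(0.25, abs=1e-6)
        assert pf.polya_pvalue(1, 10, 100, 1e8) == pytest.approx(0.1, abs=1e-6)

    def test_monotone_in_w(self):
        for a in (0.0, 0.5, 1.0, 3.0):
            ps = [pf.polya_pvalue(w, 6, 40, a) for w in range(41)]
            assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_tiny_tail_has_relative_precision(self):
        # upper-tail sums must not collapse to 0 from 1 - sum cancellation
        p = pf.polya_pvalue(95, 10, 100, 0.0)
        assert 0 < p < 1e-80

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            pf.polya_pvalue(5, 3, 4, 1.0)  # w > s
        with pytest.raises(DomainError):
            pf.polya_pmf(-1, 3, 4, 1.0)
        with pytest.raises(DomainError):
            pf.polya_pmf(1, 3, 4, -0.5)
        with pytest.raises(DomainError):
            pf.polya_pvalue(1.5, 3, 4.0, 1.0)  # non-whole w in exact mode


class TestApproximations:
    def test_equals_disparity_at_a1_bitwise(self):
        for w, k, s in [(10, 3, 100), (1, 7, 9), (250, 12, 1000), (999, 2, 1000)]:
            assert pf.polya_pvalue_approx(w, k, s, 1.0) == pf.disparity_pvalue(w, k, s)

    def test_closed_form_value(self):
        assert pf.polya_pvalue_approx(10, 3, 100, 1.0) == pytest.approx(0.81, abs=1e-12)

    def test_agrees_with_exact_in_tail_regime(self):
        """In the regime s >> k/a with w at or above the null mean, the
        large-strength form tracks the exact survival closely."""
        assert abs(
            pf.polya_pvalue_approx(5000, 10, 10_000, 2.0)
            - pf.polya_pvalue(5000, 10, 10_000, 2.0)
        ) < 1e-3
        assert abs(
            pf.polya_pvalue_approx(1000, 10, 10_000, 1.0)
            - pf.polya_pvalue(1000, 10, 10_000, 1.0)
        ) < 1e-3

    def test_clipping_to_unit_interval(self):
        # below the null mean the raw expression can exceed 1
        assert pf.polya_pvalue_approx(50, 10, 10_000, 2.0) <= 1.0
        assert pf.polya_pvalue_ratio(1e-8, 2.0) == 1.0

    def test_ratio_form(self):
        assert pf.polya_pvalue_ratio(1.0, 1.0) == pytest.approx(np.exp(-1), abs=1e-12)
        assert pf.polya_pvalue_ratio(4.0, 1.0) < pf.polya_pvalue_ratio(2.0, 1.0)

    def test_approx_requires_positive_a(self):
        with pytest.raises(DomainError):
            pf.polya_pvalue_approx(1, 3, 10, 0.0)
        with pytest.raises(DomainError):
            pf.polya_pvalue_ratio(1.0, 0.0)


class TestDisparity:
    def test_values(self):
        assert pf.disparity_pvalue(2, 3, 4) == pytest.approx(0.25, abs=1e-12)
        assert pf.disparity_pvalue(0, 5, 10) == 1.0
        assert pf.disparity_pvalue(7, 1, 10) == 1.0  # exponent zero

    def test_domain(self):
        with pytest.raises(DomainError):
            pf.disparity_pvalue(11, 3, 10)


class TestRatio:
    def test_values(self):
        assert pf.ratio_r(2, 3, 4) == pytest.approx(1.5)
        assert pf.ratio_r(10, 5, 50) == pytest.approx(1.0)  # w = <w>
        assert pf.ratio_r(50, 5, 50) == pytest.approx(5.0)  # dominant link

    def test_domain(self):
        with pytest.raises(DomainError):
            pf.ratio_r(1, 3, 0)


class TestNullMoments:
    def test_mean_is_one_and_variance_formula(self):
        st_ = pf.null_ratio_moments(3, 4, 1.0)
        assert st_.mu_r == 1.0
        assert st_.var_r == pytest.approx(0.875, abs=1e-12)

    def test_binomial_limit_variance(self):
        st_ = pf.null_ratio_moments(6, 120, 0.0)
        assert st_.var_r == pytest.approx(5.0 / 120.0, abs=1e-12)

    def test_monte_carlo_agreement(self):
        """Sample moments of r under the null match the closed forms within
        three standard errors at 1e5 draws."""
        k, s, a, n = 3, 4, 1.0, 100_000
        rng = np.random.default_rng(99)
        w = pf.sample_null_weights(k, s, a, n, rng)
        r = w * k / s
        stats = pf.null_ratio_moments(k, s, a)
        se_mean = r.std(ddof=1) / np.sqrt(n)
        assert abs(r.mean() - stats.mu_r) < 3 * se_mean
        var_emp = r.var(ddof=1)
        se_var = np.sqrt((np.mean((r - r.mean()) ** 4) - var_emp**2) / n)
        assert abs(var_emp - stats.var_r) < 3 * se_var


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    k=st.integers(min_value=2, max_value=12),
    s=st.integers(min_value=1, max_value=300),
    a=st.one_of(st.just(0.0), st.floats(min_value=1e-4, max_value=20.0, allow_nan=False)),
)
def test_pmf_normalizes_and_pvalue_bounded(k, s, a):
    xs = np.arange(s + 1)
    pmf = pf.polya_pmf(xs, k, s, a)
    assert np.all(pmf >= 0)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
    ps = pf.polya_pvalue(xs, np.full(s + 1, k), np.full(s + 1, s), a)
    assert np.all((0 <= ps) & (ps <= 1))
    assert np.all(np.diff(ps) <= 1e-12)  # non-increasing in w
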