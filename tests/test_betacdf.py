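"""Central and noncentral beta/F cdf enclosures."""

import math
from fractions import Fraction

import pytest
from mpmath import mpf

from vfpow.autodiff import DiffInterval
from vfpow.betacdf import (
    ParameterError,
    central_beta_cdf,
    f_to_beta,
    noncentral_beta_cdf,
    noncentral_f_cdf,
)
from vfpow.interval import Interval, IntervalDomainError, point

from .data_tables import NONCENTRAL_CDF_CASES
from .oracles import (
    central_beta_literal_fraction,
    mp_central_beta,
    mp_noncentral_beta,
)


class TestCentralBeta:
    def test_identity_b1_a1(self):
        r = central_beta_cdf(point(0.95), 1, 1)
        assert r.contains(0.95) and r.wid() < 1e-14

    def test_published_quantile_value(self):
        # the upper 0.05 quantile for a=1, b=2 is 0.776393...
        r = central_beta_cdf(point(0.776393), 1, 2)
        assert abs(r.mid() - 0.95) < 1e-6

    def test_sqrt_closed_form(self):
        # I_x(1/2, 1) = sqrt(x): exactly 0.95 at x = 0.9025
        r = central_beta_cdf(point(0.9025), 0.5, 1)
        assert r.contains(0.95) and r.wid() < 1e-14

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            central_beta_cdf(point(0.5), 1.0, 2.5)
        with pytest.raises(ParameterError):
            central_beta_cdf(point(0.5), -1.0, 2)
        with pytest.raises(IntervalDomainError):
            central_beta_cdf(point(1.5), 1.0, 2)

    def test_randomized_against_high_precision(self, rng):
        for _ in range(300):
            a = rng.uniform(0.5, 25.0)
            b = rng.randint(1, 20)
            x = rng.uniform(0.0, 1.0)
            r = central_beta_cdf(point(x), a, b)
            ref = float(mp_central_beta(x, a, b))
            assert r.lo - 1e-30 <= ref <= r.hi + 1e-30

    def test_recurrence_equals_literal_rational_form(self, rng):
        """The incremental-product evaluation agrees with the literal
        (factorial/power) form computed in exact rational arithmetic."""
        for _ in range(40):
            a = rng.randint(1, 20)
            b = rng.randint(1, 15)
            x = Fraction(rng.randint(1, 99), 100)
            exact = central_beta_literal_fraction(
                Fraction(x), Fraction(a), b
            )
            r = central_beta_cdf(point(float(x)), float(a), b)
            # float(x) == x exactly only for dyadic x; compare at the
            # float argument via a pure-rational re-evaluation
            exact_at_float = central_beta_literal_fraction(
                Fraction(float(x)), Fraction(a), b
            )
            assert Fraction(r.lo) <= exact_at_float <= Fraction(r.hi)
            assert abs(float(exact) - float(exact_at_float)) < 1e-12

    def test_diff_carrier_consistent_with_plain(self, rng):
        """The generic autodiff path and the specialized interval path
        enclose the same function."""
        for _ in range(50):
            a = rng.uniform(0.5, 10.0)
            b = rng.randint(1, 30)
            lo = rng.uniform(0.0, 0.98)
            x = Interval(lo, lo + rng.uniform(0, 0.02))
            plain = central_beta_cdf(x, a, b)
            diff = central_beta_cdf(DiffInterval.variable(x), a, b)
            ref = float(mp_central_beta(x.mid(), a, b))
            assert plain.lo - 1e-30 <= ref <= plain.hi + 1e-30
            assert diff.val.lo - 1e-30 <= ref <= diff.val.hi + 1e-30

    def test_derivative_is_beta_density(self, rng):
        """The autodiff derivative of I_x(a,b) encloses the beta density
        x^(a-1)(1-x)^(b-1)/B(a,b)."""
        import mpmath

        for _ in range(30):
            a = rng.uniform(0.5, 10.0)
            b = rng.randint(1, 20)
            x = rng.uniform(0.05, 0.95)
            d = central_beta_cdf(DiffInterval.variable(point(x)), a, b)
            dens = float(
                mpf(x) ** (a - 1) * (1 - mpf(x)) ** (b - 1)
                / mpmath.beta(a, b)
            )
            assert d.der.lo - 1e-10 <= dens <= d.der.hi + 1e-10


class TestNoncentralBeta:
    def test_zero_lambda_reduces_to_central(self, rng):
        for _ in range(30):
            a = round(rng.uniform(0.5, 10.0) * 2) / 2
            b = rng.randint(1, 25)
            x = rng.uniform(0.0, 1.0)
            nc = noncentral_beta_cdf(point(x), a, b, point(0.0))
            c = central_beta_cdf(point(x), a, b)
            assert nc.lo <= c.hi and c.lo <= nc.hi  # overlap
            assert nc.wid() < c.wid() + 1e-13

    @pytest.mark.parametrize(
        "a,b,lam,x,correct",
        [(c[0], c[1], c[2], c[3], c[4]) for c in NONCENTRAL_CDF_CASES],
    )
    def test_published_cdf_values(self, a, b, lam, x, correct):
        r = noncentral_beta_cdf(point(x), a, b, point(lam))
        assert float(f"%.6e" % r.mid()) == pytest.approx(correct, abs=1e-10)
        assert r.wid() < 1e-10

    def test_b1_closed_form(self):
        # I_x(a, 1; lam) = exp(-(lam/2)(1-x)) x^a
        x, a, lam = 0.9025, 0.5, 46.1803
        r = noncentral_beta_cdf(point(x), a, 1, point(lam))
        expect = math.exp(-(lam / 2) * (1 - x)) * x ** a
        assert abs(r.mid() - expect) < 1e-12
        assert abs(r.mid() - 0.10) < 1e-5

    def test_domain_errors(self):
        with pytest.raises(IntervalDomainError):
            noncentral_beta_cdf(point(0.5), 1.0, 2, Interval(-1, 1))
        with pytest.raises(ParameterError):
            noncentral_beta_cdf(point(0.5), 1.0, 2.5, point(1.0))

    def test_endpoint_identities(self, rng):
        for _ in range(10):
            a = round(rng.uniform(0.5, 10.0) * 2) / 2
            b = rng.randint(1, 50)
            lam = rng.uniform(0.0, 100.0)
            assert noncentral_beta_cdf(point(0.0), a, b, point(lam)).contains(0.0)
            assert noncentral_beta_cdf(point(1.0), a, b, point(lam)).contains(1.0)

    def test_monotone_in_x_and_lambda(self, rng):
        """Midpoints increase in x and strictly decrease in lambda."""
        for _ in range(20):
            a = round(rng.uniform(0.5, 10.0) * 2) / 2
            b = rng.randint(2, 40)
            x1 = rng.uniform(0.1, 0.5)
            x2 = rng.uniform(x1 + 0.1, 0.95)
            lam1 = rng.uniform(0.0, 50.0)
            lam2 = lam1 + rng.uniform(5.0, 100.0)
            m = lambda x, lam: noncentral_beta_cdf(
                point(x), a, b, point(lam)
            ).mid()
            assert m(x1, lam1) <= m(x2, lam1) + 1e-12
            assert m(x1, lam2) < m(x1, lam1) + 1e-12

    def test_oracle_containment_randomized(self, rng):
        """Enclosures contain the value of the defining Poisson-mixture
        series (50-digit, rigorously truncated)."""
        for _ in range(60):
            a = rng.uniform(0.5, 25.0)
            a = round(a * 2) / 2          # keep a+i exactly representable
            b = rng.randint(1, 100)
            x = rng.uniform(0.0, 1.0)
            lam = rng.uniform(0.0, 500.0)
            r = noncentral_beta_cdf(point(x), a, b, point(lam))
            val, tail = mp_noncentral_beta(x, a, b, lam)
            assert float(r.lo) - 1e-30 <= float(val) + float(tail)
            assert float(val) <= float(r.hi) + 1e-30

    def test_lambda_derivative_sign(self):
        """d/dlam of the cdf is negative (larger noncentrality shifts
        mass to the right)."""
        d = noncentral_beta_cdf(
            point(0.8640), 5, 5, DiffInterval.variable(point(54.0))
        )
        assert d.der.hi < 0.0


class TestFMapping:
    def test_mapping_values(self):
        a, b, x = f_to_beta(10, 10, 1.0)
        assert (a, b) == (5.0, 5)
        assert x.contains(0.5) and x.wid() < 1e-15

    def test_zero_w(self):
        a, b, x = f_to_beta(1, 2, 0.0)
        assert (a, b) == (0.5, 1)
        assert x.contains(0.0)

    def test_odd_nu2_rejected(self):
        with pytest.raises(ParameterError):
            f_to_beta(10, 7, 1.0)

    def test_noncentral_f_matches_beta(self):
        # w chosen so that x = 0.8640 for nu1 = nu2 = 10
        x = 0.8640
        w = 10 * x / (10 * (1 - x))
        rf = noncentral_f_cdf(point(w), 10, 10, point(54.0))
        rb = noncentral_beta_cdf(point(x), 5, 5, point(54.0))
        # same quantity up to the rounding of the w -> x mapping
        assert rf.lo <= rb.hi and rb.lo <= rf.hi
        assert abs(rf.mid() - 0.4563026) < 1e-6

    def test_central_f_against_high_precision(self, rng):
        import mpmath

        for _ in range(20):
            nu1 = rng.randint(1, 20)
            nu2 = 2 * rng.randint(1, 20)
            w = rng.uniform(0.1, 5.0)
            r = noncentral_f_cdf(point(w), nu1, nu2, point(0.0))
            x = mpf(nu1) * mpf(w) / (mpf(nu1) * mpf(w) + nu2)
            ref = float(mpmath.betainc(mpf(nu1) / 2, mpf(nu2) / 2, 0, x,
                                       regularized=True))
            assert r.lo - 1e-12 <= ref <= r.hi + 1e-12
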