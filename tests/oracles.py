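"""Independent high-precision references used only by the test suite.

These deliberately avoid the package's own evaluation path: exact
rational arithmetic (fractions.Fraction) for the four elementary
operations and the finite closed forms, and 50-digit mpmath for
transcendental quantities and for the noncentral beta cdf via its
defining Poisson-mixture series with a rigorous geometric tail bound.
"""

from __future__ import annotations

from fractions import Fraction

import mpmath
from mpmath import mp, mpf

mp.dps = 50

E_50 = mpf("2.71828182845904523536028747135266249775724709369996")


# ---------------------------------------------------------------------
# exact rational reference for elementary interval operations
# ---------------------------------------------------------------------

def frac_op(u: Fraction, v: Fraction, op: str) -> Fraction:
    if op == "+":
        return u + v
    if op == "-":
        return u - v
    if op == "*":
        return u * v
    if op == "/":
        return u / v
    raise ValueError(op)


# ---------------------------------------------------------------------
# central beta cdf references
# ---------------------------------------------------------------------

def mp_central_beta(x, a, b) -> mpf:
    """Regularized incomplete beta ratio at 50 digits (mpmath)."""
    return mpmath.betainc(mpf(a), mpf(b), 0, mpf(x), regularized=True)


def central_beta_literal_fraction(x: Fraction, a: Fraction, b: int) -> Fraction:
    """Exact rational evaluation of the integer-b closed form, written
    with literal products and powers (no incremental recurrences), as an
    independent check of the recurrence-based evaluation."""
    total = Fraction(1)
    for n in range(1, b):
        prod = Fraction(1)
        for m in range(1, n + 1):
            prod *= (a + m - 1) / Fraction(m)
        total += prod * (1 - x) ** n
    # x ** a only rational for integer a
    if a.denominator != 1:
        raise ValueError("literal rational form needs integer a")
    return x ** a.numerator * total


def noncentral_beta_literal_fraction(x: Fraction, a: Fraction, b: int,
                                     lam: Fraction):
    """Exact rational pair (coeff_i) * I_x(a+i, b-i) with literal
    factorials and powers; the exp factor is left symbolic, so the
    return value is (z, sum) with cdf = exp(-z) * sum."""
    z = lam / 2 * (1 - x)
    total = Fraction(0)
    fact = 1
    for i in range(b):
        if i > 0:
            fact *= i
        total += z ** i / fact * central_beta_literal_fraction(x, a + i, b - i)
    return z, total


def mp_noncentral_beta(x, a, b, lam, tail_stop=mpf("1e-40")):
    """Noncentral beta cdf from the defining Poisson mixture
    sum_i pois(i; lam/2) I_x(a+i, b), truncated with a rigorous
    geometric bound on the dropped tail.

    Returns ``(value, tail_bound)``: the true cdf lies in
    [value, value + tail_bound].
    """
    x = mpf(x)
    a = mpf(a)
    bm = mpf(b)
    lam = mpf(lam)
    half = lam / 2
    w = mpmath.e ** (-half)          # Poisson weight, i = 0
    I = mpmath.betainc(a, bm, 0, x, regularized=True)
    # T(a) = x^a (1-x)^b / (a B(a,b));  I_x(a+1,b) = I_x(a,b) - T(a)
    T = x ** a * (1 - x) ** bm / (a * mpmath.beta(a, bm))
    s = w * I
    i = 0
    while True:
        I = I - T
        if I < 0:
            I = mpf(0)
        T = T * x * (a + i + bm) / (a + i + 1)
        i += 1
        w = w * half / i
        s += w * I
        # rigorous geometric tail: for j > i the weight ratio
        # w_{j+1}/w_j = half/(j+1) <= r := half/(i+1) < 1, and the
        # central beta factors are decreasing in the shift and <= 1
        if i > half and w < tail_stop:
            r = half / (i + 1)
            cap = min(max(I, mpf(0)), mpf(1))
            return s, w * r / (1 - r) * cap


def mp_noncentral_f(w, nu1, nu2, lam):
    """Noncentral F cdf through the exact beta mapping."""
    w = mpf(w)
    x = nu1 * w / (nu1 * w + nu2)
    val, tail = mp_noncentral_beta(x, mpf(nu1) / 2, int(nu2) // 2, lam)
    return val, tail


def verified_digits(lo: float, hi: float) -> int:
    """Number of significant digits pinned down by an enclosure: the
    largest k such that the radius is at most half an ulp of the
    midpoint at k significant digits."""
    import math

    mid = 0.5 * (lo + hi)
    rad = 0.5 * (hi - lo)
    if rad <= 0.0:
        return 17
    if mid == 0.0:
        return 0
    e = math.floor(math.log10(abs(mid)))
    return max(0, min(17, math.floor(e + 1 - math.log10(2 * rad))))
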