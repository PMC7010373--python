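"""Verified cdf evaluation for the central and noncentral beta (and F)
distributions with integer second shape parameter.

For integer b the regularized incomplete beta function has the finite
closed form

    I_x(a, b) = x^a * (1 + sum_{n=1}^{b-1} [prod_{m=1}^{n} (a+m-1)/m] (1-x)^n)

and the noncentral beta cdf the finite mixture

    I_x(a, b; lam) = exp(-(lam/2)(1-x)) *
                     sum_{i=0}^{b-1} ((lam/2)(1-x))^i / i! * I_x(a+i, b-i),

so both are computable from the four arithmetic operations, the power
function and exp alone — evaluated here entirely in outwardly rounded
interval arithmetic, which turns each result into a mathematically
guaranteed enclosure of the true cdf value.

Terms are generated by overflow-safe recurrences (t_i = t_{i-1} * z / i and
p_n = p_{n-1} * (a+n-1)/n) rather than literal powers and factorials, which
is algebraically identical but remains finite up to b = 500 and beyond.
Every entry point accepts either a plain :class:`Interval` or a
:class:`DiffInterval` carrier for the quantity being varied, so the same
formulas serve both value and derivative enclosures.

The noncentral F cdf is reached through the exact parameter mapping
a = nu1/2, b = nu2/2, x = nu1*w / (nu1*w + nu2), which requires nu2 even.
"""

from __future__ import annotations

import math
from math import inf, nextafter

from .autodiff import DiffInterval
from .interval import Interval, IntervalDomainError, point
from .interval import _add_down, _add_up

__all__ = [
    "central_beta_cdf",
    "noncentral_beta_cdf",
    "f_to_beta",
    "noncentral_f_cdf",
    "ParameterError",
]

_UNIT = Interval(0.0, 1.0)


class ParameterError(ValueError):
    """Distribution parameters outside the supported family
    (non-integer b, non-positive a, odd nu2, negative lambda...)."""


def _check_ab(a: float, b: int):
    if not float(a) > 0.0:
        raise ParameterError(f"shape parameter a must be positive, got {a!r}")
    bf = float(b)
    if not (bf.is_integer() and bf >= 1.0):
        raise ParameterError(
            f"shape parameter b must be a positive integer, got {b!r}"
        )


def _clip_unit(res):
    """Intersect a cdf enclosure with [0,1] (the true value always lies
    there, so this only trims rounding inflation)."""
    if isinstance(res, DiffInterval):
        return DiffInterval(res.val.intersect(_UNIT), res.der)
    return res.intersect(_UNIT)


# ---------------------------------------------------------------------
# central beta cdf, Singh–Relyea closed form
# ---------------------------------------------------------------------

def central_beta_cdf(x, a: float, b: int):
    """Enclosure of the regularized incomplete beta ratio I_x(a, b).

    ``x`` is an :class:`Interval` or :class:`DiffInterval` with values in
    [0, 1]; ``a`` a positive real, ``b`` a positive integer.  Returns a
    carrier of the same kind: an interval guaranteed to contain I_x(a, b),
    plus a derivative enclosure if ``x`` carries one.
    """
    _check_ab(a, b)
    b = int(b)
    a = float(a)
    if isinstance(x, DiffInterval):
        xv = x.val
    elif isinstance(x, Interval):
        xv = x
    else:
        xv = point(float(x))
        x = xv
    if xv.is_empty:
        raise IntervalDomainError("empty interval argument")
    if xv.lo < 0.0 or xv.hi > 1.0:
        raise IntervalDomainError(f"x must lie within [0, 1], got {xv!r}")

    if isinstance(x, Interval):
        lo, hi = _central_sum_fast(x.lo, x.hi, a, b)
        return Interval(lo, hi).intersect(_UNIT)

    # generic carrier path (DiffInterval)
    if b == 1:
        return _clip_unit(x.pow_scalar(a))
    omx = 1.0 - x
    u = omx                     # (1-x)^n, incrementally
    p = point(a)                # prod_{m<=n} (a+m-1)/m, plain interval
    s = u * p + 1.0
    for n in range(2, b):
        p = p * ((point(a) + float(n - 1)) / float(n))
        u = u * omx
        s = s + u * p
    return _clip_unit(x.pow_scalar(a) * s)


def _central_sum_fast(xlo: float, xhi: float, a: float, b: int):
    """Endpoint-level evaluation of the closed form for a plain interval
    0 <= [xlo, xhi] <= 1.  All intermediate quantities are non-negative,
    so each partial result needs only a lower bound from the lower
    endpoints and an upper bound from the upper endpoints.  Returns the
    (lo, hi) pair of the enclosure of I_x(a, b).

    Kept free of object allocation: this is the hot inner loop of the
    noncentral double sum (O(b^2) work at b = 500).
    """
    # (1 - x) with tight directed rounding via two-sum
    omlo = _add_down(1.0, -xhi)
    if omlo < 0.0:
        omlo = 0.0
    omhi = _add_up(1.0, -xlo)

    p_lo = 1.0
    p_hi = 1.0
    u_lo = 1.0
    u_hi = 1.0
    ts_lo = [1.0]   # term n = 0
    ts_hi = [1.0]
    for n in range(1, b):
        # c = a + n - 1 with directed bounds (exact for dyadic a)
        k = float(n - 1)
        c_lo = _add_down(a, k)
        c_hi = _add_up(a, k)
        # p *= (a+n-1)/n  (non-negative scalars; one outward step per
        # rounding operation)
        p_lo = nextafter(nextafter(p_lo * c_lo, -inf) / n, -inf)
        p_hi = nextafter(nextafter(p_hi * c_hi, inf) / n, inf)
        if p_lo < 0.0:
            p_lo = 0.0
        # u *= (1-x)
        u_lo = nextafter(u_lo * omlo, -inf) if u_lo > 0.0 and omlo != 0.0 else 0.0
        u_hi = nextafter(u_hi * omhi, inf) if u_hi != 0.0 and omhi != 0.0 else 0.0
        if u_lo < 0.0:
            u_lo = 0.0
        t_lo = p_lo * u_lo
        if t_lo != 0.0:
            t_lo = nextafter(t_lo, -inf)
        t_hi = p_hi * u_hi
        if t_hi != 0.0:
            t_hi = nextafter(t_hi, inf)
            ts_lo.append(max(t_lo, 0.0))
            ts_hi.append(t_hi)
        else:
            break
    # pairwise (tree) accumulation: O(log b) rounding depth per term
    # instead of O(b), which keeps the sum tight at large b
    while len(ts_lo) > 1:
        nxt_lo = [
            _add_down(ts_lo[j], ts_lo[j + 1])
            for j in range(0, len(ts_lo) - 1, 2)
        ]
        nxt_hi = [
            _add_up(ts_hi[j], ts_hi[j + 1])
            for j in range(0, len(ts_hi) - 1, 2)
        ]
        if len(ts_lo) % 2:
            nxt_lo.append(ts_lo[-1])
            nxt_hi.append(ts_hi[-1])
        ts_lo = nxt_lo
        ts_hi = nxt_hi
    s_lo = ts_lo[0]
    s_hi = ts_hi[0]
    # x^a factor
    if xlo == 0.0:
        xa_lo = 0.0
    else:
        xa_lo = nextafter(nextafter(math.pow(xlo, a), -inf), -inf)
        if xa_lo < 0.0:
            xa_lo = 0.0
    if xhi == 0.0:
        xa_hi = 0.0
    else:
        xa_hi = nextafter(nextafter(math.pow(xhi, a), inf), inf)
    lo = xa_lo * s_lo
    if lo != 0.0:
        lo = nextafter(lo, -inf)
    hi = xa_hi * s_hi
    if hi != 0.0:
        hi = nextafter(hi, inf)
        if hi == inf:
            hi = 1.0  # cdf value; [0,1] clip applied by caller anyway
    return (max(lo, 0.0), min(hi, 1.0))


# ---------------------------------------------------------------------
# noncentral beta cdf, Sibuya finite mixture
# ---------------------------------------------------------------------

def noncentral_beta_cdf(x, a: float, b: int, lam):
    """Enclosure of the noncentral beta cdf I_x(a, b; lam).

    Exactly one of ``x`` and ``lam`` may be a :class:`DiffInterval`
    (the differentiation variable); the other is a plain interval or
    number.  lam must be >= 0; lam = [0,0] reduces to the central cdf.
    """
    _check_ab(a, b)
    b = int(b)
    a = float(a)

    x_diff = isinstance(x, DiffInterval)
    lam_diff = isinstance(lam, DiffInterval)
    if x_diff and lam_diff:
        raise ValueError("only one of x and lam may carry a derivative")

    xv = x.val if x_diff else (x if isinstance(x, Interval) else point(float(x)))
    if not x_diff and not isinstance(x, Interval):
        x = xv
    lv = lam.val if lam_diff else (
        lam if isinstance(lam, Interval) else point(float(lam))
    )
    if not lam_diff and not isinstance(lam, Interval):
        lam = lv

    if xv.is_empty or lv.is_empty:
        raise IntervalDomainError("empty interval argument")
    if xv.lo < 0.0 or xv.hi > 1.0:
        raise IntervalDomainError(f"x must lie within [0, 1], got {xv!r}")
    if lv.lo < 0.0:
        raise IntervalDomainError(f"lambda must be >= 0, got {lv!r}")

    # central I_x(a+i, b-i) factors; constants unless x is the variable.
    # The shifted shape a+i must be exactly representable or the shifted
    # central evaluations would silently target perturbed parameters;
    # this always holds for the half-integer a arising from F degrees of
    # freedom.
    cs = []
    for i in range(b):
        ai = a + float(i)
        if i and ai - float(i) != a:
            raise ParameterError(
                f"a={a!r} cannot be shifted by {i} without rounding; "
                "use a shape parameter with a short binary fraction "
                "(e.g. a half-integer)"
            )
        cs.append(central_beta_cdf(x, ai, b - i))

    z = (lam * 0.5) * (1.0 - x)          # (lam/2)(1-x), carrier
    s = cs[0]                            # i = 0 term: t_0 = 1
    t = 1.0
    for i in range(1, b):
        t = t * z / float(i)             # t_i = t_{i-1} * z / i
        s = s + t * cs[i]
    res = (-z).exp() * s
    return _clip_unit(res)


# ---------------------------------------------------------------------
# F <-> beta mapping
# ---------------------------------------------------------------------

def f_to_beta(nu1: float, nu2: int, w):
    """Map noncentral-F arguments to noncentral-beta arguments.

    Returns ``(a, b, x)`` with a = nu1/2, b = nu2/2 and
    x = nu1*w / (nu1*w + nu2) computed in interval arithmetic when ``w``
    is an interval.  ``nu2`` must be a positive even integer so that b is
    a positive integer (the family this method supports).
    """
    if not float(nu1) > 0.0:
        raise ParameterError(f"nu1 must be positive, got {nu1!r}")
    nf = float(nu2)
    if not (nf.is_integer() and nf > 0.0 and int(nf) % 2 == 0):
        raise ParameterError(
            f"nu2 must be a positive even integer, got {nu2!r} "
            "(odd denominator degrees of freedom are not supported)"
        )
    a = float(nu1) / 2.0
    b = int(nf) // 2
    w_iv = w if isinstance(w, (Interval, DiffInterval)) else point(float(w))
    wv = w_iv.val if isinstance(w_iv, DiffInterval) else w_iv
    if wv.lo < 0.0:
        raise IntervalDomainError(f"w must be >= 0, got {wv!r}")
    num = w_iv * float(nu1)
    x = num / (num + float(nu2))
    return a, b, _clip_unit(x)


def noncentral_f_cdf(w, nu1: float, nu2: int, lam):
    """Enclosure of the noncentral F cdf F(w; nu1, nu2, lam), nu2 even."""
    a, b, x = f_to_beta(nu1, nu2, w)
    return noncentral_beta_cdf(x, a, b, lam)
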