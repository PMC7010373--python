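"""Outwardly rounded interval arithmetic over IEEE double endpoints.

An :class:`Interval` is a closed, connected subset of the extended real
line, represented by two machine floats ``lo <= hi`` (either of which may
be infinite).  Every arithmetic operation returns an interval that is
mathematically guaranteed to contain the exact real-arithmetic result:
after each endpoint is computed in native floating point it is widened
outward (away from the interval) by stepping to neighbouring representable
floats, so rounding errors can never cause the enclosure to lose the true
value.  Additions and subtractions use an error-free transformation
(two-sum) to detect when the native result is already exact, in which case
no widening is applied; multiplicative and transcendental endpoints are
widened unconditionally (one ulp for *, /, two ulps for the power,
exponential and logarithm whose libm implementations are not guaranteed
correctly rounded).

Overflowing endpoints become +/-inf, never an exception, so catastrophic
loss of precision shows up as a wide (possibly unbounded) interval rather
than a silently wrong number.  The empty interval is a canonical sentinel
(``EMPTY``) and propagates through arithmetic and set operations.
"""

from __future__ import annotations

import math
from math import inf, nextafter

__all__ = [
    "Interval",
    "EMPTY",
    "IntervalDomainError",
    "point",
    "hull",
    "intersect",
    "interior_subset",
]


class IntervalDomainError(ValueError):
    """Operation applied outside its mathematical domain (e.g. log of a
    set containing non-positive numbers, division by a set containing 0)."""


def _down(v: float) -> float:
    # next float toward -inf; -inf is a fixed point
    return nextafter(v, -inf) if v > -inf else v


def _up(v: float) -> float:
    return nextafter(v, inf) if v < inf else v


def _down2(v: float) -> float:
    return _down(_down(v))


def _up2(v: float) -> float:
    return _up(_up(v))


class Interval:
    """Closed real interval ``[lo, hi]`` with outward-rounded arithmetic.

    Mixed operands (``int`` / ``float``) are treated as exact point
    intervals.  The canonical empty interval is the module-level ``EMPTY``
    sentinel (``lo > hi``); arithmetic on empty operands yields ``EMPTY``.
    """

    __slots__ = ("lo", "hi")

    def __init__(self, lo: float, hi: float):
        lo = float(lo)
        hi = float(hi)
        if math.isnan(lo) or math.isnan(hi):
            raise ValueError("interval endpoints must not be NaN")
        if lo > hi:
            raise ValueError(f"invalid interval: lo={lo!r} > hi={hi!r}")
        self.lo = lo
        self.hi = hi

    # -- fast internal constructor (skips validation) ----------------
    @classmethod
    def _raw(cls, lo: float, hi: float) -> "Interval":
        iv = object.__new__(cls)
        iv.lo = lo
        iv.hi = hi
        return iv

    @property
    def is_empty(self) -> bool:
        return self.lo > self.hi

    # -- metrics -----------------------------------------------------
    def mid(self) -> float:
        """A machine float inside the (bounded, non-empty) interval,
        close to the exact midpoint."""
        self._require_nonempty()
        if self.lo == -inf or self.hi == inf:
            raise IntervalDomainError("midpoint of unbounded interval")
        m = 0.5 * (self.lo + self.hi)
        if not math.isfinite(m):  # (lo+hi) overflowed
            m = 0.5 * self.lo + 0.5 * self.hi
        # clamp: directed rounding cannot push m outside by construction,
        # but guard against pathological endpoint pairs
        if m < self.lo:
            m = self.lo
        elif m > self.hi:
            m = self.hi
        return m

    def wid(self) -> float:
        """Width ``hi - lo``, rounded up (tight: exact differences are
        not widened, so the width is never under-reported)."""
        self._require_nonempty()
        if self.lo == -inf or self.hi == inf:
            return inf
        return _add_up(self.hi, -self.lo)

    def rad(self) -> float:
        """Radius, half the width (halving is exact in binary)."""
        return 0.5 * self.wid()

    def mag(self) -> float:
        """Magnitude: largest absolute value in the interval."""
        self._require_nonempty()
        return max(abs(self.lo), abs(self.hi))

    def mig(self) -> float:
        """Mignitude: smallest absolute value in the interval
        (0 whenever the interval contains 0)."""
        self._require_nonempty()
        if self.lo <= 0.0 <= self.hi:
            return 0.0
        return min(abs(self.lo), abs(self.hi))

    def _require_nonempty(self):
        if self.lo > self.hi:
            raise IntervalDomainError("operation on empty interval")

    # -- set operations ----------------------------------------------
    def contains(self, v: float) -> bool:
        return self.lo <= v <= self.hi

    def intersect(self, other: "Interval") -> "Interval":
        lo = self.lo if self.lo > other.lo else other.lo
        hi = self.hi if self.hi < other.hi else other.hi
        if lo > hi:
            return EMPTY
        return Interval._raw(lo, hi)

    def hull(self, other: "Interval") -> "Interval":
        if self.is_empty:
            return other
        if other.is_empty:
            return self
        return Interval._raw(min(self.lo, other.lo), max(self.hi, other.hi))

    def interior_subset(self, other: "Interval") -> bool:
        """True iff ``self`` lies in the topological interior of ``other``
        (strict inequality at both endpoints)."""
        if self.is_empty or other.is_empty:
            return False
        return other.lo < self.lo and self.hi < other.hi

    # -- arithmetic --------------------------------------------------
    def __neg__(self) -> "Interval":
        if self.lo > self.hi:
            return EMPTY
        return Interval._raw(-self.hi, -self.lo)

    def __add__(self, other):
        if isinstance(other, Interval):
            if self.lo > self.hi or other.lo > other.hi:
                return EMPTY
            return Interval._raw(
                _add_down(self.lo, other.lo), _add_up(self.hi, other.hi)
            )
        if isinstance(other, (int, float)):
            c = float(other)
            if self.lo > self.hi:
                return EMPTY
            return Interval._raw(_add_down(self.lo, c), _add_up(self.hi, c))
        return NotImplemented

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, Interval):
            if self.lo > self.hi or other.lo > other.hi:
                return EMPTY
            return Interval._raw(
                _add_down(self.lo, -other.hi), _add_up(self.hi, -other.lo)
            )
        if isinstance(other, (int, float)):
            c = float(other)
            if self.lo > self.hi:
                return EMPTY
            return Interval._raw(_add_down(self.lo, -c), _add_up(self.hi, -c))
        return NotImplemented

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            c = float(other)
            if self.lo > self.hi:
                return EMPTY
            return Interval._raw(_add_down(c, -self.hi), _add_up(c, -self.lo))
        return NotImplemented

    def __mul__(self, other):
        if isinstance(other, Interval):
            if self.lo > self.hi or other.lo > other.hi:
                return EMPTY
            a, b, c, d = self.lo, self.hi, other.lo, other.hi
            # fast path: both operands non-negative (the common case in
            # cdf evaluation where everything lives in [0, 1] or [0, inf))
            if a >= 0.0 and c >= 0.0:
                return Interval._raw(_mul_down(a, c), _mul_up(b, d))
            ps = (_p(a, c), _p(a, d), _p(b, c), _p(b, d))
            return Interval._raw(_down(min(ps)), _up(max(ps)))
        if isinstance(other, (int, float)):
            c = float(other)
            if self.lo > self.hi:
                return EMPTY
            if c >= 0.0:
                return Interval._raw(_mul_down(self.lo, c), _mul_up(self.hi, c))
            return Interval._raw(_mul_down(self.hi, c), _mul_up(self.lo, c))
        return NotImplemented

    __rmul__ = __mul__

    def reciprocal(self) -> "Interval":
        if self.lo > self.hi:
            return EMPTY
        if self.lo <= 0.0 <= self.hi:
            raise IntervalDomainError("division by interval containing 0")
        lo = 0.0 if self.hi == inf else _down(1.0 / self.hi)
        hi = 0.0 if self.lo == -inf else _up(1.0 / self.lo)
        return Interval._raw(lo, hi)

    def __truediv__(self, other):
        if isinstance(other, Interval):
            if self.lo > self.hi or other.lo > other.hi:
                return EMPTY
            return self * other.reciprocal()
        if isinstance(other, (int, float)):
            c = float(other)
            if c == 0.0:
                raise IntervalDomainError("division by zero")
            if self.lo > self.hi:
                return EMPTY
            if c > 0.0:
                return Interval._raw(_div_down(self.lo, c), _div_up(self.hi, c))
            return Interval._raw(_div_down(self.hi, c), _div_up(self.lo, c))
        return NotImplemented

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            return point(float(other)) * self.reciprocal()
        return NotImplemented

    # -- powers ------------------------------------------------------
    def pow_int(self, n: int) -> "Interval":
        """``x ** n`` for integer n, using endpoint monotonicity by
        parity (tighter than the general power; defined for any sign of
        the base).  Negative n requires 0 not in x."""
        if self.lo > self.hi:
            return EMPTY
        if n == 0:
            return Interval._raw(1.0, 1.0)
        if n < 0:
            return self.pow_int(-n).reciprocal()
        a, b = self.lo, self.hi
        if n % 2 == 1 or a >= 0.0:
            return Interval._raw(_pow_down(a, n), _pow_up(b, n))
        if b <= 0.0:
            return Interval._raw(_pow_down(b, n), _pow_up(a, n))
        # even power of interval containing 0
        return Interval._raw(0.0, _pow_up(max(-a, b), n))

    def pow_scalar(self, e: float) -> "Interval":
        """``x ** e`` for real constant exponent, x >= 0.

        Monotone endpoint evaluation; ``0 ** e = 0`` for e > 0 (the
        continuous extension needed to evaluate cdf formulas on intervals
        touching 0).  Negative e requires lo > 0."""
        if self.lo > self.hi:
            return EMPTY
        if float(e).is_integer() and abs(e) < 2**31:
            return self.pow_int(int(e))
        if self.lo < 0.0:
            raise IntervalDomainError("negative base in real power")
        if e > 0.0:
            lo = 0.0 if self.lo == 0.0 else _down2(math.pow(self.lo, e))
            hi = 0.0 if self.hi == 0.0 else _up2(math.pow(self.hi, e))
            return Interval._raw(max(lo, 0.0), hi)
        if self.lo == 0.0:
            raise IntervalDomainError("non-positive power of interval touching 0")
        lo = _down2(math.pow(self.hi, e))
        hi = _up2(math.pow(self.lo, e))
        return Interval._raw(max(lo, 0.0), hi)

    def __pow__(self, other):
        if isinstance(other, int):
            return self.pow_int(other)
        if isinstance(other, float):
            return self.pow_scalar(other)
        if isinstance(other, Interval):
            if self.lo > self.hi or other.lo > other.hi:
                return EMPTY
            if other.lo <= 0.0:
                raise IntervalDomainError("interval exponent must be positive")
            if self.lo < 0.0:
                raise IntervalDomainError("interval base must be non-negative")
            corners = []
            for base in (self.lo, self.hi):
                for ex in (other.lo, other.hi):
                    corners.append(_pow_corner(base, ex))
            return Interval._raw(
                max(_down2(min(corners)), 0.0), _up2(max(corners))
            )
        return NotImplemented

    # -- elementary functions ----------------------------------------
    def exp(self) -> "Interval":
        if self.lo > self.hi:
            return EMPTY
        try:
            lo = math.exp(self.lo) if self.lo > -inf else 0.0
        except OverflowError:
            lo = nextafter(inf, -inf)
            return Interval._raw(lo, inf)
        try:
            hi = math.exp(self.hi) if self.hi < inf else inf
        except OverflowError:
            hi = inf
        return Interval._raw(max(_down2(lo), 0.0), _up2(hi))

    def log(self) -> "Interval":
        if self.lo > self.hi:
            return EMPTY
        if self.lo <= 0.0:
            raise IntervalDomainError("log of interval touching (-inf, 0]")
        lo = math.log(self.lo)
        hi = math.log(self.hi) if self.hi < inf else inf
        return Interval._raw(_down2(lo), _up2(hi))

    def sqrt(self) -> "Interval":
        return self.pow_scalar(0.5)

    # -- misc --------------------------------------------------------
    def __contains__(self, v) -> bool:
        return self.contains(float(v))

    def __eq__(self, other):
        if not isinstance(other, Interval):
            return NotImplemented
        if self.is_empty and other.is_empty:
            return True
        return self.lo == other.lo and self.hi == other.hi

    def __hash__(self):
        return hash((self.lo, self.hi))

    def __repr__(self):
        if self.is_empty:
            return "Interval.EMPTY"
        return f"Interval({self.lo!r}, {self.hi!r})"


EMPTY: Interval = Interval._raw(inf, -inf)
Interval.EMPTY = EMPTY


def point(v: float) -> Interval:
    """The degenerate (zero-width) interval [v, v]."""
    v = float(v)
    if math.isnan(v) or math.isinf(v):
        raise ValueError("point interval requires a finite value")
    return Interval._raw(v, v)


def hull(x: Interval, y: Interval) -> Interval:
    return x.hull(y)


def intersect(x: Interval, y: Interval) -> Interval:
    return x.intersect(y)


def interior_subset(x: Interval, y: Interval) -> bool:
    """True iff x lies in the interior of y (strict at both ends)."""
    return x.interior_subset(y)


# ---------------------------------------------------------------------
# directed endpoint helpers
# ---------------------------------------------------------------------

def _add_down(a: float, b: float) -> float:
    s = a + b
    if s == -inf:
        return s
    if s == inf:  # overflow upward: largest finite float is a valid lower bound
        return nextafter(inf, -inf)
    # two-sum error term: exact when |err| representable (always for IEEE)
    bv = s - a
    err = (a - (s - bv)) + (b - bv)
    if err < 0.0:
        return _down(s)
    return s


def _add_up(a: float, b: float) -> float:
    s = a + b
    if s == inf:
        return s
    if s == -inf:
        return nextafter(-inf, inf)
    bv = s - a
    err = (a - (s - bv)) + (b - bv)
    if err > 0.0:
        return _up(s)
    return s


def _p(a: float, b: float) -> float:
    """Endpoint product with the 0 * inf = 0 convention."""
    if a == 0.0 or b == 0.0:
        return 0.0
    return a * b


def _mul_down(a: float, b: float) -> float:
    if a == 0.0 or b == 0.0:
        return 0.0
    p = a * b
    if p == -inf:
        return p
    if p == inf:
        return nextafter(inf, -inf)
    return _down(p)


def _mul_up(a: float, b: float) -> float:
    if a == 0.0 or b == 0.0:
        return 0.0
    p = a * b
    if p == inf:
        return p
    if p == -inf:
        return nextafter(-inf, inf)
    return _up(p)


def _div_down(a: float, b: float) -> float:
    if a == 0.0:
        return 0.0
    q = a / b
    if q == -inf:
        return q
    if q == inf:
        return nextafter(inf, -inf)
    return _down(q)


def _div_up(a: float, b: float) -> float:
    if a == 0.0:
        return 0.0
    q = a / b
    if q == inf:
        return q
    if q == -inf:
        return nextafter(-inf, inf)
    return _up(q)


def _pow_down(v: float, n: int) -> float:
    if v == 0.0:
        return 0.0
    if v == inf or v == -inf:
        p = -inf if (v < 0 and n % 2) else inf
        return p if p == -inf else nextafter(inf, -inf)
    try:
        p = math.pow(v, n)
    except OverflowError:
        p = inf if (v > 0 or n % 2 == 0) else -inf
    if p == -inf:
        return p
    if p == inf:
        return nextafter(inf, -inf)
    return _down2(p)


def _pow_up(v: float, n: int) -> float:
    if v == 0.0:
        return 0.0
    if v == inf or v == -inf:
        p = (-inf if (v < 0 and n % 2) else inf)
        return p if p == inf else nextafter(-inf, inf)
    try:
        p = math.pow(v, n)
    except OverflowError:
        p = inf if (v > 0 or n % 2 == 0) else -inf
    if p == inf:
        return p
    if p == -inf:
        return nextafter(-inf, inf)
    return _up2(p)


def _pow_corner(base: float, ex: float) -> float:
    if base == 0.0:
        return 0.0  # ex > 0 guaranteed by caller
    if base == inf:
        return inf if ex > 0 else 0.0
    try:
        return math.pow(base, ex)
    except OverflowError:
        return inf
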