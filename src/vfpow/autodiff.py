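"""Forward-mode automatic differentiation on intervals.

A :class:`DiffInterval` is a pair ``(val, der)`` of intervals: ``val``
encloses the values of an expression over the input interval and ``der``
encloses its first derivative over the same input.  Propagating both
components through an expression (sum, product, quotient, power, exp, log
rules) yields a rigorous enclosure of f' that the interval Newton operator
consumes — no symbolic differentiation and no truncation error.

Constants (Python numbers or plain :class:`~vfpow.interval.Interval`
values) embed with zero derivative; the differentiation variable is seeded
with derivative [1, 1] via :meth:`DiffInterval.variable`.
"""

from __future__ import annotations

from .interval import Interval, IntervalDomainError, point

__all__ = ["DiffInterval"]

_ZERO = Interval(0.0, 0.0)
_ONE = Interval(1.0, 1.0)


def _as_interval(v) -> Interval:
    if isinstance(v, Interval):
        return v
    return point(float(v))


class DiffInterval:
    """Element of the algebra of interval differential numbers."""

    __slots__ = ("val", "der")

    def __init__(self, val: Interval, der: Interval):
        self.val = val
        self.der = der

    @classmethod
    def variable(cls, v) -> "DiffInterval":
        """Lift ``v`` as the differentiation variable (derivative [1,1])."""
        return cls(_as_interval(v), _ONE)

    @classmethod
    def constant(cls, v) -> "DiffInterval":
        """Lift ``v`` as a constant (derivative [0,0])."""
        return cls(_as_interval(v), _ZERO)

    @property
    def is_empty(self) -> bool:
        return self.val.is_empty or self.der.is_empty

    # -- arithmetic --------------------------------------------------
    def __neg__(self):
        return DiffInterval(-self.val, -self.der)

    def __add__(self, other):
        if isinstance(other, DiffInterval):
            return DiffInterval(self.val + other.val, self.der + other.der)
        if isinstance(other, (int, float, Interval)):
            return DiffInterval(self.val + other, self.der)
        return NotImplemented

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, DiffInterval):
            return DiffInterval(self.val - other.val, self.der - other.der)
        if isinstance(other, (int, float, Interval)):
            return DiffInterval(self.val - other, self.der)
        return NotImplemented

    def __rsub__(self, other):
        if isinstance(other, (int, float, Interval)):
            return DiffInterval(other - self.val, -self.der)
        return NotImplemented

    def __mul__(self, other):
        if isinstance(other, DiffInterval):
            return DiffInterval(
                self.val * other.val,
                self.der * other.val + self.val * other.der,
            )
        if isinstance(other, (int, float, Interval)):
            return DiffInterval(self.val * other, self.der * other)
        return NotImplemented

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, DiffInterval):
            g = other.val
            num = self.der * g - self.val * other.der
            return DiffInterval(self.val / g, num / g.pow_int(2))
        if isinstance(other, (int, float, Interval)):
            return DiffInterval(self.val / other, self.der / other)
        return NotImplemented

    def __rtruediv__(self, other):
        if isinstance(other, (int, float, Interval)):
            return DiffInterval.constant(other) / self
        return NotImplemented

    # -- powers ------------------------------------------------------
    def pow_int(self, n: int) -> "DiffInterval":
        """Integer power with derivative ``n * x**(n-1) * x'``."""
        if n == 0:
            return DiffInterval(_ONE, _ZERO)
        return DiffInterval(
            self.val.pow_int(n),
            self.val.pow_int(n - 1) * float(n) * self.der,
        )

    def pow_scalar(self, e: float) -> "DiffInterval":
        """Real constant power with derivative ``e * x**(e-1) * x'``.

        Using the constant-exponent rule (instead of the log-bearing
        general power rule) keeps the value part evaluable at a base
        touching 0 when e >= 1; the derivative factor x**(e-1) may then
        be unbounded, which is a sound enclosure."""
        e = float(e)
        if e.is_integer() and abs(e) < 2**31:
            return self.pow_int(int(e))
        val = self.val.pow_scalar(e)
        der = self.val.pow_scalar(e - 1.0) * e * self.der
        return DiffInterval(val, der)

    def __pow__(self, other):
        if isinstance(other, int):
            return self.pow_int(other)
        if isinstance(other, float):
            return self.pow_scalar(other)
        if isinstance(other, Interval):
            # constant interval exponent: envelope of constant-exponent rule
            val = self.val ** other
            if self.val.lo <= 0.0:
                raise IntervalDomainError(
                    "interval-exponent power requires positive base"
                )
            der = val * (other * self.der / self.val)
            return DiffInterval(val, der)
        if isinstance(other, DiffInterval):
            # f ** g, f > 0: d(f^g) = f^g * (g' log f + g f'/f)
            f, g = self.val, other.val
            if f.lo <= 0.0:
                raise IntervalDomainError("general power requires base > 0")
            val = f ** g
            inner = other.der * f.log() + g * self.der / f
            return DiffInterval(val, val * inner)
        return NotImplemented

    # -- elementary functions ----------------------------------------
    def exp(self) -> "DiffInterval":
        ev = self.val.exp()
        return DiffInterval(ev, ev * self.der)

    def log(self) -> "DiffInterval":
        return DiffInterval(self.val.log(), self.der / self.val)

    def sqrt(self) -> "DiffInterval":
        return self.pow_scalar(0.5)

    def __repr__(self):
        return f"DiffInterval(val={self.val!r}, der={self.der!r})"
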