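"""Univariate interval Newton method with verified outcomes.

The interval Newton operator

    N(f, f'; x, xt) = xt - f(xt) / f'(x)

contracts any zero of f lying in x: every root in x also lies in N(...).
Iterating ``x <- x  intersect  N(f, f'; x, mid(x))`` therefore yields one of
three mathematically rigorous outcomes:

* ``UNIQUE`` — an iterate was mapped into the *interior* of its
  predecessor, which proves existence and uniqueness of a zero in that
  iterate; the final enclosure brackets it.
* ``EMPTY``  — an intersection came out empty (or the function enclosure
  excluded zero), which proves f has no zero in the initial interval.
* ``FAILED`` — neither fact could be established within the iteration
  budget; the last enclosure may or may not contain a zero.

Function and derivative enclosures come from evaluating the target
expression on :class:`~vfpow.autodiff.DiffInterval` carriers, so the only
requirement on ``f`` is that it accepts either carrier kind.  When the
derivative enclosure straddles zero the iteration falls back to bisection
(bounded by a subdivision budget) instead of extended interval division —
adequate for the monotone cdf equations this package solves.  Near-point
iterates are epsilon-inflated before the final uniqueness test, since an
exact point interval can never be mapped into its own interior.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from math import inf, nextafter

from .autodiff import DiffInterval
from .interval import EMPTY, Interval, IntervalDomainError, point

__all__ = [
    "NewtonStatus",
    "NewtonResult",
    "DerivativeStraddlesZero",
    "newton_operator",
    "newton_iterate",
    "epsilon_inflate",
]


class NewtonStatus(enum.Enum):
    UNIQUE = "unique"
    EMPTY = "empty"
    FAILED = "failed"


class DerivativeStraddlesZero(ArithmeticError):
    """The derivative enclosure contains 0, so the plain Newton operator
    is undefined (callers bisect instead)."""


@dataclass
class NewtonResult:
    """Outcome of a verified Newton iteration."""

    status: NewtonStatus
    enclosure: Interval
    iterations: int = 0
    trace: list = field(default_factory=list)
    message: str = ""

    @property
    def verified(self) -> bool:
        return self.status is NewtonStatus.UNIQUE


def newton_operator(f, x: Interval, xt: float) -> Interval:
    """One application of the interval Newton operator on ``x`` with
    expansion point ``xt`` (a float inside ``x``).

    Returns the interval ``xt - f(xt)/f'(x)``; every zero of f in x lies
    in the result.  Raises :class:`DerivativeStraddlesZero` when the
    derivative enclosure contains 0.
    """
    if x.is_empty:
        return EMPTY
    if not x.contains(xt):
        raise ValueError("expansion point must lie in the interval")
    df = f(DiffInterval.variable(x))
    der = df.der
    if der.is_empty:
        return EMPTY
    if der.contains(0.0):
        raise DerivativeStraddlesZero(repr(der))
    fxt = f(point(xt))
    if isinstance(fxt, DiffInterval):
        fxt = fxt.val
    if fxt.is_empty:
        return EMPTY
    return point(xt) - fxt / der


def epsilon_inflate(x: Interval, eps: float) -> Interval:
    """Widen ``x`` relatively by ``eps`` and absolutely by at least one
    ulp per side, so that ``x`` lies strictly inside the result."""
    if x.is_empty:
        raise IntervalDomainError("cannot inflate empty interval")
    if not eps > 0.0:
        raise ValueError("eps must be positive")
    delta = eps * x.mag()
    lo = nextafter(x.lo - delta, -inf)
    hi = nextafter(x.hi + delta, inf)
    return Interval(lo, hi)


def _rel_wid(x: Interval) -> float:
    w = x.wid()
    m = x.mig()
    if m > 0.0:
        return w / m
    return w


def newton_iterate(
    f,
    x0: Interval,
    rel_tol: float = 1e-13,
    max_iter: int = 100,
    subdivisions: int = 64,
    keep_trace: bool = False,
) -> NewtonResult:
    """Run the verified interval Newton iteration for ``f`` on ``x0``.

    ``f`` must accept an :class:`Interval` (returning a value enclosure)
    or a :class:`DiffInterval` (returning value and derivative
    enclosures).  Iteration stops when the enclosure's relative width
    drops below ``rel_tol`` or stops shrinking; uniqueness is then
    certified through an interior-containment test, retried on
    epsilon-inflated enclosures for near-point iterates.

    Where the derivative enclosure straddles zero the interval is
    bisected (up to ``subdivisions`` splits over the whole run) and the
    halves are solved independently; sub-results are merged so that the
    overall verdict stays rigorous.
    """
    if x0.is_empty:
        raise ValueError("initial interval is empty")
    if not rel_tol > 0.0:
        raise ValueError("rel_tol must be positive")

    trace: list = []
    budget = [int(subdivisions)]
    iters = [0]
    results: list[NewtonResult] = []

    def attempt_unique(x: Interval) -> Interval | None:
        """Certify a unique zero in a neighbourhood of x; return the
        certified (possibly tightened) enclosure or None."""
        eps = 1e-10
        for _ in range(2):
            y = epsilon_inflate(x, eps)
            try:
                ny = newton_operator(f, y, y.mid())
            except (DerivativeStraddlesZero, IntervalDomainError):
                eps *= 100.0
                continue
            if ny.is_empty:
                # no zero in y >= x: contradicts nothing — treat as failure
                return None
            if ny.interior_subset(y):
                tight = ny.intersect(x)
                return tight if not tight.is_empty else ny.intersect(y)
            eps *= 100.0
        return None

    def solve(x: Interval) -> None:
        unique_seen = False
        prev_wid = inf
        while iters[0] < max_iter:
            iters[0] += 1
            if keep_trace:
                trace.append(x)
            # function/derivative enclosures over the current box
            try:
                df = f(DiffInterval.variable(x))
            except IntervalDomainError:
                results.append(
                    NewtonResult(NewtonStatus.FAILED, x, iters[0], trace,
                                 "function not evaluable on enclosure")
                )
                return
            val, der = df.val, df.der
            if val.is_empty or der.is_empty:
                results.append(NewtonResult(NewtonStatus.FAILED, x, iters[0],
                                            trace, "empty evaluation"))
                return
            if not val.contains(0.0):
                results.append(NewtonResult(NewtonStatus.EMPTY, EMPTY,
                                            iters[0], trace))
                return
            if x.lo == -inf or x.hi == inf:
                results.append(NewtonResult(NewtonStatus.FAILED, x, iters[0],
                                            trace, "unbounded iterate"))
                return
            if der.contains(0.0):
                # derivative straddles zero: bisect
                if budget[0] <= 0 or x.wid() <= 0.0:
                    results.append(
                        NewtonResult(NewtonStatus.FAILED, x, iters[0], trace,
                                     "derivative enclosure contains 0")
                    )
                    return
                budget[0] -= 1
                m = x.mid()
                solve(Interval(x.lo, m))
                solve(Interval(m, x.hi))
                return
            m = x.mid()
            try:
                fm = f(point(m))
            except IntervalDomainError:
                results.append(NewtonResult(NewtonStatus.FAILED, x, iters[0],
                                            trace, "midpoint not evaluable"))
                return
            if isinstance(fm, DiffInterval):
                fm = fm.val
            nx = point(m) - fm / der
            new = nx.intersect(x)
            if new.is_empty:
                results.append(NewtonResult(NewtonStatus.EMPTY, EMPTY,
                                            iters[0], trace))
                return
            if nx.interior_subset(x):
                unique_seen = True
            w = new.wid()
            if _rel_wid(new) <= rel_tol or w >= prev_wid:
                if unique_seen:
                    results.append(NewtonResult(NewtonStatus.UNIQUE, new,
                                                iters[0], trace))
                    return
                cert = attempt_unique(new)
                if cert is not None:
                    results.append(NewtonResult(NewtonStatus.UNIQUE, cert,
                                                iters[0], trace))
                else:
                    results.append(
                        NewtonResult(NewtonStatus.FAILED, new, iters[0], trace,
                                     "uniqueness verification failed")
                    )
                return
            prev_wid = w
            x = new
        results.append(NewtonResult(NewtonStatus.FAILED, x, iters[0], trace,
                                    "iteration budget exhausted"))

    solve(x0)

    uniques = [r for r in results if r.status is NewtonStatus.UNIQUE]
    fails = [r for r in results if r.status is NewtonStatus.FAILED]
    if len(uniques) == 1 and not fails:
        u = uniques[0]
        return NewtonResult(NewtonStatus.UNIQUE, u.enclosure, iters[0], trace)
    if not uniques and not fails:
        return NewtonResult(NewtonStatus.EMPTY, EMPTY, iters[0], trace)
    # merge everything that might hold a zero into one conservative hull
    hullv = EMPTY
    msgs = []
    for r in uniques + fails:
        hullv = hullv.hull(r.enclosure)
        if r.message:
            msgs.append(r.message)
    if len(uniques) > 1 and not fails:
        return NewtonResult(NewtonStatus.FAILED, hullv, iters[0], trace,
                            "multiple verified zeros in initial interval")
    return NewtonResult(NewtonStatus.FAILED, hullv, iters[0], trace,
                        "; ".join(msgs) or "verification failed")
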