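"""Verified power analysis: enclosing the central-beta quantile and the
noncentrality parameter of the noncentral beta/F distribution.

The three-step procedure mirrors how minimal detectable differences are
computed in ANOVA power analysis, but every step carries mathematical
guarantees:

1. Candidate values ``x_{1-alpha}`` and ``lambda`` (typically produced by
   the statistical software being cross-checked) are inflated into thin
   intervals ``[(1-eps)v, (1+eps)v]``.
2. The interval Newton method solves ``I_x(a, b) = 1 - alpha`` on the
   inflated x-interval, yielding a rigorous enclosure of the upper-alpha
   quantile of the central beta distribution — or a proof that the
   candidate interval contains no solution.
3. With the verified quantile enclosure substituted as a *thick* constant
   (so the guarantee survives), ``I_x(a, b; lambda) = beta`` is solved for
   lambda the same way.

Both solve steps also run in *wide mode* without any candidate: a verified
sign-change bracket is located first (bisection on rigorously evaluated
point values; for lambda the upper end comes from doubling until the cdf
enclosure provably drops below beta) and the interval Newton iteration is
then started on the bracket.  Since the central cdf is strictly increasing
in x and the noncentral cdf strictly decreasing in lambda, the verified
zero in the bracket is the only zero in the full initial range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import inf, nextafter

from .autodiff import DiffInterval
from .betacdf import ParameterError, central_beta_cdf, noncentral_beta_cdf
from .interval import Interval, point
from .newton import NewtonResult, NewtonStatus, newton_iterate

__all__ = [
    "BetaProblem",
    "PowerSolution",
    "inflate_candidate",
    "quantile_enclosure",
    "lambda_enclosure",
    "solve_power",
    "SANE_A_MAX",
    "SANE_B_MAX",
]

# advisory parameter range: outside it the method stays rigorous but may
# start reporting verification failures
SANE_A_MAX = 25.0
SANE_B_MAX = 500
SANE_EPS_MAX = 1e-4

_WIDE_X0 = Interval(1e-300, 1.0)


@dataclass(frozen=True)
class BetaProblem:
    """One power-analysis instance: shapes a = nu1/2 (positive real) and
    b = nu2/2 (positive integer), type I error ``alpha`` and type II error
    ``beta_err``, both in (0, 1) with ``beta_err < 1 - alpha`` (otherwise
    no positive noncentrality can push the cdf down to beta_err)."""

    a: float
    b: int
    alpha: float
    beta_err: float

    def __post_init__(self):
        if not float(self.a) > 0.0:
            raise ParameterError(f"a must be positive, got {self.a!r}")
        bf = float(self.b)
        if not (bf.is_integer() and bf >= 1):
            raise ParameterError(f"b must be a positive integer, got {self.b!r}")
        for name in ("alpha", "beta_err"):
            v = getattr(self, name)
            if not 0.0 < float(v) < 1.0:
                raise ParameterError(f"{name} must lie in (0,1), got {v!r}")
        if not self.beta_err < 1.0 - self.alpha:
            raise ParameterError(
                f"beta_err={self.beta_err!r} >= 1 - alpha={1.0 - self.alpha!r}: "
                "the central cdf at the quantile already equals 1 - alpha, "
                "so no positive lambda can satisfy the power equation"
            )

    def warn_if_outside_sane_range(self):
        if self.a > SANE_A_MAX or self.b > SANE_B_MAX:
            warnings.warn(
                f"(a={self.a}, b={self.b}) outside the tested range "
                f"a <= {SANE_A_MAX}, b <= {SANE_B_MAX}; results remain "
                "rigorous but verification may fail",
                stacklevel=3,
            )


@dataclass
class PowerSolution:
    """Verified enclosures (or refutations) for one problem instance."""

    problem: BetaProblem
    x_result: NewtonResult
    lambda_result: NewtonResult | None
    eps_x: float
    eps_lambda: float


def inflate_candidate(v: float, eps: float) -> Interval:
    """Thin interval ``[(1-eps)v, (1+eps)v]`` (endpoints outward-rounded)
    around a positive candidate value ``v``."""
    v = float(v)
    if not v > 0.0:
        raise ValueError(f"candidate value must be positive, got {v!r}")
    if not 0.0 < eps < 1.0:
        raise ValueError(f"inflation parameter must lie in (0,1), got {eps!r}")
    if eps >= SANE_EPS_MAX:
        warnings.warn(
            f"inflation parameter {eps!r} >= {SANE_EPS_MAX}: the verification "
            "may slow down or fail, though never report a wrong enclosure",
            stacklevel=2,
        )
    iv = point(v) * Interval(1.0 - eps, 1.0 + eps)
    # guarantee v strictly inside even for denormal-scale v
    return Interval(min(iv.lo, nextafter(v, -inf)), max(iv.hi, nextafter(v, inf)))


def _sign(f, v: float) -> int:
    """Rigorous sign of f at the point v: -1, +1, or 0 if the enclosure
    of f(v) contains zero (v is numerically at the root)."""
    fv = f(point(v))
    if isinstance(fv, DiffInterval):
        fv = fv.val
    if fv.hi < 0.0:
        return -1
    if fv.lo > 0.0:
        return 1
    return 0


def _bracketed_newton(f, lo: float, hi: float, s_lo: int,
                      rel_tol: float, max_iter: int) -> NewtonResult:
    """Newton iteration preceded by verified-sign bisection.

    ``[lo, hi]`` must bracket a sign change (``s_lo`` is the verified sign
    at ``lo``).  The bracket is bisected on rigorously evaluated point
    values until the interval Newton iteration certifies a unique zero,
    which point evaluations keep tight even where whole-interval
    enclosures of the cdf formulas are badly overestimated.
    """
    for _ in range(80):
        width = hi - lo
        mid_scale = max(abs(lo), abs(hi), 1e-300)
        if width / mid_scale < 0.25 or width < 4e-16 * mid_scale:
            res = newton_iterate(f, Interval(lo, hi), rel_tol=rel_tol,
                                 max_iter=max_iter)
            if res.status is not NewtonStatus.FAILED:
                return res
        m = 0.5 * (lo + hi)
        if not lo < m < hi:
            break
        s = _sign(f, m)
        if s == 0:
            # m is numerically at the root: shrink around it and verify
            break
        if s == s_lo:
            lo = m
        else:
            hi = m
    return newton_iterate(f, Interval(lo, hi), rel_tol=rel_tol,
                          max_iter=max_iter)


def quantile_enclosure(a: float, b: int, alpha: float,
                       x0: Interval | None = None,
                       rel_tol: float = 1e-13,
                       max_iter: int = 100) -> NewtonResult:
    """Verified enclosure of the upper-``alpha`` quantile of the central
    beta distribution: the solution x of ``I_x(a, b) = 1 - alpha``.

    ``x0`` is the initial interval (a thin inflated candidate in the
    cross-checking use case).  Without ``x0`` the full wide interval just
    inside [0, 1] is searched via a verified sign-change bracket.
    Returns UNIQUE with the enclosure, EMPTY if ``x0`` provably contains
    no solution, or FAILED.
    """
    target = 1.0 - alpha

    def f(u):
        return central_beta_cdf(u, a, b) - target

    if x0 is not None:
        x0 = x0.intersect(_WIDE_X0)
        if x0.is_empty:
            raise ValueError("initial interval does not meet (0, 1]")
        return newton_iterate(f, x0, rel_tol=rel_tol, max_iter=max_iter)

    lo, hi = _WIDE_X0.lo, _WIDE_X0.hi
    s_lo = _sign(f, lo)   # I_x -> 0 as x -> 0, so f < 0 here
    s_hi = _sign(f, hi)
    if s_lo == 0 or s_hi == 0 or s_lo == s_hi:
        return newton_iterate(f, _WIDE_X0, rel_tol=rel_tol, max_iter=max_iter)
    return _bracketed_newton(f, lo, hi, s_lo, rel_tol, max_iter)


def lambda_enclosure(a: float, b: int, beta_err: float, x_enc: Interval,
                     lam0: Interval | None = None,
                     rel_tol: float = 1e-13,
                     max_iter: int = 100) -> NewtonResult:
    """Verified enclosure of the noncentrality parameter: the solution of
    ``I_x(a, b; lambda) = beta_err`` with x fixed at the verified quantile
    enclosure ``x_enc``.

    ``x_enc`` enters as a thick interval constant, so the returned
    enclosure is valid for *every* x in ``x_enc`` — the guarantee from the
    quantile step propagates.  Without ``lam0``, the search interval
    [0, Lambda] is built by doubling Lambda until the cdf enclosure lies
    provably below ``beta_err``.
    """
    if x_enc.is_empty or x_enc.lo <= 0.0 or x_enc.hi >= 1.0:
        raise ValueError(
            f"x_enc must be a verified quantile enclosure within (0,1), "
            f"got {x_enc!r}"
        )
    # the central I_x(a+i, b-i) factors do not depend on lambda: compute
    # them once over the thick x constant and reuse them in every Newton
    # step (they dominate the cost at large b)
    b = int(b)
    for i in range(1, b):
        if a + float(i) - float(i) != a:
            raise ParameterError(
                f"a={a!r} cannot be shifted by {i} without rounding"
            )
    cs = [central_beta_cdf(x_enc, a + float(i), b - i) for i in range(b)]
    omx_half = (1.0 - x_enc) * 0.5

    def g(u):
        z = u * omx_half
        s = cs[0]
        t = 1.0
        for i in range(1, b):
            t = t * z / float(i)
            s = s + t * cs[i]
        val = (-z).exp() * s
        if isinstance(val, DiffInterval):
            val = DiffInterval(val.val.intersect(Interval(0.0, 1.0)), val.der)
        else:
            val = val.intersect(Interval(0.0, 1.0))
        return val - beta_err

    if lam0 is not None:
        if lam0.lo < 0.0:
            raise ValueError(f"lambda interval must be >= 0, got {lam0!r}")
        return newton_iterate(g, lam0, rel_tol=rel_tol, max_iter=max_iter)

    # wide mode: verified doubling bracket
    s0 = _sign(g, 0.0)
    if s0 <= 0:
        # cdf at lambda=0 is 1-alpha <= beta_err: no positive solution
        return newton_iterate(g, Interval(0.0, 1.0), rel_tol=rel_tol,
                              max_iter=max_iter)
    cap = float(2 ** 60)
    lam_hi = 1.0
    while lam_hi <= cap:
        s = _sign(g, lam_hi)
        if s < 0:
            return _bracketed_newton(g, 0.0, lam_hi, s0, rel_tol, max_iter)
        lam_hi *= 2.0
    raise ValueError(
        "could not bracket lambda below 2**60; check problem parameters"
    )


def solve_power(problem: BetaProblem,
                x_cand: float | None = None,
                lam_cand: float | None = None,
                eps_x: float = 1e-6,
                eps_lambda: float = 1e-6,
                rel_tol: float = 1e-13,
                max_iter: int = 100) -> PowerSolution:
    """Run the full verified power analysis for one problem instance.

    With candidates, Step 1 inflates them (radius ``eps_x`` and
    ``eps_lambda``); without, wide initial intervals are searched.  Step 3
    (the lambda solve) runs only when Step 2 produced a verified quantile
    enclosure, since the lambda equation is meaningless without one.
    """
    problem.warn_if_outside_sane_range()

    if x_cand is not None:
        x0 = inflate_candidate(x_cand, eps_x).intersect(Interval(0.0, 1.0))
        if x0.is_empty:
            raise ValueError(f"inflated x candidate lies outside (0,1)")
        x_res = quantile_enclosure(problem.a, problem.b, problem.alpha, x0,
                                   rel_tol=rel_tol, max_iter=max_iter)
    else:
        x_res = quantile_enclosure(problem.a, problem.b, problem.alpha,
                                   rel_tol=rel_tol, max_iter=max_iter)

    lam_res = None
    if x_res.status is NewtonStatus.UNIQUE:
        if lam_cand is not None:
            lam0 = inflate_candidate(lam_cand, eps_lambda)
            lam_res = lambda_enclosure(problem.a, problem.b, problem.beta_err,
                                       x_res.enclosure, lam0,
                                       rel_tol=rel_tol, max_iter=max_iter)
        else:
            lam_res = lambda_enclosure(problem.a, problem.b, problem.beta_err,
                                       x_res.enclosure,
                                       rel_tol=rel_tol, max_iter=max_iter)
    return PowerSolution(problem, x_res, lam_res, eps_x, eps_lambda)
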