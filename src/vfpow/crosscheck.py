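"""Batch cross-checking of candidate quantile / noncentrality values.

This is the tool's primary use case: a statistical package under test
produces ``x_{1-alpha}`` and ``lambda`` for a grid of problems; each pair
is inflated into thin intervals and the interval Newton method delivers a
per-record verdict:

* ``VERIFIED`` — the candidate interval provably contains the true value
  (the software under test is at least as accurate as the inflation
  radius);
* ``REJECTED`` — the candidate interval provably does *not* contain the
  true value (the software's error exceeds the inflation radius);
* ``FAILED``   — verification was inconclusive (rare; typically cured by
  increasing the radius);
* ``SKIPPED``  — the lambda step never ran because the x step did not
  verify.

Input records are plain whitespace-separated text, one problem per line,
in either the beta parametrization ``a b alpha beta x_cand lambda_cand``
or the F parametrization ``nu1 nu2 alpha beta x_cand lambda_cand`` (nu2
even).  ``#`` starts a comment.  The module also provides the
significant-digit comparator used to score candidate cdf values against
verified enclosures, and a fixture generator that emulates software under
test (exact, noisy, or overflow-corrupted output).
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .betacdf import ParameterError
from .interval import EMPTY, Interval
from .newton import NewtonStatus
from .solver import BetaProblem, inflate_candidate, solve_power

__all__ = [
    "CrossCheckRecord",
    "Verdict",
    "VerdictStatus",
    "ParseError",
    "parse_input_file",
    "parse_records",
    "crosscheck",
    "count_correct_sigdigits",
    "generate_fixtures",
    "format_report",
    "REPORT_COLUMNS",
]


class ParseError(ValueError):
    """Malformed input line (carries the 1-based line number)."""


class VerdictStatus(enum.Enum):
    VERIFIED = "VERIFIED"
    REJECTED = "REJECTED"
    FAILED = "FAILED"
    SKIPPED = "SKIPPED"
    ERROR = "ERROR"


@dataclass(frozen=True)
class CrossCheckRecord:
    """One parsed input line: a problem instance plus the two candidate
    values to be cross-checked."""

    id: str
    a: float
    b: int
    alpha: float
    beta_err: float
    x_cand: float
    lam_cand: float


@dataclass
class Verdict:
    """Outcome of cross-checking one record."""

    record: CrossCheckRecord
    x_status: VerdictStatus
    lambda_status: VerdictStatus
    x_enclosure: Interval = field(default_factory=lambda: EMPTY)
    lambda_enclosure: Interval = field(default_factory=lambda: EMPTY)
    message: str = ""


_STATUS_FROM_NEWTON = {
    NewtonStatus.UNIQUE: VerdictStatus.VERIFIED,
    NewtonStatus.EMPTY: VerdictStatus.REJECTED,
    NewtonStatus.FAILED: VerdictStatus.FAILED,
}


# ---------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------

def parse_records(lines: Iterable[str], dialect: str = "beta",
                  source: str = "<input>") -> list[CrossCheckRecord]:
    """Parse whitespace-separated candidate records.

    ``dialect`` selects the first two fields: ``beta`` reads ``a b``
    directly; ``f`` reads ``nu1 nu2`` and maps them through a = nu1/2,
    b = nu2/2 (nu2 must be even).  Blank lines and ``#`` comments are
    ignored.  A malformed line raises :class:`ParseError` naming the
    line; an odd nu2 is also a parse-time error for that line.
    """
    if dialect not in ("beta", "f"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 6:
            raise ParseError(
                f"{source}:{lineno}: expected 6 fields "
                f"({'a b' if dialect == 'beta' else 'nu1 nu2'} alpha beta "
                f"x_cand lambda_cand), got {len(fields)}"
            )
        try:
            vals = [float(v) for v in fields]
        except ValueError as exc:
            raise ParseError(f"{source}:{lineno}: {exc}") from None
        if dialect == "f":
            nu1, nu2 = vals[0], vals[1]
            if not (nu2 > 0 and float(nu2).is_integer() and int(nu2) % 2 == 0):
                raise ParseError(
                    f"{source}:{lineno}: nu2 must be a positive even "
                    f"integer, got {fields[1]}"
                )
            a, b = nu1 / 2.0, int(nu2) // 2
        else:
            a, b = vals[0], vals[1]
            if not (b > 0 and float(b).is_integer()):
                raise ParseError(
                    f"{source}:{lineno}: b must be a positive integer, "
                    f"got {fields[1]}"
                )
            b = int(b)
        alpha, beta_err, x_cand, lam_cand = vals[2], vals[3], vals[4], vals[5]
        for name, v in (("alpha", alpha), ("beta", beta_err),
                        ("x_cand", x_cand), ("lambda_cand", lam_cand)):
            if not (v > 0.0 and v < float("inf")):
                raise ParseError(
                    f"{source}:{lineno}: {name} must be finite and "
                    f"positive, got {v!r}"
                )
        records.append(CrossCheckRecord(
            id=str(lineno), a=a, b=b, alpha=alpha, beta_err=beta_err,
            x_cand=x_cand, lam_cand=lam_cand,
        ))
    return records


def parse_input_file(path, dialect: str = "beta") -> list[CrossCheckRecord]:
    """Parse a candidate file (see :func:`parse_records`)."""
    with open(path, "rt", encoding="utf-8") as fh:
        return parse_records(fh, dialect=dialect, source=str(path))


# ---------------------------------------------------------------------
# cross-checking
# ---------------------------------------------------------------------

def crosscheck(records: Sequence[CrossCheckRecord],
               eps_x: float = 1e-6,
               eps_lambda: float = 1e-6,
               rel_tol: float = 1e-13,
               max_iter: int = 100) -> list[Verdict]:
    """Run the verified power analysis for every record independently.

    A record whose parameters are invalid (or whose solve raises) yields
    an ``ERROR`` verdict; it never aborts the batch.
    """
    verdicts = []
    for rec in records:
        try:
            problem = BetaProblem(rec.a, rec.b, rec.alpha, rec.beta_err)
            sol = solve_power(problem, rec.x_cand, rec.lam_cand,
                              eps_x=eps_x, eps_lambda=eps_lambda,
                              rel_tol=rel_tol, max_iter=max_iter)
        except (ParameterError, ValueError) as exc:
            verdicts.append(Verdict(rec, VerdictStatus.ERROR,
                                    VerdictStatus.SKIPPED, message=str(exc)))
            continue
        x_status = _STATUS_FROM_NEWTON[sol.x_result.status]
        if x_status is VerdictStatus.REJECTED:
            # echo the refuted (inflated) input interval in the report
            x_enc = inflate_candidate(rec.x_cand, eps_x)
        else:
            x_enc = sol.x_result.enclosure
        if sol.lambda_result is None:
            lam_status = VerdictStatus.SKIPPED
            lam_enc = EMPTY
            msg = f"x candidate {x_status.value.lower()}; lambda step skipped"
        else:
            lam_status = _STATUS_FROM_NEWTON[sol.lambda_result.status]
            if lam_status is VerdictStatus.REJECTED:
                lam_enc = inflate_candidate(rec.lam_cand, eps_lambda)
            else:
                lam_enc = sol.lambda_result.enclosure
            msg = sol.lambda_result.message or sol.x_result.message
        verdicts.append(Verdict(rec, x_status, lam_status, x_enc, lam_enc,
                                msg))
    return verdicts


# ---------------------------------------------------------------------
# significant-digit comparator
# ---------------------------------------------------------------------

def _round_sig(v: float, k: int) -> str:
    return f"%.{k - 1}e" % v


def count_correct_sigdigits(candidate: float, verified: Interval,
                            max_digits: int = 7) -> int:
    """Number of correct significant digits of ``candidate`` against a
    verified enclosure.

    Returns the largest ``k <= max_digits`` such that the candidate and
    the enclosure midpoint agree after both are rounded to k significant
    digits; 0 if they disagree already at one digit.  The enclosure must
    be tight enough that rounding its midpoint to ``max_digits`` digits
    is unambiguous (both endpoints round identically), otherwise the
    comparison would be meaningless and an error is raised.
    """
    if verified.is_empty:
        raise ValueError("verified enclosure is empty")
    if _round_sig(verified.lo, max_digits) != _round_sig(verified.hi, max_digits):
        raise ValueError(
            f"enclosure {verified!r} too wide to compare at "
            f"{max_digits} significant digits"
        )
    mid = verified.mid()
    best = 0
    for k in range(1, max_digits + 1):
        if _round_sig(candidate, k) == _round_sig(mid, k):
            best = k
        else:
            break
    return best


# ---------------------------------------------------------------------
# fixture generation (emulating software under test)
# ---------------------------------------------------------------------

def generate_fixtures(grid: Sequence[tuple], error_model: str = "exact",
                      seed: int = 0, delta: float = 1e-3,
                      eps: float = 1e-9) -> str:
    """Produce candidate records as an emulated software-under-test would.

    ``grid`` lists ``(a, b, alpha, beta)`` tuples.  For each, the solver
    itself provides reference values (enclosure midpoints at inflation
    radius ``eps``, obtained in wide mode), which are then corrupted
    according to ``error_model``:

    * ``exact`` — emitted unchanged (an accurate implementation);
    * ``relative-perturb`` — lambda multiplied by ``1 +/- delta`` (random
      sign, seeded), emulating a mildly inaccurate implementation;
    * ``overflow-bogus`` — lambda replaced by a wildly wrong value
      (seeded factor of 1e3–1e6), emulating silent overflow corruption.

    Returns the file content as text (parseable by
    :func:`parse_records`); byte-identical for identical inputs and seed.
    """
    if error_model not in ("exact", "relative-perturb", "overflow-bogus"):
        raise ValueError(f"unknown error model {error_model!r}")
    rng = random.Random(seed)
    out = [
        "# synthetic cross-check fixture",
        f"# error model: {error_model}",
        "# a b alpha beta x_cand lambda_cand",
    ]
    for a, b, alpha, beta_err in grid:
        problem = BetaProblem(float(a), int(b), float(alpha), float(beta_err))
        sol = solve_power(problem)
        if (sol.x_result.status is not NewtonStatus.UNIQUE
                or sol.lambda_result is None
                or sol.lambda_result.status is not NewtonStatus.UNIQUE):
            raise RuntimeError(
                f"reference solve failed for (a={a}, b={b}): cannot "
                "generate a fixture record"
            )
        x_val = sol.x_result.enclosure.mid()
        lam_val = sol.lambda_result.enclosure.mid()
        if error_model == "relative-perturb":
            lam_val *= 1.0 + delta * rng.choice((-1.0, 1.0))
        elif error_model == "overflow-bogus":
            lam_val *= 10.0 ** rng.uniform(3.0, 6.0)
        out.append(
            f"{a!r} {int(b)} {alpha!r} {beta_err!r} "
            f"{x_val!r} {lam_val!r}"
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------

REPORT_COLUMNS = (
    "id", "a", "b", "alpha", "beta",
    "x_status", "x_lo", "x_hi",
    "lambda_status", "lambda_lo", "lambda_hi", "message",
)


def _fmt_bound(v: float, digits: int, direction: int) -> str:
    """Scientific-notation bound rounded outward so the printed interval
    still encloses the in-memory one."""
    if v == float("inf"):
        return "inf"
    if v == float("-inf"):
        return "-inf"
    s = f"%.{digits - 1}e" % v
    r = float(s)
    if direction < 0 and r > v:
        # step the printed mantissa down one unit in the last place
        s = f"%.{digits - 1}e" % _nudge(v, s, digits, -1)
    elif direction > 0 and r < v:
        s = f"%.{digits - 1}e" % _nudge(v, s, digits, +1)
    return s


def _nudge(v: float, s: str, digits: int, direction: int) -> float:
    mant, exp = s.split("e")
    step = 10.0 ** (int(exp) - digits + 1)
    return float(s) + direction * step


def format_report(verdicts: Sequence[Verdict], digits: int = 12) -> str:
    """TSV report: one row per verdict, enclosure bounds printed with
    outward rounding at ``digits`` significant digits."""
    lines = ["\t".join(REPORT_COLUMNS)]
    for v in verdicts:
        rec = v.record
        if v.x_enclosure.is_empty:
            x_lo = x_hi = "-"
        else:
            x_lo = _fmt_bound(v.x_enclosure.lo, digits, -1)
            x_hi = _fmt_bound(v.x_enclosure.hi, digits, +1)
        if v.lambda_enclosure.is_empty:
            lam_lo = lam_hi = "-"
        else:
            lam_lo = _fmt_bound(v.lambda_enclosure.lo, digits, -1)
            lam_hi = _fmt_bound(v.lambda_enclosure.hi, digits, +1)
        lines.append("\t".join((
            rec.id, repr(rec.a), str(rec.b), repr(rec.alpha),
            repr(rec.beta_err),
            v.x_status.value, x_lo, x_hi,
            v.lambda_status.value, lam_lo, lam_hi,
            v.message or "-",
        )))
    return "\n".join(lines) + "\n"
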