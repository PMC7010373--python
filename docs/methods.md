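# Methods

## The model and the two equations

The power of an ANOVA *F* test against an alternative with
noncentrality λ is governed by the noncentral-*F* cdf. Through the
exact parameter mapping a = ν₁/2, b = ν₂/2, x = ν₁w/(ν₁w + ν₂) the
problem becomes one about the noncentral *beta* distribution, and for
integer b both cdfs have *finite* closed forms built from the four
arithmetic operations, the power function and exp alone:

    I_x(a,b)   = x^a (1 + Σ_{n=1}^{b-1} [Π_{m=1}^{n} (a+m-1)/m] (1-x)^n)
    I_x(a,b;λ) = e^{-(λ/2)(1-x)} Σ_{i=0}^{b-1} ((λ/2)(1-x))^i / i! · I_x(a+i, b-i)

The package encloses two roots: the upper-α quantile x₁₋α with
I_x(a,b) = 1 − α, and the noncentrality λ with I_{x₁₋α}(a,b;λ) = β.
Both functions are strictly monotone in the unknown (increasing in x,
decreasing in λ), so each equation has exactly one root; the difficulty
is entirely in evaluating the sums without silent precision loss, which
is what the interval arithmetic guarantees against.

## Outward rounding policy

Endpoints are IEEE doubles. After each endpoint operation the result is
widened away from the interval:

* `+`, `−`: a two-sum error-free transformation detects whether the
  native result is exact; if not, the affected endpoint steps one
  representable float outward. Exact sums (e.g. integer endpoints) are
  not widened at all.
* `×`, `÷`: one `nextafter` step per endpoint, unconditionally
  (nearest rounding errs by at most half an ulp, one step always
  covers it). Division is x · [1/ȳ, 1/y̲] as in the operational
  definitions; endpoint products use the 0 · ∞ = 0 convention.
* `^`, `exp`, `log`: two steps per endpoint, since libm implementations
  are not guaranteed correctly rounded (observed errors are below one
  ulp; two steps leave a safety margin). Integer powers use endpoint
  monotonicity by parity, which is tighter than the general power and
  well-defined for negative bases.

Overflow produces an infinite endpoint — a valid, if useless, bound —
never an exception; underflow at a lower endpoint clamps at 0 where the
quantity is provably non-negative. The empty interval is a canonical
sentinel that propagates through arithmetic and set operations (the
Newton intersection step needs it).

## Evaluating the sums

Terms are generated by the recurrences tᵢ = tᵢ₋₁·z/i (z = (λ/2)(1−x))
and pₙ = pₙ₋₁·(a+n−1)/n — algebraically identical to the printed
factorial forms but finite at b = 500, where 499! would overflow any
machine float. The i = 0 term of the noncentral sum is taken as
I_x(a,b) directly, avoiding 0⁰ at x = 1 or λ = 0, and x^a at an
endpoint touching 0 is defined as 0 for a > 0 via the monotone
endpoint rule. Every cdf enclosure is intersected with [0, 1]: the true
value lies there, so the intersection only trims rounding inflation.

Two evaluation paths exist. Plain-interval inputs use a specialized
endpoint-level loop (all intermediate quantities are non-negative, so
lower bounds need only lower endpoints and vice versa); this is the
O(b²) hot path of the noncentral double sum. Autodiff carriers take the
generic operator-overloading path. The central sum accumulates its
terms **pairwise** (tree reduction) rather than linearly: with ~500
slowly-decaying terms, linear accumulation costs O(b) rounding steps
per term and limits quantile enclosures to ~11 significant digits at
b = 500, while the tree's O(log b) depth keeps all grid cells at ≥ 12.

The shifted shapes a + i that appear inside the noncentral sum must be
exactly representable, otherwise the shifted central factors would be
silently evaluated at perturbed parameters and the enclosure guarantee
would be void; the package raises a parameter error in that case. For
the intended inputs (a = ν₁/2 with integer ν₁) the condition always
holds.

## Derivatives

The interval Newton operator needs an enclosure of f′ over an interval.
Forward-mode automatic differentiation on pairs (value interval,
derivative interval) supplies it: sums, products, quotients, powers and
exp/log propagate both components by the usual rules, evaluated in
interval arithmetic. Constant exponents use the rule e·x^{e−1}·x′
rather than the log-bearing general power rule, so the quantile
equation stays differentiable on intervals touching x = 0 (the
derivative factor may be unbounded there — a sound enclosure). Only
first derivatives are needed.

## Interval Newton iteration

One step maps x to x ∩ (x̌ − f(x̌)/f′(x)), with x̌ the midpoint. The
iteration delivers:

* **EMPTY** — an intersection was empty, or the function enclosure over
  the current box excluded 0: f provably has no root there.
* **UNIQUE** — some operator image landed in the *interior* of its
  argument, which proves existence and uniqueness; iteration then
  continues until the relative width falls below `rel_tol`
  (default 10⁻¹³) or stops shrinking.
* **FAILED** — neither could be established (iteration budget
  `max_iter` = 100).

If the derivative enclosure straddles zero the box is bisected (up to
64 subdivisions per run) and the halves solved independently; extended
interval division is deliberately omitted — the target equations are
monotone, so straddling only occurs on overwide boxes, and the
value-exclusion test discards root-free halves quickly.

Near-point iterates can never be mapped *strictly* inside themselves,
so when width convergence precedes an interior-containment event the
final enclosure is ε-inflated (relative 10⁻¹⁰, at least one ulp per
side, one retry at ×100) and a single operator step is applied to the
inflated box to certify uniqueness.

Stopping uses relative width against the mignitude; unbounded iterates
abort as FAILED.

## The three-step verified solve

1. **Inflation.** A candidate v becomes [(1−ε)v, (1+ε)v] with
   ε = 10⁻⁶ by default (values ≥ 10⁻⁴ only warn: the method may slow
   down or fail to verify, but can never emit a wrong enclosure).
   Non-positive candidates are rejected — multiplicative inflation is
   meaningless at 0.
2. **Quantile.** Newton on I_x(a,b) − (1−α) over the inflated interval
   (or wide mode, below). EMPTY refutes the candidate; FAILED aborts
   step 3.
3. **Noncentrality.** Newton on I_x(a,b;λ) − β where x is the *entire*
   verified enclosure from step 2, entering as a thick interval
   constant. This is the choice that preserves the guarantee: the λ
   enclosure is then valid for every x in the x-enclosure, so the two
   guarantees compose. The λ-independent central factors I_x(a+i, b−i)
   are computed once per solve and reused across iterations (they
   dominate the cost at large b; each is still evaluated independently
   by the closed form).

### Wide mode

Without candidates the initial intervals are [10⁻³⁰⁰, 1] for x and
[0, Λ] for λ, with Λ found by doubling until the cdf enclosure at the
point Λ lies provably below β (capped at 2⁶⁰). Closed-form enclosures
over such wide boxes are enormously overestimated (the (1−x)ⁿ powers
and x^a factors decorrelate), so the Newton bisection budget would be
exhausted before the derivative enclosure becomes single-signed at
large b. Instead the solver first narrows the range by **verified-sign
bisection**: the function is evaluated at midpoints as thin point
intervals — which the arithmetic keeps tight (~10⁻¹³ relative) — and
the rigorous sign of each value shrinks the bracket; once the bracket
is moderately narrow the interval Newton iteration runs on it and
certifies the root. Monotonicity of both equations means the verified
unique root in the bracket is the only root in the full initial range.
If a midpoint's value enclosure contains 0, the midpoint is already at
the root to ~full precision and Newton takes over immediately.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| ε_x, ε_λ | 10⁻⁶ | candidate inflation radius (dimensionless, relative) |
| rel_tol | 10⁻¹³ | Newton stopping width, relative to the enclosure |
| max_iter | 100 | Newton iteration budget per solve |
| subdivisions | 64 | bisection budget on derivative straddling |
| sane range | a ≤ 25, b ≤ 500 | advisory; outside it the package warns but stays rigorous |

The acceptance tests reproduce the full published 9 × 22 grid
(α = 0.05, β = 0.10) in wide mode — about 15 s on one CPU — and run
the randomized suites at 10³ cases each, with shapes a drawn as
half-integers (the representability condition above), b uniform on
1…500 and λ uniform on [0, 2500].

## What the synthetic fixtures emulate — and what they do not

`generate_fixtures` emulates a statistical package under test: the
solver's own enclosure midpoints serve as "reported" values, optionally
corrupted by a seeded relative perturbation (10⁻³ by default — an
implementation losing ~3 digits) or by a wildly wrong factor of
10³–10⁶ (emulating silent overflow corruption of the kind that has
produced bogus published tables). Only λ is corrupted, so the λ verdict
isolates the error model; a corrupted x would merely skip the λ step.
The fixtures exercise the verdict logic end to end, but they cannot
stand in for a real third-party implementation's error *structure*
(e.g. errors correlated across the grid, or x and λ wrong together);
passing them shows the verdicts are sound and sensitive at the stated
radii, not that any particular external package is accurate.

## Known limitations

* Non-integer b (odd ν₂) is outside the method: the closed forms are
  what make finite, special-function-free evaluation possible.
* Tightness degrades gracefully, not catastrophically: enclosures on
  wide input boxes are valid but overestimated; all precision claims
  refer to thin inputs (points or inflated candidates).
* The uniqueness statuses quantify roots of the *evaluated expressions*
  over the given initial interval; wide-mode uniqueness over the full
  parameter range additionally relies on monotonicity of the cdf in its
  argument, which is a property of the distribution, not of the
  arithmetic.
* Trigonometric functions, multi-dimensional boxes and higher-order
  (Taylor-model) arithmetic are out of scope.
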