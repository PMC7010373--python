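# vfpow — self-validating power computations for the noncentral-F test

Computations involving the noncentral-*F* distribution are notoriously
fragile in floating point: silent overflow, underflow and catastrophic
cancellation have repeatedly produced published tables of minimal
detectable differences with *no* correct significant digits — while
looking perfectly plausible. `vfpow` computes the quantities involved
with **guaranteed accuracy**, so it can be used to cross-check any other
statistical package automatically.

Every result is an *enclosure*: an interval that provably contains the
true value, maintained through outwardly rounded interval arithmetic
(each floating-point endpoint is widened away from the interval after
every operation) and verified root-finding with the interval Newton
method.

## What it computes

For an ANOVA *F* test with ν₁, ν₂ degrees of freedom, write
a = ν₁/2, b = ν₂/2 (b must be a positive integer, i.e. ν₂ even) and
x = ν₁w/(ν₁w + ν₂). The package encloses:

* the **central beta cdf** I_x(a, b) via the finite closed form
  I_x(a,b) = xᵃ (1 + Σₙ₌₁^{b−1} (Πₘ₌₁ⁿ (a+m−1)/m) (1−x)ⁿ);
* the **noncentral beta / noncentral F cdf**
  I_x(a,b;λ) = e^{−(λ/2)(1−x)} Σᵢ₌₀^{b−1} ((λ/2)(1−x))ⁱ/i! · I_x(a+i, b−i),
  evaluated with overflow-safe term recurrences (never literal
  factorials — the formula stays finite up to b = 500 and beyond);
* the **upper-α quantile** x₁₋α solving I_x(a,b) = 1 − α;
* the **noncentrality parameter** λ solving I_{x₁₋α}(a,b;λ) = β, the
  quantity behind minimal-detectable-difference tables
  (power = 1 − β).

The interval Newton iteration
x⁽ᵏ⁺¹⁾ = x⁽ᵏ⁾ ∩ (x̌⁽ᵏ⁾ − f(x̌⁽ᵏ⁾)/f′(x⁽ᵏ⁾)), with derivative
enclosures from forward-mode automatic differentiation on intervals,
ends in one of three *mathematically rigorous* outcomes: a unique root
enclosed, a proof that no root exists in the initial interval, or an
explicit verification failure. Cross-checking inflates a candidate
value v into [(1−ε)v, (1+ε)v] (default ε = 10⁻⁶) and reports which
outcome the iteration reaches: `VERIFIED` means the software under test
is at least as accurate as ε; `REJECTED` means its error provably
exceeds ε.

## Worked example

Verified wide-mode solve (no candidate values needed) for
a = 5, b = 10, α = 0.05, β = 0.10:

```text
$ vfpow solve -a 5 -b 10 --wide
x_1-alpha: UNIQUE  [5.40005446524e-01, 5.40005446524e-01]  mid=5.40005446524e-01
lambda   : UNIQUE  [3.10600250474e+01, 3.10600250474e+01]  mid=3.10600250474e+01
```

Both equations were solved with guaranteed error control: the true
quantile and noncentrality lie inside the printed intervals (bounds are
rounded outward; at 12 digits they often print identically). A power
program reporting λ = 31.06 here is accurate to the 4 digits it prints.

Cross-checking a candidate file (fields: `a b alpha beta x_cand
lambda_cand`; `#` comments allowed; `--params f` accepts `nu1 nu2`
instead of `a b`):

```text
$ cat candidates.txt
0.5 1 0.05 0.10 0.9025 46.1803
1 1 0.05 0.10 0.95 90.052
$ vfpow crosscheck candidates.txt
id  a    b  alpha  beta  x_status  x_lo             x_hi             lambda_status  lambda_lo         lambda_hi         message
1   0.5  1  0.05   0.1   VERIFIED  9.02499999999e-01  9.02500000001e-01  VERIFIED   4.61803445867e+01  4.61803445869e+01  -
2   1.0  1  0.05   0.1   VERIFIED  9.49999999999e-01  9.50000000001e-01  REJECTED   9.00519099479e+01  9.00520900521e+01  -
```

Record 1 is verified: both candidates sit within 10⁻⁶ of the truth
(for b = 1 the closed form λ = 2(a·ln x − ln β)/(1−x) = 46.18034…
confirms it). Record 2's λ = 90.052 is **proved wrong** at radius
10⁻⁶ — the true value is 90.05167…, a relative error of 4·10⁻⁶; the
rejected row echoes the refuted input interval.

`vfpow demo-e` prints the classic sanity exhibit: interval evaluation of
(1 + 1/n)ⁿ and (1 − 1/n)⁻ⁿ for n = 10ᵏ, k = 1…17. Plain floating point
produces supposed lower bounds that exceed e; the interval version
always brackets e = 2.718281828…, and signals precision loss through
visibly wide intervals instead of silently wrong digits.

## Scope and limitations

* b = ν₂/2 must be a positive integer (even denominator degrees of
  freedom); this is what makes the closed forms finite.
* The tested parameter range is a ≤ 25, b ≤ 500, 0.01 ≤ α, β ≤ 0.99.
  Outside it the package warns but remains rigorous: an enclosure, once
  printed, is always correct — at worst verification fails explicitly.
* Shifted shapes a + i must be exactly representable floats (always
  true for a = ν₁/2 with integer ν₁).

See `docs/methods.md` for the numerical design: rounding policy,
Newton stopping rules, ε-inflation, and the verified bracketing used in
wide mode.
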