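# Methods

## Setting and notation

Two studies address the same effect in the pre-specified direction: an
original with one-sided p-value `p_o` and a replication with `p_r`.
One-sided p-values are `p = 1 − Φ(z)` with `z` the effect estimate divided
by its standard error; `p > 0.5` simply means the estimate points the wrong
way and needs no special casing anywhere. The *intersection null* — both
true effects zero — makes `p_o` and `p_r` independent standard uniforms,
and a combination method is *valid* when its combined p-value is uniform
under that null. All methods here are used at the overall one-sided level
`α² ` (0.000625 for `α = 0.025`), the level the two-trials rule implies.

Inputs exactly 0 or 1 are clipped to `[1e-16, 1 − 1e-16]` with a logged
warning so z-transforms stay finite; ordinary inputs are never altered.

## The combination methods

| method | statistic | combined p | success region |
|---|---|---|---|
| two-trials | `max(p_o, p_r)` | `max²` | both `≤ α` |
| Edgington | `E = p_o + p_r` | Irwin–Hall(2) CDF at `E` | `E ≤ b = √2·α` |
| weighted Edgington | `E_w = w_o p_o + w_r p_r` | weighted-sum CDF at `E_w` | `E_w ≤ b_w = √(2 w_o w_r)·α` |
| Fisher | `−2 log(p_o p_r)` | χ²₄ survival | `p_o p_r ≤ c_F` |
| meta-analysis | `z_MA = (z_o + √c z_r)/√(1+c)` | normal survival | `z_MA ≥ z_{1−α²}` |

The Irwin–Hall CDF is computed by the alternating-sum closed form with
compensated summation on the scalar path and the truncated-power identity
on the array path; it is restricted to `n ≤ 10` summands because the
closed form loses precision catastrophically beyond that (the package
needs at most `n = 3`). The weighted-sum CDF is the three-piece polynomial
on `(0, w_o]`, `(w_o, w_r]`, `(w_r, w_o + w_r]`; it is stated for
`w_o ≤ w_r`, and since the distribution is symmetric in the weight labels
the implementation sorts the weights internally, so any positive pair is
accepted. Branch points evaluate on the lower branch (the pieces are
closed on the right); the pieces agree there to well below 1e-12. Only the
weight ratio matters: all outputs are invariant under rescaling both
weights by a positive constant. The default weighting 1:2 up-weights the
replication, reflecting the concern that original studies are the more
bias-prone of the two; it doubles the budget on `E_w` to `2α` while
capping the replication's effective level at `α`.

The budget formulas invert only the first CDF branch and are guarded:
`b_w > min(w_o, w_r)` raises rather than silently returning an invalid
threshold. Success at exact equality `p ≤ α²` counts as success.

## Operating characteristics

Every criterion has the form `p_r ≤ t(p_o)`, so the *conditional Type-I
error rate* given the original result equals the threshold `t(p_o)` itself:
`b − p_o` (Edgington), `(b_w − w_o p_o)/w_r` (weighted), `min(c_F/p_o, 1)`
(Fisher), a shifted normal tail (meta), and `α·1{p_o ≤ α}` (two-trials).
The Edgington variants keep this bounded by `b ≈ 0.035` and `b_w/w_r =
0.025`; Fisher and meta let it grow toward 1 as `p_o → 0` — the meta
threshold does so only logarithmically slowly (0.993 at `p_o = 1e-12`).

*Project power* uses the normal model: `z_o ~ N(μ_o, 1)` with
`μ_o = z_{1−α} + Φ⁻¹(original power)`, and `z_r ~ N(d·√c·μ_o, 1)`
independently, where `d = θ_r/θ_o` is the effect ratio and `c = n_r/n_o`
the relative sample size. This is the unique normal model in which the
original study has its stated design power and the replication's
noncentrality scales with `√c` and `d`. Two-trials and meta have closed
forms (a product of normal tails; a single tail at the shifted `z_MA`
mean). The other methods integrate the conditional replication power over
`z_o` with adaptive quadrature on `μ_o ± 8.5` (abs tolerance well under
1e-6); the z-scale is used because the integrand is smooth there, whereas
the p-scale density spikes at 0. The `c → ∞` limits are reported by a
separate closed form `Φ(μ_o − z_{1−L})` with `L` the method's admissibility
bound on `p_o` (`α`, `b`, or `b_w/w_o`), rather than by evaluating at a
huge `c`, for exactness; they require `d > 0` (otherwise `p_r` stays
uniform in the limit and the function raises).

## Replication design

Sample sizes follow the balanced two-sample z-test formula with the
method-specific level `α'` = the conditional threshold above in place of
`α`: per-group `n_r = 2τ²(z_{1−α'} + z_{1−β})²/θ̂_o²` (reported real-valued
and ceiled) and relative `c = (z_{1−α'} + z_{1−β})²/z_o²`. An optional
shrinkage fraction deflates `θ̂_o` before use (common choices 0.25–0.5,
against inflation of published effects). Unweighted Edgington needs a
*smaller* replication than the two-trials rule exactly when
`p_o < α(√2 − 1) ≈ 0.01`; the maximal saving, at `p_o → 0` (evaluated at
`p_o = 1e-12`, the ratio being monotone), is 10.6% at 80% power and 9.2%
at 90%.

*Predictive power* averages the replication's success probability over the
uncertainty of the original estimate using the normal-normal predictive
distribution `θ̂_r | θ̂_o ~ N(θ̂_o, σ_o² + σ_r²)`, giving
`Φ((z_o√c − z_{1−α'})/√(c+1))`. This always shrinks the conditional power
toward 1/2 (tipping point at `z_o√c = z_{1−α'}`), so predictive sample
sizes are larger. The predictive `c` is found by Brent root-finding on
`√c ∈ [1e-3, 1e3]` (tolerance 1e-10; the power is monotone in `√c` over
the bracket for attainable targets). The predictive sample-size *ratio*
against the two-trials rule has an interior minimum near `p_o = 9e-5`
(11.2% saving at 80% power) instead of the conditional case's boundary
extremum.

## Multiple replications and alpha-spending

With one original and two replications the sum `E₃ = p_o + p_r1 + p_r2` is
referred to Irwin–Hall(3); the budget inverting the small-sum branch
`b³/6 = α²` is 0.155 (≈ 0.16). For sequential conduct, an alpha-spending
plan splits `α²`: stage 1 stops for success when `E₂ = p_o + p_r1 ≤ b₂ =
√(2·fraction·α²)`, and the final budget `b₃` solves

```
∫_{b₂}^{b₃} e·(b₃ − e) de = (1 − fraction)·α² ,
```

i.e. `b₃(b₃² − b₂²)/2 − (b₃³ − b₂³)/3 = (1 − fraction)·α²`, by bracketed
Brent iteration on `(b₂, 1]` (tolerance 1e-12). The density `f_{E₂}(e) = e`
used in the integral is exact for `e ≤ 1`, which every budget in the
operating region satisfies, so no general convolution is needed. Futility
is declared only when success is arithmetically impossible (`E₂ > b₃`) —
no predictive futility bound is imposed — and otherwise the second
replication runs at level `b₃ − E₂`. An even split gives `b₂ = 0.025` and
`b₃ ≈ 0.128`; Monte Carlo over uniform triples confirms the whole
procedure spends exactly `α²`. Weighted multi-study budgets and more than
two stages are out of scope.

## Study tables

CSV tables carry either direct one-sided p-values (`study_id, po, pr[, c]`)
or correlation-scale estimates with sample sizes (`study_id, ro, no, rr,
nr`), from which `p = 1 − Φ(atanh(r)·√(n−3))` (Fisher's z-transformation).
When both are present the direct p-values win, with a logged warning. The
variance ratio defaults to `(n_r − 3)/(n_o − 3)` — the squared ratio of
Fisher-z standard errors — and to 1 when sample sizes are absent. A record
a method cannot handle yields NaN for that method rather than aborting the
table. Headline replication rates of the published large-scale projects
require their external dataset; the loader accepts such a file, but no
test or reported number depends on it — the assessment machinery is
validated on synthetic records including the two discordant pairs
(0.028 with a very strong replication; 0.027 with 0.006) that the
two-trials rule fails and both Edgington variants pass.

## The synthetic generator, and what the tests do and do not show

`simulate_pairs` draws from exactly the normal model above with numpy's
PCG64 and an explicit seed in every entry point (identical seeds give
identical pairs). Under `mu_o = 0` both p-values are uniform regardless of
`d` — the intersection null. The generator emulates the *statistical*
structure the methods assume: independent studies, normal z-values with
unit variance, noncentrality scaling in `√c`. It does not emulate
publication bias, questionable research practices, effect heterogeneity
beyond a deterministic ratio `d`, or non-normal small-sample behaviour;
passing tests therefore certify the calibration and power algebra of the
methods under their own model, not their robustness on biased real data.
Default Monte-Carlo sizes: 1e5 draws for distributional (KS) checks, 1e6
for power comparisons at 3-SE tolerance, and 1e7 where rates near 6e-4
must be resolved (≥ ~6000 expected events).

## Known limitations

- The weighted-sum CDF inverts only its first branch for budgets; weight
  ratios extreme enough to push `b_w` past the smallest weight raise an
  error instead of inverting numerically.
- The meta criterion needs the variance ratio `c`; it is the only method
  that uses more than the two p-values.
- The sequential machinery covers exactly two replications; the weighted
  multi-study rule is not specified and not implemented.
- Conditional-power sample sizes inherit the usual caveat that the
  original estimate is treated as the truth; the predictive mode mitigates
  but does not remove optimism when originals are selected for
  significance.
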