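# repsum — replication success via the sum of p-values

`repsum` assesses whether a replication study confirms an original finding.
It is written for statisticians and meta-researchers who analyse replication
projects (or plan individual replications) and want a success criterion that
is *calibrated* — the probability of declaring success when both true
effects are zero is controlled — without the rigidity of demanding that both
studies be significant on their own.

## The statistic

Let `p_o` and `p_r` be the one-sided p-values of the original and
replication study. The classical **two-trials rule** requires both to be at
most `α` (typically 0.025 one-sided), an overall Type-I error rate of `α²`.
Its combined p-value is `max(p_o, p_r)²`, and it ignores how convincing the
smaller p-value is: the pair (0.026, 0.001) fails while (0.024, 0.024)
passes.

**Edgington's method** instead sums the p-values, `E = p_o + p_r`, and
refers the sum to the Irwin–Hall distribution (the sum of independent
standard uniforms):

```
p_E = Pr(U₁ + U₂ ≤ E) = E²/2          for E ≤ 1,
```

declaring success when `p_E ≤ α²`, i.e. when the sum stays within the
*budget* `b = √2·α ≈ 0.035`. A strong replication can thus rescue a
marginal original and vice versa, while the overall Type-I error stays at
`α²`. A weighted variant `E_w = w_o·p_o + w_r·p_r` (default weights 1:2,
up-weighting the replication) uses the analogous three-piece distribution
of the weighted uniform sum, with budget `b_w = √(2·w_o·w_r)·α`.

The package also provides, as calibrated comparators, Fisher's combination
(`−2·log(p_o·p_r)` against χ²₄) and the fixed-effect meta-analysis
criterion (weighted Stouffer z), plus:

- **operating characteristics** — conditional Type-I error rates given the
  original result, Monte-Carlo verification of the overall level, and
  project power as a function of the relative sample size `c = n_r/n_o`;
- **replication design** — the method-specific significance level the
  replication must meet, absolute and relative sample sizes under
  conditional or predictive power, and sample-size ratios against the
  two-trials rule;
- **multi-study extensions** — budgets for one original plus two
  replications via Irwin–Hall(3), and a two-stage alpha-spending procedure
  with a sequential success/futility/continue rule;
- **study tables** — CSV readers for p-value or correlation-scale records
  (one-sided p-values recomputed via Fisher's z-transformation), per-study
  assessments, success-rate curves and replication-rate-by-threshold
  summaries;
- **simulation** — a seeded generator of synthetic study pairs under the
  normal model the analytical results assume, used throughout the tests as
  the Monte-Carlo oracle.

## Worked example

The two canonical pairs, from the command line:

```sh
$ repsum combine --po 0.026 --pr 0.001 --round 7
method            edgington
statistic         0.027
p_combined        0.0003645
overall_level     0.000625
success           True

$ repsum combine --po 0.024 --pr 0.024 --round 7
method            edgington
statistic         0.048
p_combined        0.001152
overall_level     0.000625
success           False
```

The first pair sums to 0.027, within the budget 0.035, so its combined
p-value 0.00036 clears the overall level `0.025² = 0.000625` — replication
success, even though the original alone was not significant at 0.025. The
second pair passes the two-trials rule but its sum 0.048 overshoots the
budget. The same computations are available in Python:

```python
from repsum import StudyPair, p_edgington
p_edgington(StudyPair(0.026, 0.001)).p_combined   # 0.0003645
```

Designing a replication for an original with `p_o = 0.005` analysed with
Edgington's method:

```sh
$ repsum design --po 0.005 --power 0.8 --round 4
replication_level 0.0304
relative_c        1.1128
```

The replication may be significant at the relaxed level `b − p_o = 0.0304`
and needs about 11% more subjects than the original for 80% conditional
power — less than the two-trials rule would require at the same power.
Planning two sequential replications with half the overall level spent at
the first:

```sh
$ repsum spend --fraction 0.5 --round 4
b2                0.025
b3                0.1277
```

Stop for success if `p_o + p_r1 ≤ 0.025`; stop for futility if the sum
exceeds 0.1277; otherwise run a second replication at level
`0.1277 − (p_o + p_r1)`.

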