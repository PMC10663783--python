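# nullregions

Interval-null hypothesis testing through one decision rule: **a test is
significant exactly when the confidence interval lies entirely outside the
prespecified null region(s)** — the span(s) of population effect values the
test seeks to rule out.

Traditional NHST tests only the point null of "no effect at all", so with
enough data any nonzero effect becomes "significant", however inconsequential.
Stating the null hypothesis as a *region* instead lets researchers ask the
questions they actually care about, and five familiar tests become one
procedure differing only in the region's geometry:

| test | question | null region H0 |
|---|---|---|
| two-sided NHST | any effect at all? | `{0}` |
| one-sided NHST | effect in the hoped-for direction? | `(-inf, 0]` |
| minimum-effect test (MET) | effect large enough to matter? | `(-inf, +delta]` or `[-delta, +delta]` |
| equivalence test (EqT) | effect practically zero? | `(-inf, -delta] U [+delta, +inf)` |
| strong-form Part 1 | far from the predicted value theta? (reject theory) | `[theta-eps, theta+eps]` |
| strong-form Part 2 | close to the predicted value? (retain theory) | `(-inf, theta-eps] U [theta+eps, +inf)` |
| non-inferiority | new treatment no more than trivially worse? | the harmful side of the margin, e.g. `[log 1.11, +inf)` on the log-hazard scale |

`delta` is the largest effect magnitude still considered inconsequential,
`eps` the tolerated deviation from a theoretical prediction, and the
non-inferiority margin the boundary of unacceptable inferiority. Regions for
ratio measures (hazard/odds ratios) live on the log scale and for
correlations on the Fisher-z scale; boundaries are supplied on the natural
scale. All finite boundaries are closed — touching a boundary is not
exclusion.

The library computes effect estimates and CIs (from summary statistics or
raw CSV data), applies the rule, combines complementary tests into
three-outcome verdicts (meaningful / practically zero / inconclusive, and
reject / retain / inconclusive for theory tests), and provides exact
normal-theory power, Monte-Carlo operating characteristics, and sample-size
search. Key operating characteristics, all verified in the test suite:

- the type-I error of a one-sided region test is capped at the implied
  one-sided alpha `(1 - level)/2`, attained at the region boundary;
- an observed effect *inside* the null region is never significant at any
  sample size (the CI always contains its own point estimate);
- for a true effect outside the region, power increases to 1 with n, and the
  probability of an inconclusive result (CI partially inside the region)
  vanishes.

## Worked example

Suppose an original study found a treatment superior in 75% of participants
and a replication in 60/100 vs 75/100 — a proportion difference of −0.15.
Is the difference from the original large enough to matter, or practically
zero? Take differences within ±0.10 to be inconsequential:

```python
from nullregions import TestSpec, combined_verdict, effect_from_two_groups, run_test

y1 = [1] * 60 + [0] * 40   # replication arm
y2 = [1] * 75 + [0] * 25   # original-rate arm
est = effect_from_two_groups(y1, y2, measure="proportion_difference")
# est.estimate = -0.15, est.se = 0.0654 (Wald)

met = run_test(TestSpec(kind="met_two_sided", delta=0.10, level=0.90, ci_method="z"), est)
eqt = run_test(TestSpec(kind="equivalence",   delta=0.10, level=0.90, ci_method="z"), est)
print(met.statement)
print(combined_verdict([met, eqt], "met_plus_eqt").statement)
```

prints

```
not significant by MET (CI partially inside the null region): 90% CI [-0.2575, -0.04245] vs null region [-0.1, 0.1].
inconclusive: the data do not provide sufficient evidence for either inference; more, and more precise, data are needed.
```

The 90% CI `[-0.257, -0.042]` straddles the boundary −0.10: the data rule
out neither "too small to matter" nor "big enough to matter", and the
composite verdict says so instead of misreading a non-significant NHST as
"no difference". How much data would settle it? For a true effect of 0.25,
per-observation SD 1 and a one-sided MET boundary at 0.10:

```python
from nullregions import required_n
required_n(TestSpec(kind="met_one_sided", delta=0.10, level=0.90), 0.25, 1.0, 0.80)
# -> 275
```

The same analyses are available from the shell:

```bash
nullregions test --kind equivalence --delta 0.2 --estimate 0.05 --se 0.05 --level 0.90 --ci-method z
nullregions power --kind met_one_sided --delta 0.10 --true-effect 0.25 --n 50 --n 200 --level 0.90
nullregions samplesize --kind met_one_sided --delta 0.10 --true-effect 0.25 --target-power 0.80 --level 0.90
nullregions simulate-data --model two_group_binomial --rate1 0.6 --rate2 0.75 --n 100 --seed 1 --out sim.csv
nullregions ambient-noise --corr corr.csv
```

Results are JSON on stdout; `ambient-noise` estimates the mean absolute
off-diagonal correlation of a large correlation matrix (the "crud" level of
incidental correlations) as a defensible floor when no substantive basis for
`delta` exists.

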