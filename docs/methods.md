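# Methods

## The decision rule

Every test in this package is a statement about where the *population*
effect lies. The null hypothesis is a region — one or two disjoint intervals
of population values — and the test is significant exactly when a two-sided
confidence interval for the effect lies entirely outside that region. If the
CI is even partially inside the region the test is not significant; the
three-way position classification (outside / overlapping / inside) is
retained because composite verdicts need to separate "the data place the
effect inside the region" from "the data are too imprecise to tell".

Two conventions make the rule unambiguous at boundaries, both chosen as the
conservative reading of "entirely outside":

- **All finite region boundaries are closed** — a boundary value belongs to
  H0.
- **The CI is treated as a closed interval** — an endpoint exactly equal to
  a closed boundary counts as overlap, so significance requires strict
  exclusion.

Ties of this kind have probability zero under any continuous sampling model;
the conventions matter only for exactness of the geometry, not for operating
characteristics.

## Geometries and scales

Regions are built from natural-scale boundary parameters and stored on an
*analysis scale* on which the normal approximation for the estimator is
reasonable:

- `identity` for mean and proportion differences;
- `log` for ratio measures. Symmetric MET/EqT half-widths are fold-change
  ratios (`delta > 1`, giving the region `[-log delta, +log delta]`, i.e.
  ratios between `1/delta` and `delta`); a non-inferiority margin must sit on
  the harmful side of 1 for the declared direction (e.g. a hazard-ratio
  margin of 1.11 with `direction="less"` yields `[log 1.11, +inf)`);
- `fisher_z` for correlations: half-widths are correlation magnitudes
  (< 1) mapped through arctanh; for the strong-form geometries
  `theta ± epsilon` is formed on the correlation scale and then transformed
  endpoint-wise, which keeps the stored region an exact image of the stated
  natural-scale one (at the cost of slight asymmetry in z units).

Because `exp` and `tanh` are strictly increasing, back-transforming a CI
endpoint-wise preserves ordering, level and every containment relation, so
the decision is identical whether taken on the analysis or the natural
scale; the package takes it on the analysis scale and reports both.

## Effect estimates

- Mean differences use the Welch (unequal-variance) standard error and
  Welch–Satterthwaite degrees of freedom by default; pooled-variance
  formulas sit behind a flag. Welch is the safer default when group
  variances may differ and costs essentially nothing when they do not.
- Proportion differences use the Wald standard error with z intervals. Wald
  is deliberately the default (rather than Wilson/Newcombe) because it makes
  the Monte-Carlo engine and the closed-form normal-theory power mutually
  consistent and transparent; for small n or extreme rates Wald intervals
  are known to under-cover.
- Correlations are analysed as Fisher-z values with the large-sample
  standard error `1/sqrt(n - 3)`; a sample correlation within `1e-12` of
  ±1 is rejected as degenerate input rather than mapped to an astronomical z.
- Hazard ratios enter only as (log-estimate, SE) summary input; no survival
  model is fitted here.
- CIs are symmetric two-sided `estimate ± q·se` with `q` a normal or
  Student-t quantile at `(1+level)/2`; the t interval is the default
  whenever degrees of freedom are known. One-sided tests consume the same
  two-sided CI, and every result reports the implied one-sided alpha
  `(1 - level)/2` so that a 90% CI is visibly a one-sided test at 0.05.

## Power and sample size

Under the summary-normal model the estimate is
`X ~ Normal(true_effect, se)` with `se = sigma/sqrt(n)` and the z CI is
`X ± q·se`. Since a CI is an interval, it avoids the whole H0 union exactly
when it fits inside one connected component `(g_lo, g_hi)` of the
complement, i.e. when `X` falls in `(g_lo + q·se, g_hi − q·se)`. Summing the
normal probability of these disjoint X-intervals over the components gives
exact rejection probabilities for all geometries; the probability of the CI
lying wholly inside H0 is computed the same way per H0 interval, and the
inconclusive probability is the remainder. Consequences, all asserted in the
tests:

- at a region boundary adjacent to a single H1 component the rejection
  probability is exactly `Phi(-q) = (1 - level)/2`, and it bounds the type-I
  error over that H0 interval;
- **bounded two-sided regions** (the point null, two-sided MET, strong
  Part 1) can reject on *either* side, so their worst-case type-I error
  approaches the sum of the two one-sided rates, `1 − level` — exactly as
  two-sided NHST with a 95% CI has type-I error 0.05. The single-alpha cap
  is a property of the single-finite-boundary geometries (one-sided tests,
  equivalence, strong Part 2);
- power is non-decreasing in n for any true effect in H1, tends to 1 in the
  interior of an H1 component, and tends to 0 for a true effect in the
  interior of H0 — the reversal of the NHST pathology in which precision
  manufactures significance;
- the inconclusive probability vanishes with n for any true effect off a
  boundary.

Monte-Carlo operating characteristics (`simulate_oc`) support the summary
model and two raw-data models (two-group normal with Welch-t intervals,
two-group binomial with Wald-z intervals) that route through the same
estimator formulas as the `effects` module. One root `SeedSequence` is
spawned into one child stream per grid cell, so tables are reproducible
independent of grid shape or evaluation order.

`required_n` searches the analytic power curve by doubling then bisection
(valid because power is monotone in n on the searched bracket), capped at
n = 10^7; an unreachable target — e.g. a true effect barely inside a narrow
H1 gap, where the CI cannot fit until astronomically large n — raises a
dedicated error carrying the power attained at the cap rather than
returning a misleading number.

## Choosing the region: ambient noise

Where no substantive basis (cost-benefit, minimal clinically important
difference, theory) fixes `delta`, the `specify` module estimates the
*ambient noise level*: the mean absolute off-diagonal entry of a large
correlation matrix, i.e. the typical magnitude of correlations between
variables with no intrinsic relation. The absolute value is used because a
symmetric region depends only on magnitude and signed means of incidental
correlations cancel toward zero; the suggested `delta` equals the mean and
is reported on the correlation scale only — converting it to other effect
measures requires design knowledge the package does not have. A zero
estimate triggers a warning that the region degenerates to the point null.
Utility analysis, MCID elicitation and practical-significance judgments are
documentation-level guidance by nature and are deliberately not implemented.

## Synthetic data

The `fixtures` module generates the three designs the package analyses:
two-group Gaussian outcomes (difference in means = the true effect, common
SD, default 1), two-group binary outcomes at two rates (the worked examples
use 0.60 vs 0.75, a −0.15 difference), and bivariate normal pairs with a
requested correlation and unit marginals. Each call uses one explicit
`numpy` Generator seeded from the scenario — no global state — so equal
specs give byte-identical datasets. These generators emulate clean,
independent, exactly-distributed sampling; they contain no measurement
error, missingness, clustering, selection or model misspecification, so
passing tests demonstrate the *statistical* operating characteristics of the
decision rule, not robustness of any real study design.

## Problem sizes and tolerances

Stochastic checks are sized so that their tolerances are principled rather
than generous: boundary type-I error uses ≥ 50,000 replicates against a
3-binomial-SE band; analytic-vs-Monte-Carlo agreement uses 20,000 replicates
per grid cell with a `3·sqrt(p(1−p)/reps)` band plus one replicate (`1/reps`)
of granularity so that cells with analytic probability at 0 or 1 remain
comparable at finite reps; the TOST cross-check runs 1,000 seeded datasets
and, with matched t intervals, the CI rule and the two one-sided Welch
t-tests are *algebraically* equivalent, so the expected disagreement count
is exactly zero. The acceptance script uses 200,000 replicates for its
reported rate. Property-based tests run derandomised so failures are
reproducible.

## Known limitations

- Normal-theory CIs only; no exact small-sample proportion or correlation
  intervals, no bootstrap.
- Analytic power assumes the summary-normal model with z intervals;
  raw-data designs are Monte Carlo only, and no power model is provided for
  correlation or hazard-ratio sampling beyond the summary approximation.
- Running MET and EqT jointly performs no multiplicity adjustment: both are
  reported at the user's level, each with its implied alpha. The two tests
  have disjoint rejection regions for the same CI, so the pair cannot
  produce contradictory significances, but familywise error across a larger
  battery of tests is the user's responsibility.
- Null regions are limited to one or two intervals; no Bayesian ROPE
  machinery.
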