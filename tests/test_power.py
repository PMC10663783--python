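"""Operating characteristics: analytic formulas vs Monte Carlo, type-I
capping, monotonicity, and the sample-size search."""

import math

import numpy as np
import pytest
from scipy import stats

from nullregions import (
    SpecificationError,
    TestSpec,
    UnreachablePowerError,
    analytic_oc,
    analytic_power,
    build_null_region,
    required_n,
    simulate_oc,
)

GEOMETRIES = [
    ("nhst_two_sided", {}),
    ("met_one_sided", {"delta": 0.10}),
    ("met_two_sided", {"delta": 0.10}),
    ("equivalence", {"delta": 0.30}),
    ("strong_part1", {"theta": 0.25, "epsilon": 0.10}),
    ("strong_part2", {"theta": 0.25, "epsilon": 0.10}),
    ("non_inferiority", {"ni_margin": 0.20}),
]


class TestAnalyticPower:
    def test_boundary_power_equals_implied_alpha(self):
        """At a single-interval boundary the rejection probability is exactly
        the one-sided alpha, for any standard error."""
        region = build_null_region("met_one_sided", delta=0.10)
        for se in (0.01, 0.3, 5.0):
            p = analytic_power(region, true_effect=0.10, se=se, level=0.90)
            assert p["p_significant"] == pytest.approx(0.05, abs=1e-12)

    def test_deep_alternative_consistency_limit(self):
        region = build_null_region("met_one_sided", delta=0.10)
        p = analytic_power(region, true_effect=0.5, se=1e-4, level=0.95)
        assert p["p_significant"] == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self):
        for kind, params in GEOMETRIES:
            region = build_null_region(kind, params)
            for mu in (-0.5, 0.0, 0.1, 0.4):
                for se in (0.05, 0.5):
                    p = analytic_power(region, mu, se, 0.95)
                    total = p["p_significant"] + p["p_inconclusive"] + p["p_inside"]
                    assert total == pytest.approx(1.0, abs=1e-9)
                    assert all(0 <= v <= 1 for v in p.values())

    def test_one_sided_formula_closed_form(self):
        """Single upper-bounded region: P = Phi((mu - b)/se - q)."""
        region = build_null_region("met_one_sided", delta=0.10)
        q = stats.norm.ppf(0.95)
        for mu, se in [(0.3, 0.08), (0.05, 0.2), (-0.2, 0.1)]:
            expected = stats.norm.cdf((mu - 0.10) / se - q)
            got = analytic_power(region, mu, se, 0.90)["p_significant"]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_central_gap_formula_closed_form(self):
        """Equivalence gap (-d, d): P = max(0, Phi((d-mu)/se - q) - Phi((-d-mu)/se + q))."""
        d = 0.3
        region = build_null_region("equivalence", delta=d)
        q = stats.norm.ppf(0.975)
        for mu, se in [(0.0, 0.05), (0.1, 0.1), (0.0, 0.4)]:
            expected = max(
                0.0,
                stats.norm.cdf((d - mu) / se - q) - stats.norm.cdf((-d - mu) / se + q),
            )
            got = analytic_power(region, mu, se, 0.95)["p_significant"]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_bounded_region_sums_two_exclusions(self):
        region = build_null_region("met_two_sided", delta=0.2)
        q = stats.norm.ppf(0.975)
        mu, se = 0.0, 0.3
        above = 1 - stats.norm.cdf((0.2 - mu) / se + q)
        below = stats.norm.cdf((-0.2 - mu) / se - q)
        got = analytic_power(region, mu, se, 0.95)["p_significant"]
        assert got == pytest.approx(above + below, abs=1e-12)

    def test_invalid_se_rejected(self):
        region = build_null_region("nhst_two_sided")
        with pytest.raises(SpecificationError):
            analytic_power(region, 0.0, 0.0, 0.95)

    def test_type_one_error_capped_over_h0_grid(self):
        """Type-I error over H0 never exceeds the CI's two-sided alpha, and
        for geometries with a single finite boundary per H0 interval (the
        one-sided tests and the central-gap tests) it never exceeds the
        implied one-sided alpha.  Bounded two-sided regions (point null,
        two-sided MET, strong Part 1) can reject on either side, so their
        boundary error approaches the sum of the two one-sided rates."""
        level = 0.90
        alpha_1s = (1 - level) / 2
        one_boundary = {"nhst_one_sided", "met_one_sided", "non_inferiority",
                        "equivalence", "strong_part2"}
        for kind, params in GEOMETRIES + [("nhst_one_sided", {})]:
            region = build_null_region(kind, params)
            cap = alpha_1s if kind in one_boundary else 2 * alpha_1s
            for iv in region.intervals:
                lo = iv.lower if math.isfinite(iv.lower) else iv.upper - 3.0
                hi = iv.upper if math.isfinite(iv.upper) else iv.lower + 3.0
                grid = [lo] if lo == hi else np.linspace(lo, hi, 21)
                for mu in grid:
                    for se in (0.02, 0.1, 0.5):
                        p = analytic_power(region, float(mu), se, level)["p_significant"]
                        assert p <= cap + 1e-12, (kind, mu, se, p)

    def test_point_null_type_one_error_is_two_sided_alpha(self):
        region = build_null_region("nhst_two_sided")
        p = analytic_power(region, 0.0, 0.3, 0.95)["p_significant"]
        assert p == pytest.approx(0.05, abs=1e-12)


class TestMonteCarloAgreement:
    @pytest.mark.parametrize("kind,params", GEOMETRIES[1:6])
    def test_analytic_matches_simulation(self, kind, params):
        spec = TestSpec(kind=kind, level=0.90, ci_method="z", **params)
        effects = [-0.3, 0.0, 0.1, 0.25, 0.5]
        ns = [10, 30, 100, 300, 1000]
        reps = 4000
        oc = simulate_oc(spec, effects, ns, reps=reps, seed=7, sigma=1.0)
        ana = analytic_oc(spec, effects, ns, sigma=1.0)
        for (_, emp), (_, ref) in zip(oc.table.iterrows(), ana.table.iterrows()):
            p = ref["p_significant"]
            tol = 3 * math.sqrt(max(p * (1 - p), 1e-12) / reps) + 1e-9
            assert abs(emp["p_significant"] - p) <= max(tol, 0.005)

    def test_boundary_rejection_rate_matches_alpha(self):
        spec = TestSpec(kind="met_one_sided", delta=0.10, level=0.90, ci_method="z")
        oc = simulate_oc(spec, 0.10, [100], reps=100_000, seed=11, sigma=1.0)
        rate = oc.table["p_significant"].iloc[0]
        tol = 3 * math.sqrt(0.05 * 0.95 / 100_000)
        assert abs(rate - 0.05) <= tol

    def test_single_rep_degenerate(self):
        spec = TestSpec(kind="nhst_two_sided", level=0.95, ci_method="z")
        oc = simulate_oc(spec, 0.5, [10], reps=1, seed=3)
        row = oc.table.iloc[0]
        for col in ("p_significant", "p_inconclusive", "p_inside"):
            assert row[col] in (0.0, 1.0)

    def test_seed_reproducibility(self):
        spec = TestSpec(kind="equivalence", delta=0.3, level=0.90, ci_method="z")
        a = simulate_oc(spec, [0.0, 0.2], [20, 50], reps=500, seed=42)
        b = simulate_oc(spec, [0.0, 0.2], [20, 50], reps=500, seed=42)
        assert a.table.equals(b.table)

    def test_probability_rows_sum_to_one(self):
        spec = TestSpec(kind="strong_part2", theta=0.2, epsilon=0.1, level=0.95,
                        ci_method="z")
        oc = simulate_oc(spec, [0.0, 0.2, 0.5], [10, 100], reps=2000, seed=5)
        sums = oc.table[["p_significant", "p_inconclusive", "p_inside"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_two_group_normal_model_tracks_summary_model(self):
        """Raw two-group simulation with per-observation SD sigma behaves like
        the summary model with effective SD sigma*sqrt(2)."""
        spec = TestSpec(kind="met_one_sided", delta=0.2, level=0.90)
        oc = simulate_oc(spec, 0.6, [50], data_model="two_group_normal",
                         reps=4000, seed=9, sigma=1.0)
        region = build_null_region("met_one_sided", delta=0.2)
        se = math.sqrt(2.0 / 50)
        ref = analytic_power(region, 0.6, se, 0.90)["p_significant"]
        assert abs(oc.table["p_significant"].iloc[0] - ref) < 0.03

    def test_two_group_binomial_model_recovers_alpha_at_boundary(self):
        spec = TestSpec(kind="met_one_sided", delta=0.10, level=0.90, ci_method="z")
        oc = simulate_oc(spec, 0.10, [800], data_model="two_group_binomial",
                         reps=5000, seed=13, model_params={"baseline_rate": 0.5})
        # Wald intervals are approximate; stay within a loose band of alpha
        assert abs(oc.table["p_significant"].iloc[0] - 0.05) < 0.02


class TestAsymptotics:
    # (geometry, params, a true effect in its H1)
    H1_CASES = [
        ("nhst_two_sided", {}, 0.45),
        ("met_one_sided", {"delta": 0.10}, 0.45),
        ("met_two_sided", {"delta": 0.10}, 0.45),
        ("equivalence", {"delta": 0.30}, 0.0),  # H1 is the central gap
        ("strong_part1", {"theta": 0.25, "epsilon": 0.10}, 0.60),
        ("strong_part2", {"theta": 0.25, "epsilon": 0.10}, 0.25),
        ("non_inferiority", {"ni_margin": 0.20}, 0.10),
    ]

    def test_power_nondecreasing_in_n(self):
        for kind, params, mu in self.H1_CASES:
            spec = TestSpec(kind=kind, level=0.90, ci_method="z", **params)
            assert not spec.build_region().contains(mu)
            oc = analytic_oc(spec, mu, [10, 30, 100, 300, 1000, 3000], sigma=1.0)
            p = oc.table["p_significant"].to_numpy()
            assert np.all(np.diff(p) >= -1e-12), (kind, p)

    def test_nhst_vs_met_contrast(self):
        """For a tiny-but-nonzero true effect, point-null NHST power climbs to
        1 with n while MET power (effect inside the region) falls to 0."""
        mu = 0.05
        nhst = TestSpec(kind="nhst_two_sided", level=0.95, ci_method="z")
        met = TestSpec(kind="met_two_sided", delta=0.2, level=0.95, ci_method="z")
        ns = [100, 1000, 10_000, 100_000]
        p_nhst = analytic_oc(nhst, mu, ns).table["p_significant"].to_numpy()
        p_met = analytic_oc(met, mu, ns).table["p_significant"].to_numpy()
        assert np.all(np.diff(p_nhst) > 0)
        assert p_nhst[-1] > 0.999
        assert np.all(np.diff(p_met) <= 1e-12)
        assert p_met[-1] < 1e-6

    def test_inconclusiveness_vanishes_off_boundary(self):
        spec = TestSpec(kind="equivalence", delta=0.3, level=0.90, ci_method="z")
        for mu in (0.0, 0.5):  # interior of gap / interior of H0
            oc = analytic_oc(spec, mu, [10, 100, 1000, 100_000])
            p_inc = oc.table["p_inconclusive"].to_numpy()
            assert p_inc[-1] < 1e-6
            assert p_inc[-1] <= p_inc[0]


class TestRequiredN:
    def test_matches_exhaustive_scan(self):
        spec = TestSpec(kind="met_one_sided", delta=0.10, level=0.90)
        n = required_n(spec, true_effect=0.25, sigma=1.0, target_power=0.80)
        region = build_null_region("met_one_sided", delta=0.10)
        powers = [
            analytic_power(region, 0.25, 1.0 / math.sqrt(k), 0.90)["p_significant"]
            for k in range(1, 5001)
        ]
        brute = next(k for k, p in zip(range(1, 5001), powers) if p >= 0.80)
        assert n == brute

    def test_effect_in_h0_rejected(self):
        spec = TestSpec(kind="met_one_sided", delta=0.10, level=0.90)
        with pytest.raises(SpecificationError, match="inside null region"):
            required_n(spec, true_effect=0.10, sigma=1.0, target_power=0.5)

    def test_unreachable_signalled(self):
        # just past the boundary, power is barely above alpha at any n within
        # the cap, so an ambitious target is unreachable
        spec = TestSpec(kind="equivalence", delta=0.10, level=0.90)
        with pytest.raises(UnreachablePowerError):
            required_n(spec, true_effect=0.0999, sigma=1.0, target_power=0.99,
                       n_cap=10_000)

    def test_monotone_in_effect_distance(self):
        spec = TestSpec(kind="met_one_sided", delta=0.10, level=0.90)
        ns = [
            required_n(spec, true_effect=mu, sigma=1.0, target_power=0.80)
            for mu in (0.15, 0.25, 0.50, 1.00)
        ]
        assert ns == sorted(ns, reverse=True)
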