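"""The single decision rule: is the CI entirely outside the null region?

Every test of the framework is conducted the same way: build the null region
for the chosen geometry, compute a confidence interval for the effect, and
declare significance if and only if the interval lies *entirely outside* the
region.  A confidence-interval endpoint exactly on a closed region boundary
counts as overlap — exclusion must be strict.

Beyond the binary verdict, the position of the CI relative to the region is
classified three ways (outside / overlapping / inside) because composite
verdicts need to distinguish "the effect is inside the region and the data
show it" from "the data are not precise enough to tell" — the inconclusive
outcome.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Mapping, Sequence

from .effects import (
    ConfidenceInterval,
    EffectEstimate,
    back_transform,
    compute_ci,
)
from .errors import ConsistencyError, SpecificationError
from .regions import (
    Interval,
    NullRegion,
    Scale,
    TestKind,
    build_null_region,
    region_contains,
)

__all__ = [
    "Position",
    "Verdict",
    "TestSpec",
    "TestResult",
    "CompositeVerdict",
    "ci_outside_region",
    "run_test",
    "combined_verdict",
    "render_statement",
    "result_to_json",
    "result_from_json",
]


class Position(str, Enum):
    """Position of the confidence interval relative to the H0 union."""

    outside_all = "outside_all"
    overlaps_region = "overlaps_region"
    inside_region = "inside_region"


class Verdict(str, Enum):
    significant = "significant"
    not_significant = "not_significant"


#: Human-readable test names used in rendered statements.
_KIND_NAMES = {
    TestKind.nhst_two_sided: "two-sided NHST",
    TestKind.nhst_one_sided: "one-sided NHST",
    TestKind.met_one_sided: "MET",
    TestKind.met_two_sided: "MET",
    TestKind.equivalence: "EqT",
    TestKind.strong_part1: "strong-form Part 1",
    TestKind.strong_part2: "strong-form Part 2",
    TestKind.non_inferiority: "the non-inferiority test",
}


@dataclass(frozen=True)
class TestSpec:
    """A complete test specification: geometry, boundaries, CI settings.

    Boundary parameters are on the natural scale (see
    :func:`nullregions.regions.build_null_region`).  ``ci_method`` of ``None``
    defaults to the t interval when the estimate carries degrees of freedom
    and the z interval otherwise.
    """

    kind: TestKind
    level: float = 0.95
    ci_method: str | None = None
    scale: Scale = Scale.identity
    direction: str = "greater"
    delta: float | None = None
    delta_lower: float | None = None
    delta_upper: float | None = None
    theta: float | None = None
    epsilon: float | None = None
    ni_margin: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", TestKind(self.kind))
        object.__setattr__(self, "scale", Scale(self.scale))
        if not (0 < self.level < 1):
            raise SpecificationError(f"confidence level must be in (0, 1), got {self.level}")

    @property
    def implied_alpha(self) -> float:
        """One-sided type-I level implied by the two-sided CI: (1 - level)/2."""
        return (1.0 - self.level) / 2.0

    def region_params(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("delta", "delta_lower", "delta_upper", "theta", "epsilon", "ni_margin")
            if getattr(self, k) is not None
        }

    def build_region(self) -> NullRegion:
        return build_null_region(
            self.kind, self.region_params(), direction=self.direction, scale=self.scale
        )

    def to_dict(self) -> dict:
        d = {"kind": self.kind.value, "level": self.level, "scale": self.scale.value,
             "direction": self.direction}
        if self.ci_method is not None:
            d["ci_method"] = self.ci_method
        d.update(self.region_params())
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TestSpec":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class TestResult:
    """Outcome of one test: verdict, CI position, and provenance."""

    verdict: Verdict
    position: Position
    ci: ConfidenceInterval
    region: NullRegion
    implied_alpha: float
    statement: str = ""

    def __post_init__(self) -> None:
        if (self.verdict is Verdict.significant) != (self.position is Position.outside_all):
            raise ConsistencyError(
                "verdict must be 'significant' exactly when the CI is outside the region"
            )

    def to_dict(self) -> dict:
        d = {
            "verdict": self.verdict.value,
            "position": self.position.value,
            "ci": self.ci.to_dict(),
            "region": self.region.to_dict(),
            "implied_alpha": self.implied_alpha,
            "statement": self.statement,
        }
        if self.ci.scale is not Scale.identity:
            nat = back_transform(self.ci)
            d["ci_natural_scale"] = {"lower": nat.lower, "upper": nat.upper}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TestResult":
        return cls(
            verdict=Verdict(d["verdict"]),
            position=Position(d["position"]),
            ci=ConfidenceInterval.from_dict(d["ci"]),
            region=NullRegion.from_dict(d["region"]),
            implied_alpha=float(d["implied_alpha"]),
            statement=str(d.get("statement", "")),
        )


class CompositeOutcome(str, Enum):
    meaningful = "meaningful"
    practically_zero = "practically_zero"
    reject_theory = "reject_theory"
    retain_theory = "retain_theory"
    inconclusive = "inconclusive"


@dataclass(frozen=True)
class CompositeVerdict:
    """Joint outcome of complementary tests run on the same estimate.

    ``met_plus_eqt`` pairs a minimum-effect test with an equivalence test:
    the effect is *meaningful*, *practically zero*, or the data are
    *inconclusive*.  ``strong_form`` pairs Parts 1 and 2: *reject theory*,
    *retain theory*, or *inconclusive* (more, and more precise, data needed).
    """

    kind: str
    outcome: CompositeOutcome
    components: tuple[TestResult, ...]
    statement: str = ""


def _ci_disjoint_from(iv: Interval, lo: float, hi: float) -> bool:
    """Is the closed CI [lo, hi] disjoint from the region interval?

    The CI is treated as closed, so touching a closed region boundary is
    contact (not disjoint); touching an open boundary is still disjoint.
    """
    if hi < iv.lower or (hi == iv.lower and not iv.lower_closed):
        return True
    if lo > iv.upper or (lo == iv.upper and not iv.upper_closed):
        return True
    return False


def ci_outside_region(ci: ConfidenceInterval, region: NullRegion) -> Position:
    """Classify the position of a CI relative to the H0 union.

    ``outside_all``: the closed interval [lower, upper] shares no point with
    any H0 interval.  ``inside_region``: the CI is wholly contained in the H0
    union.  ``overlaps_region`` otherwise — the inconclusive configuration.
    """
    if ci.scale != region.scale:
        raise SpecificationError(
            f"CI is on the {ci.scale.value} scale but the region is on "
            f"{region.scale.value}"
        )
    lo, hi = ci.lower, ci.upper
    if all(_ci_disjoint_from(iv, lo, hi) for iv in region.intervals):
        return Position.outside_all
    ci_as_interval = Interval(lo, hi, True, True)
    if any(iv.contains_interval(ci_as_interval) for iv in region.intervals):
        return Position.inside_region
    return Position.overlaps_region


def run_test(spec: TestSpec, est: EffectEstimate) -> TestResult:
    """Run one test: build the region, compute the CI, apply the rule."""
    if est.scale != spec.scale:
        raise SpecificationError(
            f"estimate is on the {est.scale.value} scale but the test is specified "
            f"on {spec.scale.value}"
        )
    region = spec.build_region()
    ci = compute_ci(est, level=spec.level, method=spec.ci_method)
    position = ci_outside_region(ci, region)
    verdict = Verdict.significant if position is Position.outside_all else Verdict.not_significant
    result = TestResult(
        verdict=verdict,
        position=position,
        ci=ci,
        region=region,
        implied_alpha=spec.implied_alpha,
    )
    return TestResult(
        verdict=verdict,
        position=position,
        ci=ci,
        region=region,
        implied_alpha=spec.implied_alpha,
        statement=render_statement(result),
    )


def _natural_region_text(region: NullRegion) -> str:
    if region.scale is Scale.identity:
        return " U ".join(str(iv) for iv in region.intervals)
    inv = math.exp if region.scale is Scale.log else math.tanh
    parts = []
    for iv in region.intervals:
        lo = inv(iv.lower) if math.isfinite(iv.lower) else (0.0 if region.scale is Scale.log and iv.lower == -math.inf else math.copysign(1.0, iv.lower))
        hi = inv(iv.upper) if math.isfinite(iv.upper) else (math.inf if region.scale is Scale.log else math.copysign(1.0, iv.upper))
        lb = "[" if iv.lower_closed else "("
        rb = "]" if iv.upper_closed else ")"
        parts.append(f"{lb}{lo:.4g}, {hi:.4g}{rb}")
    label = {"log": "ratio", "fisher_z": "correlation"}[region.scale.value]
    return " U ".join(parts) + f" ({label} scale)"


def render_statement(result: "TestResult | CompositeVerdict") -> str:
    """Deterministic one-sentence summary of a result.

    Names the test, the null region on the natural scale, the CI and its
    level, and the verdict — the concise reporting style the framework is
    meant to enable ('significant by MET').
    """
    if isinstance(result, CompositeVerdict):
        return _render_composite(result)
    kind = result.region.geometry
    name = _KIND_NAMES[kind]
    ci = result.ci
    if ci.scale is Scale.identity:
        ci_text = f"{ci.level:.0%} CI [{ci.lower:.4g}, {ci.upper:.4g}]"
    else:
        nat = back_transform(ci)
        ci_text = (
            f"{ci.level:.0%} CI [{nat.lower:.4g}, {nat.upper:.4g}] "
            f"(natural scale; [{ci.lower:.4g}, {ci.upper:.4g}] on the {ci.scale.value} scale)"
        )
    region_text = f"null region {_natural_region_text(result.region)}"
    if result.verdict is Verdict.significant:
        if kind is TestKind.non_inferiority:
            lead = "non-inferior (significant by the non-inferiority test)"
        else:
            lead = f"significant by {name}"
    else:
        qual = {
            Position.inside_region: "CI entirely inside the null region",
            Position.overlaps_region: "CI partially inside the null region",
            Position.outside_all: "",  # unreachable for a non-significant verdict
        }[result.position]
        lead = f"not significant by {name} ({qual})"
    return f"{lead}: {ci_text} vs {region_text}."


def _render_composite(cv: CompositeVerdict) -> str:
    if cv.outcome is CompositeOutcome.inconclusive:
        return (
            "inconclusive: the data do not provide sufficient evidence for either "
            "inference; more, and more precise, data are needed."
        )
    text = {
        CompositeOutcome.meaningful: "the effect is large enough to matter (significant by MET)",
        CompositeOutcome.practically_zero: "the effect is practically zero (significant by EqT)",
        CompositeOutcome.reject_theory: "the data are inconsistent with the predicted value (significant by strong-form Part 1); consider rejecting the theory",
        CompositeOutcome.retain_theory: "the data are consistent with the predicted value (significant by strong-form Part 2); retain the theory",
    }[cv.outcome]
    return text + "."


def _find_component(results: Sequence[TestResult], kinds: set[TestKind]) -> TestResult:
    matches = [r for r in results if r.region.geometry in kinds]
    if len(matches) != 1:
        wanted = "/".join(sorted(k.value for k in kinds))
        raise SpecificationError(
            f"composite verdict needs exactly one {wanted} component, found {len(matches)}"
        )
    return matches[0]


def combined_verdict(results: Sequence[TestResult], kind: str) -> CompositeVerdict:
    """Combine complementary test results into a three-outcome verdict.

    ``kind="met_plus_eqt"`` expects one MET result and one EqT result on the
    same estimate; ``kind="strong_form"`` expects Part 1 and Part 2 results
    with a shared predicted value.  When both components share the same CI
    and complementary regions, geometry forbids both being significant; that
    configuration raises :class:`ConsistencyError`.
    """
    results = tuple(results)
    if kind == "met_plus_eqt":
        met = _find_component(results, {TestKind.met_one_sided, TestKind.met_two_sided})
        eqt = _find_component(results, {TestKind.equivalence})
        if met.verdict is Verdict.significant and eqt.verdict is Verdict.significant:
            raise ConsistencyError(
                "MET and EqT cannot both be significant on the same confidence interval"
            )
        if met.verdict is Verdict.significant:
            outcome = CompositeOutcome.meaningful
        elif eqt.verdict is Verdict.significant:
            outcome = CompositeOutcome.practically_zero
        else:
            outcome = CompositeOutcome.inconclusive
    elif kind == "strong_form":
        p1 = _find_component(results, {TestKind.strong_part1})
        p2 = _find_component(results, {TestKind.strong_part2})
        if p1.region.params.get("theta") != p2.region.params.get("theta"):
            raise SpecificationError(
                "strong-form Parts 1 and 2 must share the predicted value theta"
            )
        if p1.verdict is Verdict.significant and p2.verdict is Verdict.significant:
            raise ConsistencyError(
                "strong-form Parts 1 and 2 cannot both be significant on the same CI"
            )
        if p1.verdict is Verdict.significant:
            outcome = CompositeOutcome.reject_theory
        elif p2.verdict is Verdict.significant:
            outcome = CompositeOutcome.retain_theory
        else:
            outcome = CompositeOutcome.inconclusive
    else:
        raise SpecificationError(
            f"unknown composite kind {kind!r} (use 'met_plus_eqt' or 'strong_form')"
        )
    cv = CompositeVerdict(kind=kind, outcome=outcome, components=results)
    return CompositeVerdict(
        kind=kind, outcome=outcome, components=results, statement=render_statement(cv)
    )


def result_to_json(result: TestResult, **dumps_kw) -> str:
    return json.dumps(result.to_dict(), **dumps_kw)


def result_from_json(text: str) -> TestResult:
    return TestResult.from_dict(json.loads(text))
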