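"""Null regions: the sets of population effect values a test seeks to rule out.

A null region is one or two disjoint intervals of population effect values
constituting the null hypothesis H0 of a test.  Every test in the framework —
one- and two-sided NHST, minimum-effect testing (MET), equivalence testing
(EqT), the two parts of strong-form hypothesis testing, and non-inferiority
testing — is defined entirely by the geometry of its null region; significance
is then a single shared rule (the confidence interval lying entirely outside
the region, see :mod:`nullregions.decision`).

Regions live on an *analysis scale*: ``identity`` for differences,
``log`` for ratio measures (hazard ratios, odds ratios), ``fisher_z`` for
correlations.  Boundary parameters are always supplied on the natural scale
(e.g. a hazard-ratio margin of 1.11) and stored after transformation, so that
the normal-theory confidence intervals of :mod:`nullregions.effects` can be
compared against them directly.

All finite region boundaries are closed: a boundary value belongs to H0, so
significance requires the confidence interval to strictly exclude it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .errors import SpecificationError

__all__ = [
    "Scale",
    "TestKind",
    "Interval",
    "NullRegion",
    "build_null_region",
    "region_contains",
    "region_is_subset",
    "region_to_json",
    "region_from_json",
]

_INF = float("inf")


class Scale(str, Enum):
    """Analysis scale on which effects, intervals and regions are compared."""

    identity = "identity"
    log = "log"
    fisher_z = "fisher_z"


class TestKind(str, Enum):
    """The test geometries of the framework."""

    nhst_two_sided = "nhst_two_sided"
    nhst_one_sided = "nhst_one_sided"
    met_one_sided = "met_one_sided"
    met_two_sided = "met_two_sided"
    equivalence = "equivalence"
    strong_part1 = "strong_part1"
    strong_part2 = "strong_part2"
    non_inferiority = "non_inferiority"


#: Geometries whose null region consists of two disjoint intervals.
TWO_INTERVAL_KINDS = frozenset({TestKind.equivalence, TestKind.strong_part2})

#: Geometries for which a direction flag is meaningful.
ONE_SIDED_KINDS = frozenset(
    {TestKind.nhst_one_sided, TestKind.met_one_sided, TestKind.non_inferiority}
)


@dataclass(frozen=True)
class Interval:
    """A contiguous span of effect values with open/closed endpoints.

    Endpoints may be ``-inf`` / ``+inf`` (always open).  A degenerate interval
    (``lower == upper``) must be closed at both ends — it is the point null of
    two-sided NHST.
    """

    lower: float
    upper: float
    lower_closed: bool = True
    upper_closed: bool = True

    def __post_init__(self) -> None:
        lo, hi = float(self.lower), float(self.upper)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if math.isnan(lo) or math.isnan(hi):
            raise SpecificationError("interval endpoints must not be NaN")
        if lo > hi:
            raise SpecificationError(f"interval lower {lo} exceeds upper {hi}")
        if math.isinf(lo) and self.lower_closed:
            object.__setattr__(self, "lower_closed", False)
        if math.isinf(hi) and self.upper_closed:
            object.__setattr__(self, "upper_closed", False)
        if lo == hi and not (self.lower_closed and self.upper_closed):
            raise SpecificationError(
                "a degenerate (point) interval must be closed at both ends"
            )

    def contains(self, value: float) -> bool:
        """True iff ``value`` lies in the interval, honouring closedness."""
        if value < self.lower or value > self.upper:
            return False
        if value == self.lower and not self.lower_closed:
            return False
        if value == self.upper and not self.upper_closed:
            return False
        return True

    def contains_interval(self, other: "Interval") -> bool:
        """True iff every point of ``other`` lies in this interval."""
        lo_ok = self.lower < other.lower or (
            self.lower == other.lower and (self.lower_closed or not other.lower_closed)
        )
        hi_ok = other.upper < self.upper or (
            self.upper == other.upper and (self.upper_closed or not other.upper_closed)
        )
        return lo_ok and hi_ok

    def to_dict(self) -> dict:
        return {
            "lower": _num_to_json(self.lower),
            "upper": _num_to_json(self.upper),
            "lower_closed": self.lower_closed,
            "upper_closed": self.upper_closed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Interval":
        return cls(
            lower=_num_from_json(d["lower"]),
            upper=_num_from_json(d["upper"]),
            lower_closed=bool(d.get("lower_closed", True)),
            upper_closed=bool(d.get("upper_closed", True)),
        )

    def __str__(self) -> str:
        lb = "[" if self.lower_closed else "("
        rb = "]" if self.upper_closed else ")"
        return f"{lb}{_fmt(self.lower)}, {_fmt(self.upper)}{rb}"


def _fmt(x: float) -> str:
    if x == _INF:
        return "inf"
    if x == -_INF:
        return "-inf"
    return f"{x:g}"


def _num_to_json(x: float):
    if x == _INF:
        return "inf"
    if x == -_INF:
        return "-inf"
    return x


def _num_from_json(v) -> float:
    if isinstance(v, str):
        if v in ("inf", "+inf", "Infinity"):
            return _INF
        if v in ("-inf", "-Infinity"):
            return -_INF
        return float(v)
    return float(v)


@dataclass(frozen=True)
class NullRegion:
    """The set of population values constituting H0 for one test.

    ``intervals`` holds one or two pairwise-disjoint :class:`Interval` objects
    sorted by lower bound; ``geometry`` records the test kind that produced
    the region; ``params`` the boundary parameters used (on the natural
    scale, as supplied); ``scale`` the analysis scale the intervals live on.
    """

    intervals: tuple[Interval, ...]
    geometry: TestKind
    params: Mapping[str, object] = field(default_factory=dict)
    scale: Scale = Scale.identity

    def __post_init__(self) -> None:
        ivs = tuple(self.intervals)
        object.__setattr__(self, "intervals", ivs)
        object.__setattr__(self, "geometry", TestKind(self.geometry))
        object.__setattr__(self, "scale", Scale(self.scale))
        object.__setattr__(self, "params", dict(self.params))
        expected = 2 if TestKind(self.geometry) in TWO_INTERVAL_KINDS else 1
        if len(ivs) != expected:
            raise SpecificationError(
                f"{self.geometry} region requires {expected} interval(s), got {len(ivs)}"
            )
        if len(ivs) == 2:
            a, b = ivs
            if a.lower > b.lower:
                raise SpecificationError("intervals must be sorted by lower bound")
            if not (a.upper < b.lower or (a.upper == b.lower and not (a.upper_closed and b.lower_closed))):
                raise SpecificationError("intervals must be pairwise disjoint")
        # H1 (the complement) must be non-empty.
        if len(ivs) == 1 and ivs[0].lower == -_INF and ivs[0].upper == _INF:
            raise SpecificationError("null region must not cover the whole line")

    def contains(self, value: float) -> bool:
        return any(iv.contains(value) for iv in self.intervals)

    def h1_components(self) -> list[tuple[float, float]]:
        """Open components of the complement of the H0 union, in order.

        Returned as ``(lower, upper)`` pairs; unbounded sides use infinities.
        Used by the power module: a confidence interval lies entirely outside
        the region iff it fits inside one of these gaps.
        """
        gaps: list[tuple[float, float]] = []
        prev = -_INF
        for iv in self.intervals:
            if iv.lower > prev:
                gaps.append((prev, iv.lower))
            prev = iv.upper
        if prev < _INF:
            gaps.append((prev, _INF))
        return gaps

    def finite_boundaries(self) -> list[float]:
        out = []
        for iv in self.intervals:
            for v in (iv.lower, iv.upper):
                if math.isfinite(v):
                    out.append(v)
        return out

    def describe(self) -> str:
        body = " U ".join(str(iv) for iv in self.intervals)
        return f"{body} on {self.scale.value} scale"

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.value,
            "intervals": [iv.to_dict() for iv in self.intervals],
            "scale": self.scale.value,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NullRegion":
        return cls(
            intervals=tuple(Interval.from_dict(x) for x in d["intervals"]),
            geometry=TestKind(d["geometry"]),
            params=d.get("params", {}),
            scale=Scale(d.get("scale", "identity")),
        )


def _require_positive(name: str, value) -> float:
    if value is None:
        raise SpecificationError(f"parameter '{name}' is required for this test kind")
    v = float(value)
    if not (v > 0) or math.isinf(v):
        raise SpecificationError(f"parameter '{name}' must be a finite positive number, got {value}")
    return v


def _half_width(scale: Scale, name: str, value) -> float:
    """Transformed half-width of a symmetric-about-null boundary parameter.

    On the identity scale the parameter is an additive magnitude (> 0); on the
    log scale a fold-change ratio (> 1, giving half-width ``log(value)``); on
    the Fisher-z scale a correlation magnitude in (0, 1), transformed by
    arctanh.
    """
    v = _require_positive(name, value)
    if scale is Scale.identity:
        return v
    if scale is Scale.log:
        if v <= 1:
            raise SpecificationError(
                f"on the log scale '{name}' is a ratio and must exceed 1, got {v}"
            )
        return math.log(v)
    if scale is Scale.fisher_z:
        if v >= 1:
            raise SpecificationError(
                f"on the fisher_z scale '{name}' is a correlation magnitude and must be < 1, got {v}"
            )
        return math.atanh(v)
    raise SpecificationError(f"unknown scale {scale}")


def _transform_point(scale: Scale, name: str, value) -> float:
    """Transform a location parameter (e.g. the theory-predicted value)."""
    if value is None:
        raise SpecificationError(f"parameter '{name}' is required for this test kind")
    v = float(value)
    if scale is Scale.identity:
        return v
    if scale is Scale.log:
        if v <= 0:
            raise SpecificationError(f"on the log scale '{name}' must be positive, got {v}")
        return math.log(v)
    if scale is Scale.fisher_z:
        if abs(v) >= 1:
            raise SpecificationError(
                f"on the fisher_z scale '{name}' is a correlation and must lie in (-1, 1), got {v}"
            )
        return math.atanh(v)
    raise SpecificationError(f"unknown scale {scale}")


def build_null_region(
    kind: TestKind | str,
    params: Mapping[str, object] | None = None,
    direction: str = "greater",
    scale: Scale | str = Scale.identity,
    **kw,
) -> NullRegion:
    """Construct the null region for one of the framework's test geometries.

    Parameters
    ----------
    kind
        Test geometry (a :class:`TestKind` or its string name).
    params
        Boundary parameters on the *natural* scale.  Required keys by kind:

        - ``met_one_sided`` / ``met_two_sided`` / ``equivalence``: ``delta``
          (the largest inconsequential effect magnitude); asymmetric bounds
          may be given as ``delta_lower`` / ``delta_upper`` instead.
        - ``strong_part1`` / ``strong_part2``: ``theta`` (the theoretically
          predicted value) and ``epsilon`` (tolerated deviation from it).
        - ``non_inferiority``: ``ni_margin`` (the boundary of unacceptable
          inferiority, e.g. a hazard-ratio margin).
        - NHST kinds: none.

        Keyword arguments may be used instead of the mapping.
    direction
        ``"greater"`` or ``"less"``, meaningful only for one-sided kinds.
        ``"greater"`` means the alternative of interest lies above the region
        (larger effects are better / the sought signal); ``"less"`` mirrors
        the geometry.  For non-inferiority, ``"greater"`` means higher
        outcome values are better (harm is a low value), ``"less"`` means
        lower values are better (e.g. hazard ratios: harm is a high value).
    scale
        Analysis scale.  On ``log`` and ``fisher_z`` scales the boundary
        parameters are supplied on the natural (ratio / correlation) scale
        and stored after transformation.

    Returns
    -------
    NullRegion
        The H0 set, with closed finite boundaries.
    """
    try:
        kind = TestKind(kind)
    except ValueError:
        raise SpecificationError(f"unknown test kind {kind!r}") from None
    try:
        scale = Scale(scale)
    except ValueError:
        raise SpecificationError(f"unknown scale {scale!r}") from None
    if direction not in ("greater", "less"):
        raise SpecificationError(f"direction must be 'greater' or 'less', got {direction!r}")

    p = dict(params or {})
    p.update(kw)

    # centre of "no effect" on the analysis scale: 0 for identity/fisher_z,
    # log(1) = 0 for ratios — always 0 after transformation.
    if kind is TestKind.nhst_two_sided:
        intervals = (Interval(0.0, 0.0),)
    elif kind is TestKind.nhst_one_sided:
        intervals = (
            (Interval(-_INF, 0.0),) if direction == "greater" else (Interval(0.0, _INF),)
        )
    elif kind is TestKind.met_one_sided:
        d = _half_width(scale, "delta", p.get("delta"))
        intervals = (
            (Interval(-_INF, d),) if direction == "greater" else (Interval(-d, _INF),)
        )
    elif kind in (TestKind.met_two_sided, TestKind.equivalence):
        if "delta_lower" in p or "delta_upper" in p:
            d_lo = _half_width(scale, "delta_lower", p.get("delta_lower"))
            d_hi = _half_width(scale, "delta_upper", p.get("delta_upper"))
        else:
            d_lo = d_hi = _half_width(scale, "delta", p.get("delta"))
        if kind is TestKind.met_two_sided:
            intervals = (Interval(-d_lo, d_hi),)
        else:
            intervals = (Interval(-_INF, -d_lo), Interval(d_hi, _INF))
    elif kind in (TestKind.strong_part1, TestKind.strong_part2):
        eps = p.get("epsilon")
        if scale is Scale.fisher_z:
            # tolerance applies on the correlation scale, then transform ends
            theta_nat = float(p.get("theta")) if p.get("theta") is not None else None
            e = _require_positive("epsilon", eps)
            if theta_nat is None:
                raise SpecificationError("parameter 'theta' is required for this test kind")
            lo = _transform_point(scale, "theta-epsilon", theta_nat - e)
            hi = _transform_point(scale, "theta+epsilon", theta_nat + e)
        else:
            t0 = _transform_point(scale, "theta", p.get("theta"))
            e = _half_width(scale, "epsilon", eps)
            lo, hi = t0 - e, t0 + e
        if kind is TestKind.strong_part1:
            intervals = (Interval(lo, hi),)
        else:
            intervals = (Interval(-_INF, lo), Interval(hi, _INF))
    elif kind is TestKind.non_inferiority:
        m = _require_positive("ni_margin", p.get("ni_margin"))
        if scale is Scale.identity:
            b = m
            intervals = (
                (Interval(-_INF, -b),) if direction == "greater" else (Interval(b, _INF),)
            )
        else:
            b = _transform_point(scale, "ni_margin", m)
            if direction == "greater":
                if b >= 0:
                    raise SpecificationError(
                        "non-inferiority with direction='greater' on a transformed scale "
                        "needs a margin below the null value (e.g. a ratio < 1)"
                    )
                intervals = (Interval(-_INF, b),)
            else:
                if b <= 0:
                    raise SpecificationError(
                        "non-inferiority with direction='less' on a transformed scale "
                        "needs a margin above the null value (e.g. a ratio > 1)"
                    )
                intervals = (Interval(b, _INF),)
    else:  # pragma: no cover - exhaustive above
        raise SpecificationError(f"unknown test kind {kind!r}")

    record = {k: v for k, v in p.items() if v is not None}
    if kind in ONE_SIDED_KINDS:
        record["direction"] = direction
    return NullRegion(intervals=intervals, geometry=kind, params=record, scale=scale)


def region_contains(region: NullRegion, value: float) -> bool:
    """True iff ``value`` (on the region's scale) lies in H0."""
    return region.contains(value)


def region_is_subset(a: NullRegion, b: NullRegion) -> bool:
    """True iff every point of ``a``'s H0 union lies in ``b``'s H0 union.

    Supports the nesting guarantees of the framework, e.g. the NHST point
    null is contained in every MET region.
    """
    if a.scale != b.scale:
        raise SpecificationError(
            f"cannot compare regions on different scales ({a.scale.value} vs {b.scale.value})"
        )
    # with at most 2 disjoint intervals per region, each interval of `a` must
    # fit within a single interval of `b`
    return all(
        any(biv.contains_interval(aiv) for biv in b.intervals) for aiv in a.intervals
    )


def region_to_json(region: NullRegion, **dumps_kw) -> str:
    """Serialize a region to the canonical JSON layout."""
    return json.dumps(region.to_dict(), **dumps_kw)


def region_from_json(text: str) -> NullRegion:
    """Inverse of :func:`region_to_json`."""
    return NullRegion.from_dict(json.loads(text))
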