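"""Operating characteristics of null-region tests under a normal effect model.

The canonical analytic model is the summary-normal model: the observed effect
is drawn from ``Normal(true_effect, se)`` with ``se = sigma / sqrt(n)``, and a
two-sided z interval of half-width ``q * se`` is compared against the region.
Because the CI is an interval, it lies entirely outside the H0 union exactly
when it fits inside one connected component ("gap") of the complement, which
gives closed-form rejection probabilities from normal tail areas for every
geometry — one-sided regions, the bounded MET/strong-Part-1 box, and the
central-gap equivalence/strong-Part-2 shapes alike.

These analytics make the framework's headline operating characteristics
checkable: the type-I error is capped at the implied one-sided alpha (attained
exactly at a region boundary), power for a true effect inside the region never
rises toward 1 no matter how large n grows, and the probability of an
inconclusive outcome vanishes with n for effects off the boundary.

Raw-data models (two-group normal and binomial) route through
:mod:`nullregions.effects` and are evaluated by Monte Carlo only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decision import TestSpec
from .effects import EffectEstimate
from .errors import SpecificationError, UnreachablePowerError
from .regions import NullRegion, Scale, TestKind

__all__ = [
    "OperatingCharacteristics",
    "analytic_power",
    "simulate_oc",
    "required_n",
    "N_SEARCH_CAP",
]

#: Sample-size search cap for :func:`required_n`.
N_SEARCH_CAP = 10_000_000


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Rejection / inconclusive / inside probabilities over a grid.

    ``table`` has one row per (true_effect, n) cell with columns
    ``true_effect, n, se, p_significant, p_inconclusive, p_inside``.
    """

    table: pd.DataFrame
    method: str  # "analytic" or "monte_carlo"
    spec: TestSpec
    reps: int | None = None
    seed: int | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _normal_cdf(x: float) -> float:
    return float(stats.norm.cdf(x))


def analytic_power(
    region: NullRegion, true_effect: float, se: float, level: float = 0.95
) -> dict[str, float]:
    """Exact outcome probabilities under the summary-normal model with z CIs.

    The estimate X ~ Normal(true_effect, se); the CI is X ± q·se with q the
    normal quantile at (1+level)/2.

    Significance requires the CI to fit inside one gap (g_lo, g_hi) of the
    complement of H0, i.e. X in (g_lo + q·se, g_hi − q·se); summing the
    normal probability of these (disjoint) X-intervals over gaps gives
    ``p_significant``.  For a single upper-bounded region (−inf, b] this
    reduces to Phi((true_effect − b)/se − q); for a lower-bounded region
    [b, inf) to Phi((b − true_effect)/se − q); for a central gap (a, b) to
    max(0, Phi((b − true_effect)/se − q) − Phi((a − true_effect)/se + q));
    a bounded region contributes the sum of its two one-sided exclusions.

    ``p_inside`` is the probability that the CI lies wholly within the H0
    union (within one H0 interval), and ``p_inconclusive`` the remainder.
    """
    if not (se > 0) or not math.isfinite(se):
        raise SpecificationError(f"standard error must be finite and > 0, got {se}")
    if not (0 < level < 1):
        raise SpecificationError(f"confidence level must be in (0, 1), got {level}")
    q = float(stats.norm.ppf(0.5 * (1 + level)))
    mu = float(true_effect)

    p_sig = 0.0
    for g_lo, g_hi in region.h1_components():
        lo = (g_lo + q * se - mu) / se if math.isfinite(g_lo) else -math.inf
        hi = (g_hi - q * se - mu) / se if math.isfinite(g_hi) else math.inf
        if hi > lo:
            p_sig += _normal_cdf(hi) - _normal_cdf(lo)

    p_in = 0.0
    for iv in region.intervals:
        lo = (iv.lower + q * se - mu) / se if math.isfinite(iv.lower) else -math.inf
        hi = (iv.upper - q * se - mu) / se if math.isfinite(iv.upper) else math.inf
        if hi > lo:
            p_in += _normal_cdf(hi) - _normal_cdf(lo)

    p_sig = min(max(p_sig, 0.0), 1.0)
    p_in = min(max(p_in, 0.0), 1.0 - p_sig)
    return {
        "p_significant": p_sig,
        "p_inconclusive": 1.0 - p_sig - p_in,
        "p_inside": p_in,
    }


def _classify_batch(
    lo: np.ndarray, up: np.ndarray, region: NullRegion
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized CI-vs-region classification for arrays of CI bounds.

    Returns boolean arrays (significant, inside).  Region boundaries built by
    this package are closed, so touching a boundary counts as overlap.
    """
    disjoint_all = np.ones_like(lo, dtype=bool)
    inside_any = np.zeros_like(lo, dtype=bool)
    for iv in region.intervals:
        if iv.lower_closed or not math.isfinite(iv.lower):
            below = up < iv.lower
        else:
            below = up <= iv.lower
        if iv.upper_closed or not math.isfinite(iv.upper):
            above = lo > iv.upper
        else:
            above = lo >= iv.upper
        disjoint_all &= below | above
        lo_ok = lo > iv.lower if not iv.lower_closed else lo >= iv.lower
        hi_ok = up < iv.upper if not iv.upper_closed else up <= iv.upper
        inside_any |= lo_ok & hi_ok
    return disjoint_all, inside_any


def _simulate_cell(
    spec: TestSpec,
    region: NullRegion,
    true_effect: float,
    n: int,
    data_model: str,
    reps: int,
    rng: np.random.Generator,
    sigma: float,
    model_params: Mapping[str, float],
) -> tuple[float, float, float, float]:
    """One Monte-Carlo grid cell; returns (se_used, p_sig, p_inconclusive, p_inside)."""
    if data_model == "summary_normal":
        se = sigma / math.sqrt(n)
        est = true_effect + se * rng.standard_normal(reps)
        q = float(stats.norm.ppf(0.5 * (1 + spec.level)))
        half = np.full(reps, q * se)
    elif data_model == "two_group_normal":
        sd = float(model_params.get("sd", sigma))
        y1 = true_effect + sd * rng.standard_normal((reps, n))
        y2 = sd * rng.standard_normal((reps, n))
        est = y1.mean(axis=1) - y2.mean(axis=1)
        v1 = y1.var(axis=1, ddof=1)
        v2 = y2.var(axis=1, ddof=1)
        q1, q2 = v1 / n, v2 / n
        se_arr = np.sqrt(q1 + q2)
        df = (q1 + q2) ** 2 / (q1**2 / (n - 1) + q2**2 / (n - 1))
        method = spec.ci_method or "t"
        if method == "t":
            qv = stats.t.ppf(0.5 * (1 + spec.level), df=df)
        else:
            qv = float(stats.norm.ppf(0.5 * (1 + spec.level)))
        half = qv * se_arr
        se = float(np.mean(se_arr))
    elif data_model == "two_group_binomial":
        p2 = float(model_params.get("baseline_rate", 0.5))
        p1 = p2 + true_effect
        if not (0 < p1 < 1 and 0 < p2 < 1):
            raise SpecificationError(
                f"binomial rates must lie in (0, 1); got {p1} and {p2}"
            )
        x1 = rng.binomial(n, p1, size=reps)
        x2 = rng.binomial(n, p2, size=reps)
        ph1, ph2 = x1 / n, x2 / n
        est = ph1 - ph2
        se_arr = np.sqrt(ph1 * (1 - ph1) / n + ph2 * (1 - ph2) / n)
        q = float(stats.norm.ppf(0.5 * (1 + spec.level)))
        half = q * se_arr
        se = float(np.mean(se_arr))
    else:
        raise SpecificationError(
            f"unknown data model {data_model!r} (use 'summary_normal', "
            "'two_group_normal' or 'two_group_binomial')"
        )
    sig, inside = _classify_batch(est - half, est + half, region)
    p_sig = sig.mean()
    p_in = (inside & ~sig).mean()
    return se, float(p_sig), float(1.0 - p_sig - p_in), float(p_in)


def simulate_oc(
    spec: TestSpec,
    true_effects: float | Sequence[float],
    n_grid: Sequence[int],
    data_model: str = "summary_normal",
    reps: int = 10_000,
    seed: int = 0,
    sigma: float = 1.0,
    model_params: Mapping[str, float] | None = None,
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics over a (true effect × n) grid.

    ``summary_normal`` shrinks the standard error as ``sigma / sqrt(n)``; the
    two-group models simulate raw data of ``n`` per group and estimate the
    effect exactly as :mod:`nullregions.effects` would.  Each grid cell draws
    from an independent child stream of one root ``SeedSequence``, so the
    table is reproducible regardless of evaluation order.
    """
    if reps < 1:
        raise SpecificationError(f"reps must be >= 1, got {reps}")
    if np.isscalar(true_effects):
        true_effects = [float(true_effects)]  # type: ignore[list-item]
    effects = [float(t) for t in true_effects]
    ns = [int(n) for n in n_grid]
    if any(n < 1 for n in ns):
        raise SpecificationError("all n values must be >= 1")
    region = spec.build_region()
    model_params = dict(model_params or {})

    root = np.random.SeedSequence(seed)
    children = root.spawn(len(effects) * len(ns))
    rows = []
    idx = 0
    for mu in effects:
        for n in ns:
            rng = np.random.default_rng(children[idx])
            idx += 1
            se, p_sig, p_inc, p_in = _simulate_cell(
                spec, region, mu, n, data_model, reps, rng, sigma, model_params
            )
            rows.append(
                {
                    "true_effect": mu,
                    "n": n,
                    "se": se,
                    "p_significant": p_sig,
                    "p_inconclusive": p_inc,
                    "p_inside": p_in,
                }
            )
    return OperatingCharacteristics(
        table=pd.DataFrame(rows), method="monte_carlo", spec=spec, reps=reps, seed=seed
    )


def analytic_oc(
    spec: TestSpec,
    true_effects: float | Sequence[float],
    n_grid: Sequence[int],
    sigma: float = 1.0,
) -> OperatingCharacteristics:
    """Analytic counterpart of :func:`simulate_oc` for the summary-normal model."""
    if np.isscalar(true_effects):
        true_effects = [float(true_effects)]  # type: ignore[list-item]
    region = spec.build_region()
    rows = []
    for mu in [float(t) for t in true_effects]:
        for n in (int(n) for n in n_grid):
            se = sigma / math.sqrt(n)
            probs = analytic_power(region, mu, se, spec.level)
            rows.append({"true_effect": mu, "n": n, "se": se, **probs})
    return OperatingCharacteristics(
        table=pd.DataFrame(rows), method="analytic", spec=spec
    )


def required_n(
    spec: TestSpec,
    true_effect: float,
    sigma: float,
    target_power: float,
    n_cap: int = N_SEARCH_CAP,
) -> int:
    """Smallest n with analytic power >= target under the summary-normal model.

    Searches by doubling followed by bisection.  The true effect must lie in
    H1 (power at an H0 point can never exceed the implied alpha).  If even
    ``n_cap`` observations cannot reach the target — possible when a central
    H1 gap is narrow relative to the effect's position, or simply when the
    target is extreme — an :class:`UnreachablePowerError` is raised carrying
    the power attained at the cap.
    """
    if not (0 < target_power < 1):
        raise SpecificationError(f"target power must be in (0, 1), got {target_power}")
    if not sigma > 0:
        raise SpecificationError(f"sigma must be positive, got {sigma}")
    region = spec.build_region()
    if region.contains(true_effect):
        raise SpecificationError(
            "power cannot reach target; effect inside null region"
        )

    def power_at(n: int) -> float:
        return analytic_power(region, true_effect, sigma / math.sqrt(n), spec.level)[
            "p_significant"
        ]

    n = 1
    while power_at(n) < target_power:
        if n >= n_cap:
            raise UnreachablePowerError(
                f"target power {target_power} unreachable: power at n={n_cap} is "
                f"{power_at(n_cap):.6f}"
            )
        n = min(2 * n, n_cap)
    # smallest n in (n//2, n] meeting the target
    lo, hi = max(1, n // 2), n
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return hi
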