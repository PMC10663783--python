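"""Effect estimates and confidence intervals on the analysis scale.

The decision rule of the framework compares a confidence interval against a
null region, so everything upstream reduces to producing an
:class:`EffectEstimate` — a point estimate with a standard error on the scale
the region lives on — and a symmetric two-sided :class:`ConfidenceInterval`
around it.  Estimates can be supplied directly as summary statistics (the
usual route for hazard ratios from published trials) or computed from raw
two-group or bivariate data.

Scales follow :mod:`nullregions.regions`: differences on the identity scale,
ratio measures on the log scale, correlations on the Fisher-z (arctanh)
scale with the standard large-sample error ``1/sqrt(n - 3)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, SpecificationError
from .regions import Scale

__all__ = [
    "EffectEstimate",
    "ConfidenceInterval",
    "compute_ci",
    "effect_from_two_groups",
    "effect_from_correlation",
    "back_transform",
    "read_two_group_csv",
    "read_bivariate_csv",
]


@dataclass(frozen=True)
class EffectEstimate:
    """An observed effect with its standard error on an analysis scale.

    ``df`` (degrees of freedom) is optional; when present, t-based confidence
    intervals become available and are the default.  ``n_info`` optionally
    records per-group sample sizes for reporting.
    """

    estimate: float
    se: float
    scale: Scale = Scale.identity
    df: float | None = None
    n_info: Mapping[str, int] | None = None
    measure: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "scale", Scale(self.scale))
        if not math.isfinite(self.estimate):
            raise DataError(f"effect estimate must be finite, got {self.estimate}")
        if not (self.se >= 0) or not math.isfinite(self.se):
            raise DataError(f"standard error must be finite and >= 0, got {self.se}")
        if self.df is not None and not self.df > 0:
            raise DataError(f"degrees of freedom must be > 0, got {self.df}")
        if self.measure == "correlation":
            if self.scale is not Scale.fisher_z:
                raise SpecificationError("correlation estimates live on the fisher_z scale")
            if abs(math.tanh(self.estimate)) >= 1:  # pragma: no cover - atanh is finite
                raise DataError("correlation magnitude must be < 1")


@dataclass(frozen=True)
class ConfidenceInterval:
    """A two-sided confidence interval on an analysis scale."""

    lower: float
    upper: float
    level: float
    scale: Scale = Scale.identity
    method: str = "z"

    def __post_init__(self) -> None:
        object.__setattr__(self, "scale", Scale(self.scale))
        if not (0 < self.level < 1):
            raise SpecificationError(f"confidence level must be in (0, 1), got {self.level}")
        if self.lower > self.upper:
            raise SpecificationError(
                f"CI lower bound {self.lower} exceeds upper bound {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "scale": self.scale.value,
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConfidenceInterval":
        return cls(
            lower=float(d["lower"]),
            upper=float(d["upper"]),
            level=float(d["level"]),
            scale=Scale(d.get("scale", "identity")),
            method=str(d.get("method", "z")),
        )

    def __str__(self) -> str:
        return f"[{self.lower:.4g}, {self.upper:.4g}] ({self.level:.0%} {self.method})"


def compute_ci(
    est: EffectEstimate, level: float = 0.95, method: str | None = None
) -> ConfidenceInterval:
    """Symmetric two-sided confidence interval ``estimate ± q * se``.

    ``q`` is the standard-normal (``method="z"``) or Student-t
    (``method="t"``, requires ``df``) quantile at ``(1 + level) / 2``.  The
    default method is ``"t"`` when degrees of freedom are known and ``"z"``
    otherwise.  The interval is computed on the analysis scale; use
    :func:`back_transform` for natural-scale presentation.
    """
    if not (0 < level < 1):
        raise SpecificationError(f"confidence level must be in (0, 1), got {level}")
    if method is None:
        method = "t" if est.df is not None else "z"
    if method == "z":
        q = stats.norm.ppf(0.5 * (1 + level))
    elif method == "t":
        if est.df is None:
            raise SpecificationError("t-method confidence interval requires degrees of freedom")
        q = stats.t.ppf(0.5 * (1 + level), df=est.df)
    else:
        raise SpecificationError(f"unknown CI method {method!r} (use 'z' or 't')")
    half = q * est.se
    return ConfidenceInterval(
        lower=est.estimate - half,
        upper=est.estimate + half,
        level=level,
        scale=est.scale,
        method=method,
    )


def _as_1d(y, name: str) -> np.ndarray:
    arr = np.asarray(y, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


def effect_from_two_groups(
    y1: Sequence[float],
    y2: Sequence[float],
    measure: str = "mean_difference",
    pooled: bool = False,
) -> EffectEstimate:
    """Effect of group 1 relative to group 2 from raw outcomes.

    ``mean_difference`` returns ``mean(y1) - mean(y2)`` with the Welch
    (unequal-variance) standard error and Welch–Satterthwaite degrees of
    freedom by default; ``pooled=True`` switches to the pooled-variance
    two-sample formulas.  ``proportion_difference`` requires binary-coded
    outcomes and returns ``p1 - p2`` with the Wald standard error (normal
    approximation, no df).
    """
    a, b = _as_1d(y1, "y1"), _as_1d(y2, "y2")
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise DataError(f"each group needs at least 2 observations (got {n1} and {n2})")
    n_info = {"n1": int(n1), "n2": int(n2)}

    if measure == "mean_difference":
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        est = a.mean() - b.mean()
        if pooled:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = float(n1 + n2 - 2)
        else:
            q1, q2 = v1 / n1, v2 / n2
            se = math.sqrt(q1 + q2)
            if se == 0:
                df = float(n1 + n2 - 2)  # degenerate: all values identical
            else:
                df = (q1 + q2) ** 2 / (q1**2 / (n1 - 1) + q2**2 / (n2 - 1))
        return EffectEstimate(
            estimate=float(est), se=float(se), df=df, n_info=n_info,
            measure="mean_difference",
        )

    if measure == "proportion_difference":
        for arr, name in ((a, "y1"), (b, "y2")):
            if not np.isin(arr, (0.0, 1.0)).all():
                raise DataError(
                    f"proportion_difference requires binary (0/1) outcomes in {name}"
                )
        p1, p2 = a.mean(), b.mean()
        se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        return EffectEstimate(
            estimate=float(p1 - p2), se=float(se), df=None, n_info=n_info,
            measure="proportion_difference",
        )

    raise SpecificationError(
        f"unknown measure {measure!r} (use 'mean_difference' or 'proportion_difference')"
    )


def effect_from_correlation(x: Sequence[float], y: Sequence[float]) -> EffectEstimate:
    """Pearson correlation as a Fisher-z effect with SE ``1/sqrt(n - 3)``."""
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise DataError(f"x and y must be paired (got lengths {xa.size} and {ya.size})")
    n = xa.size
    if n < 4:
        raise DataError(f"correlation requires n >= 4 pairs, got {n}")
    if xa.std(ddof=1) == 0 or ya.std(ddof=1) == 0:
        raise DataError("correlation requires both variables to have nonzero variance")
    r = float(stats.pearsonr(xa, ya).statistic)
    # exactly collinear data give r == +/-1 up to rounding; the Fisher z
    # transform diverges there, so treat anything within 1e-12 of unity as
    # degenerate rather than reporting an astronomical z
    if abs(r) >= 1.0 - 1e-12:
        raise DataError("correlation is +/-1 (collinear data); the Fisher z transform diverges")
    return EffectEstimate(
        estimate=float(np.arctanh(r)),
        se=1.0 / math.sqrt(n - 3),
        scale=Scale.fisher_z,
        df=None,
        n_info={"n": int(n)},
        measure="correlation",
    )


def back_transform(ci: ConfidenceInterval) -> ConfidenceInterval:
    """Endpoint-wise inverse transform to the natural scale.

    ``log`` intervals are exponentiated (giving a ratio interval), ``fisher_z``
    intervals are mapped through tanh (giving a correlation interval).  Both
    transforms are strictly increasing, so level and ordering are preserved.
    Identity-scale input is returned unchanged with a warning.
    """
    if ci.scale is Scale.identity:
        warnings.warn("back_transform on an identity-scale interval is a no-op", stacklevel=2)
        return ci
    f = math.exp if ci.scale is Scale.log else math.tanh
    return ConfidenceInterval(
        lower=f(ci.lower), upper=f(ci.upper), level=ci.level,
        scale=Scale.identity, method=ci.method,
    )


def read_two_group_csv(
    path, outcome_col: str = "outcome", group_col: str = "group"
) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    """Read long-format two-group data: one outcome column, one group column.

    Returns the two outcome vectors plus the (sorted) group labels; the first
    vector corresponds to the first label.
    """
    df = pd.read_csv(path)
    for col in (outcome_col, group_col):
        if col not in df.columns:
            raise DataError(f"column {col!r} not found in {path} (has {list(df.columns)})")
    labels = sorted(df[group_col].astype(str).unique())
    if len(labels) != 2:
        raise DataError(f"expected exactly 2 groups in {group_col!r}, found {labels}")
    g = df[group_col].astype(str)
    y1 = df.loc[g == labels[0], outcome_col].to_numpy(dtype=float)
    y2 = df.loc[g == labels[1], outcome_col].to_numpy(dtype=float)
    return y1, y2, (labels[0], labels[1])


def read_bivariate_csv(
    path, x_col: str | None = None, y_col: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Read wide-format paired numeric data for correlation analyses.

    By default the first two columns are used.
    """
    df = pd.read_csv(path)
    if x_col is None or y_col is None:
        if df.shape[1] < 2:
            raise DataError(f"{path} needs at least two numeric columns")
        x_col, y_col = df.columns[0], df.columns[1]
    for col in (x_col, y_col):
        if col not in df.columns:
            raise DataError(f"column {col!r} not found in {path} (has {list(df.columns)})")
    return df[x_col].to_numpy(dtype=float), df[y_col].to_numpy(dtype=float)
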