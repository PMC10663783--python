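"""Seeded synthetic-data scenarios for two-group and bivariate designs.

Every generator is deterministic given its seed (one `numpy` Generator per
call, no global state), so tests and worked examples are reproducible without
any external dataset.  Three data models cover the designs the rest of the
package analyses:

- ``two_group_normal``: Gaussian outcomes whose group means differ by the
  true effect;
- ``two_group_binomial``: binary outcomes at two success rates (e.g. the
  75% vs 60% treatment-superiority scenario used in the worked examples);
- ``bivariate_normal``: paired draws with a requested correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import SpecificationError

__all__ = ["ScenarioSpec", "generate", "scenario_from_file"]

_MODELS = ("two_group_normal", "two_group_binomial", "bivariate_normal")


@dataclass(frozen=True)
class ScenarioSpec:
    """A reproducible synthetic-data scenario.

    ``params`` by model:

    - ``two_group_normal``: ``effect`` (difference in means), ``sd``
      (common within-group standard deviation, default 1), ``mean_control``
      (default 0).
    - ``two_group_binomial``: ``rate1`` and ``rate2`` (success probabilities
      of the two groups, each in (0, 1)).
    - ``bivariate_normal``: ``correlation`` (|rho| < 1), unit marginals.

    ``n`` is the per-group (or per-pair) sample size.
    """

    model: str
    params: Mapping[str, float] = field(default_factory=dict)
    n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise SpecificationError(f"unknown model {self.model!r} (use one of {_MODELS})")
        if self.n < 2:
            raise SpecificationError(f"n must be >= 2, got {self.n}")
        p = dict(self.params)
        object.__setattr__(self, "params", p)
        if self.model == "two_group_normal":
            sd = float(p.get("sd", 1.0))
            if not sd > 0:
                raise SpecificationError(f"sd must be positive, got {sd}")
        elif self.model == "two_group_binomial":
            for key in ("rate1", "rate2"):
                if key not in p:
                    raise SpecificationError(f"two_group_binomial requires '{key}'")
                r = float(p[key])
                if not (0 < r < 1):
                    raise SpecificationError(f"{key} must lie in (0, 1), got {r}")
        elif self.model == "bivariate_normal":
            rho = float(p.get("correlation", 0.0))
            if not abs(rho) < 1:
                raise SpecificationError(f"|correlation| must be < 1, got {rho}")

    def to_dict(self) -> dict:
        return {"model": self.model, "params": dict(self.params), "n": self.n, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioSpec":
        return cls(
            model=str(d["model"]),
            params=dict(d.get("params", {})),
            n=int(d.get("n", 100)),
            seed=int(d.get("seed", 0)),
        )


def generate(spec: ScenarioSpec) -> pd.DataFrame:
    """Generate one dataset for a scenario; byte-identical for equal specs.

    Two-group models return a long-format frame with columns
    ``(outcome, group)`` and group labels ``"treatment"`` / ``"control"``
    (the treatment group carries the effect); the bivariate model returns
    columns ``(x, y)``.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    n = spec.n
    if spec.model == "two_group_normal":
        mu0 = float(p.get("mean_control", 0.0))
        effect = float(p.get("effect", 0.0))
        sd = float(p.get("sd", 1.0))
        y1 = rng.normal(mu0 + effect, sd, size=n)
        y2 = rng.normal(mu0, sd, size=n)
    elif spec.model == "two_group_binomial":
        y1 = rng.binomial(1, float(p["rate1"]), size=n).astype(float)
        y2 = rng.binomial(1, float(p["rate2"]), size=n).astype(float)
    else:  # bivariate_normal
        rho = float(p.get("correlation", 0.0))
        cov = np.array([[1.0, rho], [rho, 1.0]])
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})
    return pd.DataFrame(
        {
            "outcome": np.concatenate([y1, y2]),
            "group": ["treatment"] * n + ["control"] * n,
        }
    )


def scenario_from_file(path) -> ScenarioSpec:
    """Load a :class:`ScenarioSpec` from a YAML or JSON file."""
    text = open(path, "r", encoding="utf-8").read()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise SpecificationError(f"scenario file {path} must contain a mapping")
    return ScenarioSpec.from_dict(data)
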