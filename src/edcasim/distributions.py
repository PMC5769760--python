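"""Service-time distribution specifications.

Durations in the simulator (admission, triage, section treatment,
diagnostics, fast-track consultations) are described by small declarative
specs — ``{"family": "lognormal", "mean": 120, "sd": 60}`` — so that a
configuration file can state them directly and a policy transform can
rescale them without knowing the family.

Lognormal specs are parameterised by their natural-scale mean and standard
deviation (minutes), the quantities a practitioner reads off an ED
information system, and converted internally to the underlying normal
(mu, sigma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["DistSpec", "ConfigError"]


class ConfigError(ValueError):
    """A configuration value violates the schema; message names the field path."""


_FAMILIES = ("lognormal", "exponential", "uniform", "fixed")


@dataclass(frozen=True)
class DistSpec:
    """A positive duration distribution (minutes).

    family:
        ``lognormal`` (params: mean, sd on the natural scale),
        ``exponential`` (params: mean),
        ``uniform`` (params: low, high),
        ``fixed`` (params: value).
    """

    family: str
    params: Mapping[str, float]

    def validate(self, path: str = "dist") -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(f"{path}.family: unknown family {self.family!r}; "
                              f"expected one of {_FAMILIES}")
        p = dict(self.params)
        required = {
            "lognormal": ("mean", "sd"),
            "exponential": ("mean",),
            "uniform": ("low", "high"),
            "fixed": ("value",),
        }[self.family]
        for key in required:
            if key not in p:
                raise ConfigError(f"{path}.params: missing {key!r} for family "
                                  f"{self.family!r}")
            if not np.isfinite(p[key]):
                raise ConfigError(f"{path}.params.{key}: must be finite")
        extra = set(p) - set(required)
        if extra:
            raise ConfigError(f"{path}.params: unexpected keys {sorted(extra)}")
        if self.family == "lognormal" and (p["mean"] <= 0 or p["sd"] < 0):
            raise ConfigError(f"{path}.params: lognormal needs mean>0, sd>=0")
        if self.family == "exponential" and p["mean"] <= 0:
            raise ConfigError(f"{path}.params: exponential needs mean>0")
        if self.family == "uniform" and not (0 <= p["low"] <= p["high"]):
            raise ConfigError(f"{path}.params: uniform needs 0<=low<=high")
        if self.family == "fixed" and p["value"] < 0:
            raise ConfigError(f"{path}.params: fixed needs value>=0")

    @property
    def mean(self) -> float:
        p = self.params
        if self.family in ("lognormal", "exponential"):
            return float(p["mean"])
        if self.family == "uniform":
            return (p["low"] + p["high"]) / 2.0
        return float(p["value"])

    def sample(self, rng: np.random.Generator, scale: float = 1.0) -> float:
        """Draw one duration, multiplied by ``scale`` (e.g. a policy speed-up)."""
        p = self.params
        if self.family == "lognormal":
            mean, sd = p["mean"], p["sd"]
            if sd == 0:
                x = mean
            else:
                sigma2 = math.log(1.0 + (sd / mean) ** 2)
                mu = math.log(mean) - sigma2 / 2.0
                x = rng.lognormal(mu, math.sqrt(sigma2))
        elif self.family == "exponential":
            x = rng.exponential(p["mean"])
        elif self.family == "uniform":
            x = rng.uniform(p["low"], p["high"])
        else:
            x = p["value"]
        return float(x) * scale

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @staticmethod
    def from_dict(d: Mapping, path: str = "dist") -> "DistSpec":
        if not isinstance(d, Mapping) or "family" not in d:
            raise ConfigError(f"{path}: expected a mapping with 'family' and 'params'")
        spec = DistSpec(family=d["family"], params=dict(d.get("params", {})))
        spec.validate(path)
        return spec
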