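"""Simulation configuration: schema, validation, and (de)serialisation.

A :class:`SimConfig` fully parameterises one emergency-department scenario:
the non-homogeneous arrival profile, triage and admission staffing, the six
treatment sections with their service-time distributions, the
cellular-automaton abandonment parameters, the crowding-index coefficients,
and the run protocol (run length, warm-up, replications).

Configs are plain frozen dataclasses; YAML and JSON files mirror them
field-for-field.  All times are minutes, all rates patients/hour.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .distributions import ConfigError, DistSpec

__all__ = [
    "CAParams", "NedocsCoeffs", "Section", "SimConfig",
    "load_config", "save_config", "ConfigError",
]

SECTION_NAMES = (
    "suturing", "orthopedics", "pediatrics",
    "clinical_emergency", "surgical_emergency", "yellow_zone",
)

MODES = ("self", "ambulance", "police")


@dataclass(frozen=True)
class CAParams:
    """Cellular-automaton abandonment parameters.

    Tolerance times follow a three-bin mixture: with probability
    ``tol_probs[0]`` uniform on ``tol_short_range``, with ``tol_probs[1]``
    uniform on ``tol_mid_range``, and with ``tol_probs[2]`` infinite (the
    patient waits indefinitely).  ``extension_factor`` is the fraction of the
    tolerance time granted as extra waiting when a patient's memorised
    neighbours are mostly "normal".  ``crowding_boost``/``crowding_floor``
    are the relative tolerance adjustments at crowding index 0 and 200.
    """

    scheme: str = "neumann"              # or "moore"
    r: int = 1                           # neighborhood range
    tol_probs: tuple[float, float, float] = (0.51, 0.17, 0.32)
    tol_short_range: tuple[float, float] = (0.0, 120.0)
    tol_mid_range: tuple[float, float] = (120.0, 480.0)
    extension_factor: float = 0.1
    crowding_boost: float = 0.30
    crowding_floor: float = -0.30
    modulation: str = "continuous"       # or "at_seating"

    def validate(self, path: str = "ca_params") -> None:
        if self.scheme not in ("moore", "neumann"):
            raise ConfigError(f"{path}.scheme: expected 'moore' or 'neumann'")
        if self.modulation not in ("continuous", "at_seating"):
            raise ConfigError(f"{path}.modulation: expected 'continuous' or "
                              f"'at_seating'")
        if self.r < 0 or int(self.r) != self.r:
            raise ConfigError(f"{path}.r: must be a nonnegative integer")
        if len(self.tol_probs) != 3 or any(p < 0 for p in self.tol_probs):
            raise ConfigError(f"{path}.tol_probs: three nonnegative entries required")
        if abs(sum(self.tol_probs) - 1.0) > 1e-9:
            raise ConfigError(f"{path}.tol_probs: must sum to 1 "
                              f"(got {sum(self.tol_probs)})")
        for name in ("tol_short_range", "tol_mid_range"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi:
                raise ConfigError(f"{path}.{name}: need 0 <= low < high")
        if self.extension_factor < 0:
            raise ConfigError(f"{path}.extension_factor: must be >= 0")
        if self.crowding_boost < self.crowding_floor:
            raise ConfigError(f"{path}: crowding_boost must be >= crowding_floor")


#: Verbal crowding categories, least to most crowded.
NEDOCS_CATEGORIES = (
    "not busy",
    "busy",
    "extremely busy but not overcrowded",
    "overcrowded",
    "severely overcrowded",
    "dangerously overcrowded",
)


@dataclass(frozen=True)
class NedocsCoeffs:
    """Linear crowding-index coefficients, clamped to [0, 200].

    Predictors, in order: ED census / ED beds; admitted patients boarding /
    hospital beds; waiting-room occupancy ratio (count / waiting capacity);
    longest boarding wait in hours; time the most recent patient waited for
    a bed, in minutes.  Defaults follow the published linear overcrowding
    score, with the waiting-room ratio standing in for the ventilator term
    (see docs/methods.md).
    """

    intercept: float = -20.0
    occupancy: float = 85.8          # per unit of census/beds
    boarding: float = 600.0          # per unit of boarders/hospital beds
    waiting_ratio: float = 200.0     # per unit of waiting count/capacity (a half-full room reads +100)
    longest_admit_h: float = 0.93    # per hour
    last_bed_min: float = 0.094      # per minute (5.64/h)
    hospital_beds: int = 380
    clamp: tuple[float, float] = (0.0, 200.0)
    cutpoints: tuple[float, float, float, float, float] = (20.0, 60.0, 100.0, 140.0, 180.0)

    def validate(self, path: str = "nedocs_coeffs") -> None:
        lo, hi = self.clamp
        if not lo < hi:
            raise ConfigError(f"{path}.clamp: need lo < hi")
        if self.hospital_beds <= 0:
            raise ConfigError(f"{path}.hospital_beds: must be > 0")
        cps = self.cutpoints
        if len(cps) != 5 or any(b <= a for a, b in zip(cps, cps[1:])):
            raise ConfigError(f"{path}.cutpoints: five strictly increasing values")
        if not (lo < cps[0] and cps[-1] < hi):
            raise ConfigError(f"{path}.cutpoints: must lie strictly inside clamp range")


@dataclass(frozen=True)
class Section:
    """One treatment section of the ED."""

    name: str
    beds: int
    doctors: int
    nurse_technicians: int
    service_time: DistSpec
    mts_routing_weight: tuple[float, float, float, float, float]
    p_hospitalization: float = 0.1

    def validate(self, path: str) -> None:
        if self.name not in SECTION_NAMES:
            raise ConfigError(f"{path}.name: {self.name!r} not one of {SECTION_NAMES}")
        if self.beds < 1:
            raise ConfigError(f"{path}.beds: must be >= 1")
        if self.doctors < 1:
            raise ConfigError(f"{path}.doctors: must be >= 1")
        if self.nurse_technicians < 0:
            raise ConfigError(f"{path}.nurse_technicians: must be >= 0")
        self.service_time.validate(f"{path}.service_time")
        if len(self.mts_routing_weight) != 5:
            raise ConfigError(f"{path}.mts_routing_weight: five weights required")
        if any(w < 0 for w in self.mts_routing_weight):
            raise ConfigError(f"{path}.mts_routing_weight: weights must be >= 0")
        if not 0 <= self.p_hospitalization <= 1:
            raise ConfigError(f"{path}.p_hospitalization: must be in [0,1]")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of an ED scenario (times in minutes, rates per hour)."""

    hourly_rates: tuple[float, ...]                    # lambda(t), 24 entries
    mode_probs: tuple[float, float, float]             # self, ambulance, police
    mts_probs: tuple[float, float, float, float, float]
    sections: tuple[Section, ...]
    triage_nurses: int = 1
    receptionists: int = 2
    triage_time: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"mean": 7.0, "sd": 3.0}))
    admission_time: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"mean": 4.0, "sd": 2.0}))
    waiting_capacity: int = 30
    diagnostics_prob: float = 0.3
    diagnostics_time: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"mean": 45.0, "sd": 20.0}))
    doctor_time_fraction: float = 0.25
    service_scale: float = 1.0
    fast_track: bool = False
    fast_track_doctors: int = 1
    fast_track_time: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"mean": 12.0, "sd": 6.0}))
    ca_params: CAParams = field(default_factory=CAParams)
    nedocs_coeffs: NedocsCoeffs = field(default_factory=NedocsCoeffs)
    run_length: int = 4320
    warm_up: int = 2880
    replications: int = 30
    lwbs_enabled: bool = True
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> "SimConfig":
        if len(self.hourly_rates) != 24:
            raise ConfigError(f"hourly_rates: 24 entries required "
                              f"(got {len(self.hourly_rates)})")
        if any(r < 0 for r in self.hourly_rates):
            raise ConfigError("hourly_rates: rates must be >= 0")
        for name, probs, k in (("mode_probs", self.mode_probs, 3),
                               ("mts_probs", self.mts_probs, 5)):
            if len(probs) != k:
                raise ConfigError(f"{name}: {k} entries required")
            if any(not 0 <= p <= 1 for p in probs):
                raise ConfigError(f"{name}: probabilities must lie in [0,1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"{name}: must sum to 1 (got {sum(probs)})")
        if not self.sections:
            raise ConfigError("sections: at least one section required")
        seen = set()
        for i, sec in enumerate(self.sections):
            sec.validate(f"sections[{i}]")
            if sec.name in seen:
                raise ConfigError(f"sections[{i}].name: duplicate {sec.name!r}")
            seen.add(sec.name)
        for cat in range(5):
            if all(sec.mts_routing_weight[cat] == 0 for sec in self.sections):
                raise ConfigError(f"sections: all routing weights are zero for "
                                  f"MTS category {cat + 1}")
        if self.triage_nurses < 1:
            raise ConfigError("triage_nurses: must be >= 1")
        if self.receptionists < 1:
            raise ConfigError("receptionists: must be >= 1")
        self.triage_time.validate("triage_time")
        self.admission_time.validate("admission_time")
        if self.waiting_capacity < 1:
            raise ConfigError("waiting_capacity: must be >= 1")
        if not 0 <= self.diagnostics_prob <= 1:
            raise ConfigError("diagnostics_prob: must be in [0,1]")
        self.diagnostics_time.validate("diagnostics_time")
        if not 0 < self.doctor_time_fraction <= 1:
            raise ConfigError("doctor_time_fraction: must be in (0,1]")
        if self.service_scale <= 0:
            raise ConfigError("service_scale: must be > 0")
        if self.fast_track_doctors < 0:
            raise ConfigError("fast_track_doctors: must be >= 0")
        if self.fast_track and self.fast_track_doctors < 1:
            raise ConfigError("fast_track_doctors: must be >= 1 when fast_track is on")
        self.fast_track_time.validate("fast_track_time")
        self.ca_params.validate()
        self.nedocs_coeffs.validate()
        if self.run_length <= 0:
            raise ConfigError("run_length: must be > 0")
        if not 0 <= self.warm_up < self.run_length:
            raise ConfigError(f"warm_up: must satisfy 0 <= warm_up < run_length "
                              f"(got warm_up={self.warm_up}, run_length={self.run_length})")
        if self.replications < 1:
            raise ConfigError("replications: must be >= 1")
        return self

    # -- convenience --------------------------------------------------------

    @property
    def daily_arrivals(self) -> float:
        """Expected arrivals per day, the integral of lambda(t) over 24 h."""
        return float(sum(self.hourly_rates))

    @property
    def ed_beds(self) -> int:
        return sum(sec.beds for sec in self.sections)

    def section(self, name: str) -> Section:
        for sec in self.sections:
            if sec.name == name:
                return sec
        raise KeyError(name)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs).validate()

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, DistSpec):
                return obj.to_dict()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [conv(x) for x in obj]
            return obj
        return conv(self)

    @staticmethod
    def from_dict(d: Mapping) -> "SimConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(SimConfig)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config fields: {sorted(extra)}")
        missing = {"hourly_rates", "mode_probs", "mts_probs", "sections"} - set(d)
        if missing:
            raise ConfigError(f"missing required config fields: {sorted(missing)}")

        def tup(x):
            return tuple(x) if isinstance(x, Sequence) and not isinstance(x, str) else x

        kwargs: dict = {}
        for f in dataclasses.fields(SimConfig):
            if f.name not in d:
                continue
            v = d[f.name]
            if f.name in ("triage_time", "admission_time", "diagnostics_time",
                          "fast_track_time"):
                v = DistSpec.from_dict(v, f.name)
            elif f.name == "sections":
                secs = []
                for i, s in enumerate(v):
                    s = dict(s)
                    s["service_time"] = DistSpec.from_dict(
                        s["service_time"], f"sections[{i}].service_time")
                    s["mts_routing_weight"] = tuple(s["mts_routing_weight"])
                    secs.append(Section(**s))
                v = tuple(secs)
            elif f.name == "ca_params":
                v = dict(v)
                for key in ("tol_probs", "tol_short_range", "tol_mid_range"):
                    if key in v:
                        v[key] = tuple(v[key])
                v = CAParams(**v)
            elif f.name == "nedocs_coeffs":
                v = dict(v)
                for key in ("clamp", "cutpoints"):
                    if key in v:
                        v[key] = tuple(v[key])
                v = NedocsCoeffs(**v)
            else:
                v = tup(v)
            kwargs[f.name] = v
        return SimConfig(**kwargs).validate()


def load_config(path: str | Path) -> SimConfig:
    """Load and schema-validate a YAML or JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return SimConfig.from_dict(data)


def save_config(config: SimConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
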