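"""Overcrowding index on [0, 200] with six verbal categories.

A linear score in the spirit of the National Emergency Department
Overcrowding Scale: intercept plus five weighted predictors, clamped to
[0, 200], where 0 reads "not busy" and 200 "dangerously overcrowded".
The engine recomputes it every tick and the abandonment model uses it to
modulate patient tolerance times.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import NEDOCS_CATEGORIES, NedocsCoeffs
from .distributions import ConfigError

__all__ = ["CrowdingSnapshot", "compute_nedocs", "crowding_category",
           "NEDOCS_CATEGORIES"]


@dataclass(frozen=True)
class CrowdingSnapshot:
    """Instantaneous state feeding the crowding score."""

    ed_patients: int          # census: everyone physically in the ED
    ed_beds: int
    boarding: int = 0         # admitted patients waiting for a hospital bed
    waiting_count: int = 0    # patients in the waiting room
    waiting_capacity: int = 30
    longest_admit_wait_h: float = 0.0
    last_bed_wait_min: float = 0.0


def compute_nedocs(snapshot: CrowdingSnapshot, coeffs: NedocsCoeffs) -> float:
    """Linear crowding score, clamped to the configured [0, 200] range."""
    if snapshot.ed_beds <= 0:
        raise ConfigError("ed_beds must be > 0 to compute the crowding index")
    if snapshot.waiting_capacity <= 0:
        raise ConfigError("waiting_capacity must be > 0 to compute the crowding index")
    raw = (coeffs.intercept
           + coeffs.occupancy * (snapshot.ed_patients / snapshot.ed_beds)
           + coeffs.boarding * (snapshot.boarding / coeffs.hospital_beds)
           + coeffs.waiting_ratio * (snapshot.waiting_count / snapshot.waiting_capacity)
           + coeffs.longest_admit_h * snapshot.longest_admit_wait_h
           + coeffs.last_bed_min * snapshot.last_bed_wait_min)
    lo, hi = coeffs.clamp
    return float(min(hi, max(lo, raw)))


def crowding_category(index: float, coeffs: NedocsCoeffs) -> str:
    """Verbal category for a crowding index; boundaries belong to the
    upper category."""
    lo, hi = coeffs.clamp
    if not lo <= index <= hi:
        raise ValueError(f"crowding index {index} outside [{lo}, {hi}]")
    for cut, label in zip(coeffs.cutpoints, NEDOCS_CATEGORIES):
        if index < cut:
            return label
    return NEDOCS_CATEGORIES[-1]
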