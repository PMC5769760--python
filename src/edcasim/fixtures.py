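"""Bundled fixture configurations.

``default_hrtn_config`` describes a tertiary public-hospital ED modelled
on the published case: 162 arrivals/day on average over a two-peak
day/evening profile, six treatment sections, a single triage nurse, a
30-seat waiting room, and the default cellular-automaton abandonment
parameters.  Service-time means and staffing were set by the bundled
calibration (scripts/calibrate_fixture.py) so that baseline section LOS
falls inside the reference confidence intervals and the baseline LWBS
rate lies in the 8.64–10.12% band.
"""

from __future__ import annotations

from .config import Section, SimConfig
from .distributions import DistSpec

__all__ = ["default_hrtn_config", "FIXTURES", "get_fixture", "small_test_config"]

# two-peak profile (patients/hour); sums to exactly 162/day
HRTN_HOURLY_RATES = (
    4.0, 3.5, 3.0, 3.0, 3.0, 3.5,          # 00-05: overnight lull
    4.5, 6.0, 7.5, 9.0, 9.5, 9.5,          # 06-11: morning ramp/peak
    9.0, 8.5, 8.0, 8.5, 8.5, 8.5,          # 12-17: afternoon plateau
    9.0, 9.5, 8.5, 7.5, 6.0, 4.5,          # 18-23: evening peak, wind-down
)


def _lognorm(mean: float, sd: float) -> DistSpec:
    return DistSpec("lognormal", {"mean": mean, "sd": sd})


def default_hrtn_config(**overrides) -> SimConfig:
    """The calibrated default ED scenario (see module docstring)."""
    sections = (
        Section("suturing", beds=8, doctors=2, nurse_technicians=2,
                service_time=_lognorm(158.0, 70.0),
                mts_routing_weight=(0.0, 0.0, 0.20, 0.35, 0.50),
                p_hospitalization=0.02),
        Section("orthopedics", beds=8, doctors=2, nurse_technicians=2,
                service_time=_lognorm(158.0, 72.0),
                mts_routing_weight=(0.0, 0.0, 0.20, 0.35, 0.30),
                p_hospitalization=0.08),
        Section("pediatrics", beds=11, doctors=3, nurse_technicians=3,
                service_time=_lognorm(285.0, 125.0),
                mts_routing_weight=(0.0, 0.15, 0.25, 0.20, 0.20),
                p_hospitalization=0.07),
        Section("clinical_emergency", beds=15, doctors=4, nurse_technicians=4,
                service_time=_lognorm(515.0, 210.0),
                mts_routing_weight=(0.40, 0.30, 0.20, 0.10, 0.0),
                p_hospitalization=0.22),
        Section("surgical_emergency", beds=9, doctors=3, nurse_technicians=3,
                service_time=_lognorm(430.0, 180.0),
                mts_routing_weight=(0.40, 0.25, 0.15, 0.0, 0.0),
                p_hospitalization=0.25),
        Section("yellow_zone", beds=5, doctors=2, nurse_technicians=2,
                service_time=_lognorm(390.0, 165.0),
                mts_routing_weight=(0.20, 0.30, 0.0, 0.0, 0.0),
                p_hospitalization=0.35),
    )
    cfg = SimConfig(
        hourly_rates=HRTN_HOURLY_RATES,
        mode_probs=(0.72, 0.25, 0.03),
        mts_probs=(0.03, 0.15, 0.35, 0.35, 0.12),
        sections=sections,
        triage_nurses=1,
        receptionists=2,
        triage_time=_lognorm(4.4, 2.0),
        admission_time=_lognorm(1.8, 0.9),
        waiting_capacity=30,
        diagnostics_prob=0.3,
        diagnostics_time=_lognorm(45.0, 20.0),
        doctor_time_fraction=0.25,
        fast_track_time=_lognorm(8.0, 4.0),
        run_length=4320,
        warm_up=2880,
        replications=30,
    )
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg.validate()


def small_test_config(**overrides) -> SimConfig:
    """A deliberately tiny single-section scenario for fast tests."""
    sections = (
        Section("suturing", beds=3, doctors=2, nurse_technicians=1,
                service_time=_lognorm(30.0, 10.0),
                mts_routing_weight=(1.0, 1.0, 1.0, 1.0, 1.0),
                p_hospitalization=0.1),
    )
    cfg = SimConfig(
        hourly_rates=(4.0,) * 24,
        mode_probs=(0.8, 0.15, 0.05),
        mts_probs=(0.05, 0.15, 0.35, 0.30, 0.15),
        sections=sections,
        triage_time=_lognorm(4.0, 1.5),
        admission_time=_lognorm(1.8, 0.9),
        waiting_capacity=12,
        diagnostics_prob=0.1,
        diagnostics_time=_lognorm(20.0, 8.0),
        run_length=720,
        warm_up=240,
        replications=3,
    )
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg.validate()


FIXTURES = {"hrtn": default_hrtn_config, "small": small_test_config}


def get_fixture(name: str, **overrides) -> SimConfig:
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    return factory(**overrides)
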