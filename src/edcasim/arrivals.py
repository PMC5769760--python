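"""Patient arrivals and routing through the ED flow.

Arrivals follow a non-homogeneous Poisson process with a piecewise-
constant hourly rate profile lambda(t) (24 intervals), generated by
thinning against the peak rate.  On arrival a patient's mode is drawn
(walk-in, ambulance, or police custody); police-custody patients skip
admission and go straight to triage.  Triage assigns one of five acuity
categories (1 = most urgent), after which the patient is routed to a
treatment section in proportion to that section's routing weight for the
category.
"""

from __future__ import annotations

import numpy as np

from .config import MODES, SimConfig
from .core import Stage

__all__ = ["sample_arrivals", "sample_mode", "initial_stage",
           "triage_assign", "route_after_triage"]


def sample_arrivals(hourly_rates, horizon: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Arrival times (minutes, strictly increasing) on [0, horizon).

    Thinning: candidate events from a homogeneous process at the peak
    rate are kept with probability lambda(t)/lambda_max.  The profile
    repeats every 24 h for horizons beyond one day.
    """
    rates = np.asarray(hourly_rates, dtype=float)
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if rates.ndim != 1 or len(rates) != 24 or (rates < 0).any():
        raise ValueError("hourly_rates must be 24 nonnegative values")
    lam_max = rates.max()
    if lam_max == 0:
        return np.empty(0)
    lam_max_min = lam_max / 60.0          # per minute
    # expected candidate count + slack; top up in the rare shortfall case
    times = []
    t = 0.0
    while True:
        n_guess = max(16, int(lam_max_min * (horizon - t) * 1.25) + 16)
        gaps = rng.exponential(1.0 / lam_max_min, size=n_guess)
        cand = t + np.cumsum(gaps)
        accept_u = rng.random(n_guess)
        for ct, u in zip(cand, accept_u):
            if ct >= horizon:
                return np.array(times)
            hour = int(ct // 60) % 24
            if u < rates[hour] / lam_max:
                times.append(ct)
        t = float(cand[-1])


def sample_mode(rng: np.random.Generator, config: SimConfig) -> str:
    u = rng.random()
    cum = 0.0
    for mode, p in zip(MODES, config.mode_probs):
        cum += p
        if u < cum:
            return mode
    return MODES[-1]


def initial_stage(mode: str) -> str:
    """Police-custody patients skip admission and go directly to triage."""
    return Stage.TRIAGE if mode == "police" else Stage.ADMISSION


def triage_assign(rng: np.random.Generator, config: SimConfig) -> int:
    """Draw an acuity category 1..5 from the configured category mix."""
    u = rng.random()
    cum = 0.0
    for cat, p in enumerate(config.mts_probs, start=1):
        cum += p
        if u < cum:
            return cat
    return 5


def route_after_triage(mts: int, rng: np.random.Generator,
                       config: SimConfig) -> str:
    """Sample a treatment section proportionally to its routing weight for
    the patient's acuity category."""
    weights = np.array([sec.mts_routing_weight[mts - 1] for sec in config.sections],
                       dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"no section accepts MTS category {mts}")
    u = rng.random() * total
    cum = 0.0
    for sec, w in zip(config.sections, weights):
        cum += w
        if u < cum:
            return sec.name
    return config.sections[-1].name


def goes_to_fast_track(mts: int, config: SimConfig) -> bool:
    """Under the fast-track policy, the two least urgent categories are
    treated right after triage by a dedicated doctor."""
    return config.fast_track and mts in (4, 5)
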