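"""The four LWBS-prevention policies as pure config transformations.

* ``p1_extra_triage`` — add one triage nurse (the baseline department has
  a single nurse triaging every arrival).
* ``p2_fast_track`` — a dedicated doctor treats the two least urgent
  acuity categories (4 and 5) right after triage, bypassing the section
  wait.
* ``p3_bigger_waiting`` — enlarge the waiting room from 30 to 40 seats.
* ``p4_faster_service`` — staff work 10% faster: every staffed activity
  duration (treatment, triage, diagnostics) is scaled by 0.9.  The total
  length of stay falls by less than 10%, because waiting times respond to
  queueing, not to the transform itself.
"""

from __future__ import annotations

from .config import SimConfig

__all__ = ["POLICIES", "apply_policy"]

POLICIES = ("baseline", "p1_extra_triage", "p2_fast_track",
            "p3_bigger_waiting", "p4_faster_service")

_ALIASES = {"p1": "p1_extra_triage", "p2": "p2_fast_track",
            "p3": "p3_bigger_waiting", "p4": "p4_faster_service"}


def apply_policy(config: SimConfig, policy: str) -> SimConfig:
    """Return a new config with the policy applied; the input is untouched.

    ``p2``/``p3`` are idempotent (re-application is a no-op once the
    target state holds); ``p1``/``p4`` compose (two applications add two
    nurses / scale by 0.81).
    """
    policy = _ALIASES.get(policy, policy)
    if policy == "baseline":
        return config
    if policy == "p1_extra_triage":
        return config.replace(triage_nurses=config.triage_nurses + 1)
    if policy == "p2_fast_track":
        if config.fast_track:
            return config
        return config.replace(fast_track=True,
                              fast_track_doctors=max(1, config.fast_track_doctors))
    if policy == "p3_bigger_waiting":
        if config.waiting_capacity >= 40:
            return config
        return config.replace(waiting_capacity=40)
    if policy == "p4_faster_service":
        return config.replace(service_scale=config.service_scale * 0.9)
    raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
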