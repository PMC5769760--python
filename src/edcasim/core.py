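"""Agent and state containers, the message bus, and the blackboard.

Three communication types connect agents:

* **one-to-one** — a message delivered exclusively from one agent to
  another (a patient entering triage flips the nurse from "waiting for a
  patient" to "giving service");
* **one-to-n** — the same message delivered to an explicit group;
* **one-to-location** — delivered to every agent currently at a location,
  or, when posted with an expiry, to every agent entering the location
  while the posting is active.

The blackboard is a shared read/write area every agent can consult: the
current waiting-room count, the history of patients who left without
being seen, per-section queue lengths and the current crowding index.
The engine refreshes it at the end of every tick so that all agents see
the same global state when the next tick begins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from .ca import ReportMemory

__all__ = ["Stage", "Patient", "StaffAgent", "Message", "Blackboard",
           "MessageBus", "MessageError"]


class Stage:
    ADMISSION = "admission"
    TRIAGE = "triage"
    WAITING = "waiting"
    IN_SERVICE = "in_service"
    DIAGNOSTICS = "diagnostics"
    DISCHARGED = "discharged"
    HOSPITALIZED = "hospitalized"
    LWBS = "lwbs"

    TERMINAL = frozenset({DISCHARGED, HOSPITALIZED, LWBS})
    ALL = (ADMISSION, TRIAGE, WAITING, IN_SERVICE, DIAGNOSTICS,
           DISCHARGED, HOSPITALIZED, LWBS)


@dataclass
class Patient:
    """A patient agent.

    ``tolerance`` is the nominal tolerance time drawn at arrival
    (``math.inf`` = waits indefinitely); ``effective_tolerance`` is fixed
    at seating time from the then-current crowding index.  ``wait_start``
    anchors the patient's perceived wait: the ED arrival time, since the
    agent's memory is the total time spent in the department.
    """

    id: int
    arrival_time: float
    mode: str                       # self | ambulance | police
    mts: Optional[int] = None       # 1 (most urgent) .. 5
    stage: str = Stage.ADMISSION
    section: Optional[str] = None
    seat: Optional[tuple[int, int]] = None
    fast_tracked: bool = False
    tolerance: float = math.inf
    effective_tolerance: float = math.inf
    wait_start: float = 0.0
    memory: ReportMemory = field(default_factory=ReportMemory)
    extension_deadline: Optional[float] = None
    nedocs_at_seating: float = 0.0
    stage_timestamps: dict[str, float] = field(default_factory=dict)

    @property
    def n_delayed(self) -> int:
        return self.memory.n_delayed

    @property
    def n_normal(self) -> int:
        return self.memory.n_normal

    @property
    def ever_had_neighbor(self) -> bool:
        return self.memory.ever_had_neighbor

    def enter_stage(self, stage: str, now: float) -> None:
        self.stage = stage
        self.stage_timestamps[stage] = now


@dataclass
class StaffAgent:
    """A staff agent; ``giving_service`` exactly when a patient is assigned."""

    id: int
    role: str                       # receptionist | triage_nurse | doctor | nurse_technician
    section: Optional[str] = None   # section name, or "triage"/"admission"/"fast_track"
    current_patient: Optional[int] = None

    @property
    def state(self) -> str:
        return "giving_service" if self.current_patient is not None else "waiting_for_patient"

    def begin(self, patient_id: int) -> None:
        self.current_patient = patient_id

    def finish(self) -> None:
        self.current_patient = None


class MessageError(ValueError):
    """Malformed or undeliverable message."""


@dataclass(frozen=True)
class Message:
    comm_type: str                              # one_to_one | one_to_n | one_to_location
    sender: int
    payload: object
    post_time: float
    recipients: Optional[frozenset[int]] = None
    location: Optional[str] = None
    expiry: Optional[float] = None

    def validate(self) -> None:
        if self.comm_type not in ("one_to_one", "one_to_n", "one_to_location"):
            raise MessageError(f"unknown communication type {self.comm_type!r}")
        if self.comm_type == "one_to_location":
            if self.location is None or self.recipients is not None:
                raise MessageError("one_to_location messages name a location, "
                                   "not recipients")
            if self.expiry is not None and self.expiry <= self.post_time:
                raise MessageError("expiry must be after post_time")
        else:
            if self.recipients is None or self.location is not None:
                raise MessageError(f"{self.comm_type} messages name recipients, "
                                   "not a location")
            if self.comm_type == "one_to_one" and len(self.recipients) != 1:
                raise MessageError("one_to_one requires exactly one recipient")
            if not self.recipients:
                raise MessageError("recipient set must be nonempty")


class MessageBus:
    """Delivers agent messages; timed location postings stay active until
    expiry and reach any agent entering the location during the window.

    ``location_members`` maps a location name to the ids of agents
    currently there; ``known_agents`` (optional) enables recipient
    validation.  Deliveries are appended to per-agent inboxes and to a
    flat ``deliveries`` log of (time, recipient, message).
    """

    def __init__(self,
                 location_members: Optional[Callable[[str], list[int]]] = None,
                 known_agents: Optional[Callable[[int], bool]] = None):
        self._members = location_members or (lambda loc: [])
        self._known = known_agents
        self.inboxes: dict[int, list[Message]] = {}
        self.deliveries: list[tuple[float, int, Message]] = []
        self._timed: list[tuple[Message, set[int]]] = []  # posting, already-delivered

    def _deliver(self, msg: Message, recipient: int, now: float) -> None:
        self.inboxes.setdefault(recipient, []).append(msg)
        self.deliveries.append((now, recipient, msg))

    def post(self, msg: Message, now: Optional[float] = None) -> int:
        """Post a message; returns the number of immediate deliveries."""
        msg.validate()
        now = msg.post_time if now is None else now
        if self._known is not None and not self._known(msg.sender):
            raise MessageError(f"unknown sender id {msg.sender}")
        if msg.comm_type in ("one_to_one", "one_to_n"):
            if self._known is not None:
                for rid in msg.recipients:
                    if not self._known(rid):
                        raise MessageError(f"unknown recipient id {rid}")
            for rid in sorted(msg.recipients):
                self._deliver(msg, rid, now)
            return len(msg.recipients)
        # one_to_location
        if msg.expiry is None:
            members = sorted(self._members(msg.location))
            for rid in members:
                self._deliver(msg, rid, now)
            return len(members)
        if now >= msg.expiry:
            return 0  # expired on arrival: no-op
        self._timed.append((msg, set()))
        return 0

    def on_enter(self, agent_id: int, location: str, now: float) -> int:
        """Agent enters a location: deliver active timed postings (once each)."""
        delivered = 0
        still_active = []
        for msg, seen in self._timed:
            if now >= msg.expiry:
                continue
            if msg.location == location and msg.post_time <= now and agent_id not in seen:
                self._deliver(msg, agent_id, now)
                seen.add(agent_id)
                delivered += 1
            still_active.append((msg, seen))
        self._timed = still_active
        return delivered


@dataclass
class Blackboard:
    """Shared state every agent can read and write."""

    waiting_count: int = 0
    lwbs_history: list[tuple[float, Optional[tuple[int, int]], float]] = field(
        default_factory=list)           # (time, seat, minutes waited)
    lwbs_ids: set[int] = field(default_factory=set)
    queue_lengths: dict[str, int] = field(default_factory=dict)
    current_nedocs: float = 0.0

    def record_lwbs(self, patient_id: int, time: float,
                    seat: Optional[tuple[int, int]], minutes_waited: float) -> None:
        self.lwbs_history.append((time, seat, minutes_waited))
        self.lwbs_ids.add(patient_id)
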