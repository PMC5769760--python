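"""Time-stepped simulation engine.

The engine advances a fixed 1-minute tick.  Within a tick, events are
processed in a fixed order for reproducibility:

1. departures (service/diagnostics completions, dispositions),
2. service starts (free doctors and beds call patients from the waiting
   room by acuity, then arrival order),
3. triage completions and starts,
4. admission completions and starts,
5. new arrivals,
6. cellular-automaton abandonment decisions in the waiting room,
7. blackboard and crowding-index refresh, so that at the next step every
   agent sees the same global state.

Randomness is split into named substreams (arrivals, modes, acuity,
tolerance, routing, service, ...) derived from one root seed, so that two
scenarios run with the same seed share the same arrival stream and
patient population — common random numbers for sharp policy contrasts.

Timing granularity: durations are continuous draws; a completion
scheduled at a fractional minute takes effect at the next whole-minute
tick.
"""

from __future__ import annotations

import heapq
import itertools
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import arrivals as arr
from .ca import (SeatGrid, collect_reports, effective_tolerance,
                 extension_time, lwbs_decision, neighbors, sample_tolerance)
from .config import SimConfig
from .core import Blackboard, Message, MessageBus, Patient, Stage, StaffAgent
from .nedocs import CrowdingSnapshot, compute_nedocs

__all__ = ["Engine", "EngineResult"]

_STREAMS = ("arrivals", "mode", "mts", "tolerance", "routing",
            "admission", "triage", "service", "diagnostics",
            "disposition", "seating", "fast_track")


@dataclass
class EngineResult:
    """Raw output of one simulation run."""

    config: SimConfig
    seed: int
    event_log: list[dict] = field(default_factory=list)
    nedocs_series: list[float] = field(default_factory=list)
    n_arrivals: int = 0


class Engine:
    """One ED scenario run; see module docstring for the tick discipline."""

    def __init__(self, config: SimConfig, seed: Optional[int] = None):
        config.validate()
        self.config = config
        self.seed = config.seed if seed is None else seed
        ss = np.random.SeedSequence(self.seed)
        self.rng = dict(zip(_STREAMS, map(np.random.default_rng, ss.spawn(len(_STREAMS)))))

        self.clock: int = 0
        self.patients: dict[int, Patient] = {}
        self.seat_grid = SeatGrid.for_capacity(config.waiting_capacity)
        self.blackboard = Blackboard()
        self.bus = MessageBus(location_members=self._location_members,
                              known_agents=self._known_agent)
        self.event_log: list[dict] = []
        self.nedocs_series: list[float] = []

        # staff agents (negative ids so they never collide with patients)
        self.staff: dict[int, StaffAgent] = {}
        self._staff_counter = itertools.count(1)
        self._free_receptionists = self._make_pool("receptionist", "admission",
                                                   config.receptionists)
        self._free_triage_nurses = self._make_pool("triage_nurse", "triage",
                                                   config.triage_nurses)
        self._free_doctors: dict[str, list[int]] = {}
        self._beds_free: dict[str, int] = {}
        for sec in config.sections:
            self._free_doctors[sec.name] = self._make_pool("doctor", sec.name,
                                                           sec.doctors)
            self._make_pool("nurse_technician", sec.name, sec.nurse_technicians)
            self._beds_free[sec.name] = sec.beds
        self._free_ft_doctors = self._make_pool(
            "doctor", "fast_track",
            config.fast_track_doctors if config.fast_track else 0)

        # queues
        self._admission_queue: deque[int] = deque()
        self._triage_queue: deque[int] = deque()
        self._section_queue: dict[str, list] = {s.name: [] for s in config.sections}
        self._ft_queue: deque[int] = deque()
        self._waiting: dict[int, None] = {}      # insertion-ordered set
        self._unseated: deque[int] = deque()

        # completion heaps: (time, seq, payload...)
        self._seq = itertools.count()
        self._adm_end: list = []
        self._tri_end: list = []
        self._attn_end: list = []    # (t, seq, section, staff_id)
        self._svc_end: list = []     # (t, seq, pid, section)
        self._diag_evt: list = []    # (t, seq, pid, "start"/"end")
        self._ft_end: list = []      # (t, seq, pid, staff_id)

        self._last_bed_wait_min: float = 0.0
        self._neighbor_map = self._build_neighbor_map()

        # pre-generate the arrival stream and per-patient marks (common
        # random numbers: consumed in arrival order, independent of policy)
        times = arr.sample_arrivals(config.hourly_rates, config.run_length,
                                    self.rng["arrivals"])
        self._arrival_times = times
        self._arrival_ptr = 0
        self.n_arrivals = len(times)

        # counters for the conservation invariant
        self.n_departed = 0

    # -- plumbing -----------------------------------------------------------

    def _make_pool(self, role: str, section: str, n: int) -> list[int]:
        pool = []
        for _ in range(n):
            sid = -next(self._staff_counter)
            self.staff[sid] = StaffAgent(id=sid, role=role, section=section)
            heapq.heappush(pool, -sid)   # stable lowest-|id| first
        return pool

    def _take_staff(self, pool: list[int], patient_id: int) -> int:
        sid = -heapq.heappop(pool)
        self.staff[sid].begin(patient_id)
        return sid

    def _release_staff(self, pool: list[int], sid: int) -> None:
        self.staff[sid].finish()
        heapq.heappush(pool, -sid)

    def _known_agent(self, aid: int) -> bool:
        return aid in self.patients or aid in self.staff

    def _location_members(self, location: str) -> list[int]:
        if location == "waiting_room":
            return list(self._waiting)
        return [p.id for p in self.patients.values()
                if p.stage == Stage.IN_SERVICE and p.section == location]

    def _log(self, time: float, pid: int, event: str, stage: str,
             detail: Optional[dict] = None) -> None:
        self.event_log.append({"time": time, "patient_id": pid, "event": event,
                               "stage": stage, "detail": detail or {}})

    def _build_neighbor_map(self) -> dict:
        ca = self.config.ca_params
        out = {}
        for r in range(self.seat_grid.rows):
            for c in range(self.seat_grid.cols):
                out[(r, c)] = neighbors(self.seat_grid, (r, c), ca.scheme, ca.r)
        return out

    def post_message(self, msg: Message) -> int:
        """Post a message on the bus at the current clock."""
        return self.bus.post(msg, now=self.clock)

    # -- patient transitions ------------------------------------------------

    def _enter_waiting(self, p: Patient, now: float) -> None:
        p.enter_stage(Stage.WAITING, now)
        p.nedocs_at_seating = self.blackboard.current_nedocs
        p.effective_tolerance = effective_tolerance(
            p.tolerance, p.nedocs_at_seating, self.config.ca_params)
        self._waiting[p.id] = None
        seat = self.seat_grid.seat_patient(p.id, self.rng["seating"])
        p.seat = seat
        if seat is None:
            self._unseated.append(p.id)
        if p.fast_tracked:
            self._ft_queue.append(p.id)
        else:
            heapq.heappush(self._section_queue[p.section],
                           (p.mts, p.arrival_time, p.id))
        self.bus.on_enter(p.id, "waiting_room", now)

    def _leave_waiting(self, p: Patient) -> None:
        self._waiting.pop(p.id, None)
        self.seat_grid.release(p.id)
        p.seat = None

    def _dispose(self, p: Patient, now: float) -> None:
        sec = self.config.section(p.section)
        hosp = self.rng["disposition"].random() < sec.p_hospitalization
        outcome = Stage.HOSPITALIZED if hosp else Stage.DISCHARGED
        p.enter_stage(outcome, now)
        self.n_departed += 1
        self._log(now, p.id, outcome, outcome, {"section": p.section})

    def _start_section_service(self, p: Patient, section: str, now: float) -> None:
        cfg = self.config
        sec = cfg.section(section)
        self._leave_waiting(p)
        wait = now - p.stage_timestamps.get(Stage.WAITING, now)
        self._last_bed_wait_min = wait
        p.enter_stage(Stage.IN_SERVICE, now)
        self._beds_free[section] -= 1
        sid = self._take_staff(self._free_doctors[section], p.id)
        self.post_message(Message(comm_type="one_to_one", sender=sid,
                                  recipients=frozenset({p.id}),
                                  payload="called_for_treatment", post_time=now))
        duration = sec.service_time.sample(self.rng["service"], cfg.service_scale)
        attention = cfg.doctor_time_fraction * duration
        seq = next(self._seq)
        heapq.heappush(self._attn_end, (now + attention, seq, section, sid))
        end = now + duration
        if self.rng["diagnostics"].random() < cfg.diagnostics_prob:
            delay = cfg.diagnostics_time.sample(self.rng["diagnostics"],
                                                cfg.service_scale)
            heapq.heappush(self._diag_evt,
                           (now + attention, next(self._seq), p.id, "start"))
            heapq.heappush(self._diag_evt,
                           (now + attention + delay, next(self._seq), p.id, "end"))
            end += delay
        heapq.heappush(self._svc_end, (end, next(self._seq), p.id, section))
        self._log(now, p.id, "service_start", Stage.IN_SERVICE,
                  {"section": section, "wait": wait})

    def _start_fast_track(self, p: Patient, now: float) -> None:
        cfg = self.config
        self._leave_waiting(p)
        self._last_bed_wait_min = now - p.stage_timestamps.get(Stage.WAITING, now)
        p.enter_stage(Stage.IN_SERVICE, now)
        sid = self._take_staff(self._free_ft_doctors, p.id)
        self.post_message(Message(comm_type="one_to_one", sender=sid,
                                  recipients=frozenset({p.id}),
                                  payload="called_for_treatment", post_time=now))
        duration = cfg.fast_track_time.sample(self.rng["fast_track"],
                                              cfg.service_scale)
        heapq.heappush(self._ft_end, (now + duration, next(self._seq), p.id, sid))
        self._log(now, p.id, "service_start", Stage.IN_SERVICE,
                  {"section": "fast_track", "wait": self._last_bed_wait_min})

    # -- tick phases --------------------------------------------------------

    def _phase_departures(self, now: float) -> None:
        while self._attn_end and self._attn_end[0][0] <= now:
            _, _, section, sid = heapq.heappop(self._attn_end)
            self._release_staff(self._free_doctors[section], sid)
        while self._diag_evt and self._diag_evt[0][0] <= now:
            t, _, pid, kind = heapq.heappop(self._diag_evt)
            p = self.patients[pid]
            if kind == "start":
                p.enter_stage(Stage.DIAGNOSTICS, t)
                self._log(t, pid, "diagnostics_start", Stage.DIAGNOSTICS, {})
            else:
                p.enter_stage(Stage.IN_SERVICE, t)
                self._log(t, pid, "diagnostics_end", Stage.IN_SERVICE, {})
        while self._svc_end and self._svc_end[0][0] <= now:
            _, _, pid, section = heapq.heappop(self._svc_end)
            self._beds_free[section] += 1
            self._dispose(self.patients[pid], now)
        while self._ft_end and self._ft_end[0][0] <= now:
            _, _, pid, sid = heapq.heappop(self._ft_end)
            self._release_staff(self._free_ft_doctors, sid)
            self._dispose(self.patients[pid], now)

    def _phase_services(self, now: float) -> None:
        for sec in self.config.sections:
            name = sec.name
            q = self._section_queue[name]
            while self._beds_free[name] > 0 and self._free_doctors[name]:
                while q:
                    _, _, pid = q[0]
                    p = self.patients[pid]
                    if p.stage == Stage.WAITING and not p.fast_tracked:
                        break
                    heapq.heappop(q)      # stale (left or fast-tracked)
                else:
                    break
                heapq.heappop(q)
                self._start_section_service(self.patients[pid], name, now)
        while self._free_ft_doctors and self._ft_queue:
            pid = self._ft_queue.popleft()
            p = self.patients[pid]
            if p.stage == Stage.WAITING:
                self._start_fast_track(p, now)

    def _phase_triage(self, now: float) -> None:
        cfg = self.config
        while self._tri_end and self._tri_end[0][0] <= now:
            _, _, pid, sid = heapq.heappop(self._tri_end)
            self._release_staff(self._free_triage_nurses, sid)
            p = self.patients[pid]
            p.fast_tracked = arr.goes_to_fast_track(p.mts, cfg)
            self._log(now, pid, "triage", Stage.TRIAGE,
                      {"mts": p.mts, "section": p.section,
                       "fast_track": p.fast_tracked})
            self._enter_waiting(p, now)
        while self._free_triage_nurses and self._triage_queue:
            pid = self._triage_queue.popleft()
            p = self.patients[pid]
            sid = self._take_staff(self._free_triage_nurses, pid)
            self.post_message(Message(comm_type="one_to_one", sender=pid,
                                      recipients=frozenset({sid}),
                                      payload="patient_at_triage", post_time=now))
            p.enter_stage(Stage.TRIAGE, now)
            duration = cfg.triage_time.sample(self.rng["triage"], cfg.service_scale)
            heapq.heappush(self._tri_end, (now + duration, next(self._seq), pid, sid))

    def _phase_admissions(self, now: float) -> None:
        while self._adm_end and self._adm_end[0][0] <= now:
            _, _, pid, sid = heapq.heappop(self._adm_end)
            self._release_staff(self._free_receptionists, sid)
            self._triage_queue.append(pid)
        while self._free_receptionists and self._admission_queue:
            pid = self._admission_queue.popleft()
            sid = self._take_staff(self._free_receptionists, pid)
            duration = self.config.admission_time.sample(self.rng["admission"])
            heapq.heappush(self._adm_end, (now + duration, next(self._seq), pid, sid))

    def _phase_arrivals(self, now: float) -> None:
        cfg = self.config
        while (self._arrival_ptr < len(self._arrival_times)
               and self._arrival_times[self._arrival_ptr] <= now):
            t = float(self._arrival_times[self._arrival_ptr])
            pid = self._arrival_ptr
            self._arrival_ptr += 1
            mode = arr.sample_mode(self.rng["mode"], cfg)
            mts = arr.triage_assign(self.rng["mts"], cfg)
            tol = sample_tolerance(self.rng["tolerance"], cfg.ca_params)
            section = arr.route_after_triage(mts, self.rng["routing"], cfg)
            if not cfg.lwbs_enabled:
                tol = math.inf
            p = Patient(id=pid, arrival_time=t, mode=mode, mts=mts,
                        tolerance=tol, wait_start=t, section=section)
            p.stage_timestamps["arrival"] = t
            self.patients[pid] = p
            self._log(t, pid, "arrival", arr.initial_stage(mode), {"mode": mode})
            if arr.initial_stage(mode) == Stage.TRIAGE:
                p.enter_stage(Stage.TRIAGE, t)
                self._triage_queue.append(pid)
            else:
                p.enter_stage(Stage.ADMISSION, t)
                self._admission_queue.append(pid)

    def _phase_ca(self, now: float) -> None:
        if not self.config.lwbs_enabled:
            return
        # standing patients take freed seats in order of arrival to the room
        while self.seat_grid.n_free > 0 and self._unseated:
            pid = self._unseated.popleft()
            p = self.patients.get(pid)
            if p is None or p.stage != Stage.WAITING or p.seat is not None:
                continue
            p.seat = self.seat_grid.seat_patient(pid, self.rng["seating"])
        ca = self.config.ca_params
        lwbs_ids = self.blackboard.lwbs_ids
        if ca.modulation == "continuous":
            nedocs = self.blackboard.current_nedocs
            for pid in self._waiting:
                q = self.patients[pid]
                q.effective_tolerance = effective_tolerance(q.tolerance, nedocs, ca)
        wait_of, tol_of = {}, {}
        for pid in self._waiting:
            q = self.patients[pid]
            wait_of[pid] = now - q.wait_start
            tol_of[pid] = q.effective_tolerance
        for pid in list(self._waiting):
            p = self.patients[pid]
            if p.stage != Stage.WAITING:
                continue
            if p.seat is not None:
                nbr = [self.seat_grid.occupancy[s]
                       for s in self._neighbor_map[p.seat]
                       if s in self.seat_grid.occupancy]
                collect_reports(p.memory, nbr, wait_of, tol_of, lwbs_ids)
            decision = lwbs_decision(wait_of[pid], p.effective_tolerance,
                                     p.n_delayed, p.n_normal,
                                     p.ever_had_neighbor,
                                     p.extension_deadline, now)
            if decision == "extend":
                p.extension_deadline = now + extension_time(p.tolerance, ca)
            elif decision == "leave":
                seat = p.seat
                self._leave_waiting(p)
                p.enter_stage(Stage.LWBS, now)
                self.n_departed += 1
                self.blackboard.record_lwbs(pid, now, seat, wait_of[pid])
                self._log(now, pid, "lwbs", Stage.LWBS, {
                    "minutes_waited": wait_of[pid],
                    "tolerance": p.tolerance,
                    "effective_tolerance": p.effective_tolerance,
                    "n_delayed": p.n_delayed, "n_normal": p.n_normal,
                    "nedocs_at_seating": p.nedocs_at_seating})

    def _phase_refresh(self, now: float) -> None:
        bb = self.blackboard
        bb.waiting_count = len(self._waiting)
        bb.queue_lengths = {
            "admission": len(self._admission_queue),
            "triage": len(self._triage_queue),
            "fast_track": sum(1 for pid in self._ft_queue
                              if self.patients[pid].stage == Stage.WAITING),
        }
        for name, q in self._section_queue.items():
            bb.queue_lengths[name] = sum(
                1 for _, _, pid in q
                if self.patients[pid].stage == Stage.WAITING
                and not self.patients[pid].fast_tracked)
        census = sum(1 for p in self.patients.values()
                     if p.stage not in Stage.TERMINAL)
        snap = CrowdingSnapshot(
            ed_patients=census, ed_beds=self.config.ed_beds,
            boarding=0, waiting_count=bb.waiting_count,
            waiting_capacity=self.config.waiting_capacity,
            longest_admit_wait_h=0.0,
            last_bed_wait_min=self._last_bed_wait_min)
        bb.current_nedocs = compute_nedocs(snap, self.config.nedocs_coeffs)
        self.nedocs_series.append(bb.current_nedocs)

    # -- public API ---------------------------------------------------------

    def step(self) -> None:
        """Advance the simulation by one 1-minute tick."""
        now = self.clock + 1
        self._phase_departures(now)
        self._phase_services(now)
        self._phase_triage(now)
        self._phase_admissions(now)
        self._phase_arrivals(now)
        self._phase_ca(now)
        self._phase_refresh(now)
        self.clock = now

    def run(self) -> EngineResult:
        while self.clock < self.config.run_length:
            self.step()
        return EngineResult(config=self.config, seed=self.seed,
                            event_log=self.event_log,
                            nedocs_series=self.nedocs_series,
                            n_arrivals=self._arrival_ptr)

    def in_system(self) -> int:
        """Patients currently in the ED (conservation check helper)."""
        return sum(1 for p in self.patients.values()
                   if p.stage not in Stage.TERMINAL)

    def check_conservation(self) -> bool:
        """Arrivals == departures + patients still in the system."""
        return self._arrival_ptr == self.n_departed + self.in_system()
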