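"""Cellular-automaton abandonment model for the waiting room.

Patients sit on a rectangular seat lattice.  Each patient carries a
tolerance time drawn from a three-bin mixture (51% wait up to 120 min,
17% between 120 and 480 min, 32% indefinitely), adjusted for crowding at
seating time.  Once a patient's elapsed wait reaches the adjusted
tolerance, the decision to leave without being seen (LWBS) depends on the
memorised experiences of lattice neighbours: if at least as many
neighbours were delayed as were served normally, the patient leaves;
otherwise the patient waits one extra grace period of
``extension_factor x tolerance`` minutes before leaving.  A patient who
never had a neighbour leaves exactly at the tolerance time.

Neighbourhoods are the standard automaton ones: Moore (Chebyshev
distance <= r) or Von Neumann (Manhattan distance <= r), clipped at the
lattice boundary.  The default, Von Neumann with r = 1, gives each seat
up to four neighbours: left, right, front and back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .config import CAParams

__all__ = [
    "SeatGrid", "neighbors", "sample_tolerance", "effective_tolerance",
    "extension_time", "lwbs_decision", "collect_reports", "grid_shape",
    "Decision",
]

INFINITE = math.inf

#: decisions returned by :func:`lwbs_decision`
Decision = str  # "stay" | "extend" | "leave"


def grid_shape(capacity: int) -> tuple[int, int]:
    """Near-square (rows, cols) lattice holding exactly ``capacity`` seats.

    Capacity 30 gives a 6x5 room, capacity 40 gives 8x5; a prime capacity
    degenerates to a single row, which simply makes the lattice
    one-dimensional.
    """
    best = (capacity, 1)
    for cols in range(1, int(math.isqrt(capacity)) + 1):
        if capacity % cols == 0:
            best = (capacity // cols, cols)
    return best


class SeatGrid:
    """Waiting-room seating lattice; occupancy maps seat -> patient id."""

    def __init__(self, rows: int, cols: int):
        if rows < 1 or cols < 1:
            raise ValueError("grid must have at least one row and column")
        self.rows = rows
        self.cols = cols
        self.occupancy: dict[tuple[int, int], int] = {}
        self._free: list[tuple[int, int]] = [
            (r, c) for r in range(rows) for c in range(cols)]
        self._seat_of: dict[int, tuple[int, int]] = {}

    @classmethod
    def for_capacity(cls, capacity: int) -> "SeatGrid":
        return cls(*grid_shape(capacity))

    @property
    def capacity(self) -> int:
        return self.rows * self.cols

    @property
    def n_free(self) -> int:
        return len(self._free)

    def in_bounds(self, seat: tuple[int, int]) -> bool:
        r, c = seat
        return 0 <= r < self.rows and 0 <= c < self.cols

    def seat_patient(self, patient_id: int, rng: np.random.Generator
                     ) -> Optional[tuple[int, int]]:
        """Seat a patient at a uniformly random free seat.

        Returns the seat, or ``None`` when the room is full (the caller
        treats the patient as standing: waiting, but with no neighbours).
        """
        if not self._free:
            return None
        idx = int(rng.integers(len(self._free)))
        seat = self._free.pop(idx)
        self.occupancy[seat] = patient_id
        self._seat_of[patient_id] = seat
        return seat

    def release(self, patient_id: int) -> None:
        seat = self._seat_of.pop(patient_id, None)
        if seat is not None:
            del self.occupancy[seat]
            self._free.append(seat)

    def seat_of(self, patient_id: int) -> Optional[tuple[int, int]]:
        return self._seat_of.get(patient_id)


def neighbors(grid: SeatGrid, seat: tuple[int, int], scheme: str = "neumann",
              r: int = 1) -> list[tuple[int, int]]:
    """In-bounds neighbourhood of ``seat``, excluding the seat itself.

    ``moore``: Chebyshev distance <= r (square); ``neumann``: Manhattan
    distance <= r (diamond).  ``r = 0`` yields the empty set.
    """
    if not grid.in_bounds(seat):
        raise ValueError(f"seat {seat} out of bounds for "
                         f"{grid.rows}x{grid.cols} grid")
    if r < 0:
        raise ValueError("neighborhood range r must be >= 0")
    if scheme not in ("moore", "neumann"):
        raise ValueError(f"unknown neighborhood scheme {scheme!r}")
    r0, c0 = seat
    out = []
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if dr == 0 and dc == 0:
                continue
            if scheme == "neumann" and abs(dr) + abs(dc) > r:
                continue
            s = (r0 + dr, c0 + dc)
            if grid.in_bounds(s):
                out.append(s)
    return out


def sample_tolerance(rng: np.random.Generator, ca: CAParams) -> float:
    """Draw a tolerance time (minutes; ``math.inf`` = waits indefinitely).

    Mixture: p_short uniform on the short bin, p_mid uniform on the middle
    bin, and the remainder infinite.
    """
    p_short, p_mid, _ = ca.tol_probs
    u = rng.random()
    if u < p_short:
        lo, hi = ca.tol_short_range
        return float(lo + (hi - lo) * rng.random())
    if u < p_short + p_mid:
        lo, hi = ca.tol_mid_range
        return float(lo + (hi - lo) * rng.random())
    return INFINITE


def effective_tolerance(tolerance: float, nedocs: float, ca: CAParams) -> float:
    """Crowding-adjusted tolerance.

    The multiplier falls linearly from ``1 + crowding_boost`` at crowding
    index 0 to ``1 + crowding_floor`` at 200: an un-crowded ED extends a
    patient's patience by up to 30% of the nominal tolerance, while a
    dangerously overcrowded one shortens it.  Infinite tolerance stays
    infinite.
    """
    if not 0 <= nedocs <= 200:
        raise ValueError(f"crowding index must lie in [0, 200], got {nedocs}")
    if math.isinf(tolerance):
        return INFINITE
    m = 1.0 + ca.crowding_boost - (ca.crowding_boost - ca.crowding_floor) * (nedocs / 200.0)
    return tolerance * m


def extension_time(tolerance: float, ca: CAParams) -> float:
    """Grace period granted when memorised neighbours are mostly normal."""
    if math.isinf(tolerance):
        raise ValueError("extension time is undefined for infinite tolerance")
    return ca.extension_factor * tolerance


@dataclass
class ReportMemory:
    """A waiting patient's memory of neighbour experiences.

    One report per distinct neighbour; a report flips to "delayed"
    permanently once the neighbour is observed waiting past its own
    tolerance or leaving unseen (via the shared LWBS history).
    """
    reports: dict[int, bool] = field(default_factory=dict)  # id -> delayed?

    @property
    def n_delayed(self) -> int:
        return sum(self.reports.values())

    @property
    def n_normal(self) -> int:
        return len(self.reports) - self.n_delayed

    @property
    def ever_had_neighbor(self) -> bool:
        return bool(self.reports)


def collect_reports(memory: ReportMemory,
                    neighbor_ids: Iterable[int],
                    wait_of: Mapping[int, float],
                    eff_tol_of: Mapping[int, float],
                    lwbs_ids: frozenset | set = frozenset()) -> ReportMemory:
    """Update a patient's memory from its current lattice neighbours.

    ``neighbor_ids`` are the patients presently seated in neighbouring
    seats; ``wait_of``/``eff_tol_of`` give each one's elapsed wait and
    crowding-adjusted tolerance; ``lwbs_ids`` is the shared blackboard's
    history of patients who left unseen.  A neighbour counts as delayed if
    its wait exceeds its own tolerance or if it appears in the LWBS
    history; otherwise it counts as normal.  Reports are sticky once
    delayed.
    """
    for nid in neighbor_ids:
        delayed = memory.reports.get(nid, False)
        if not delayed:
            delayed = nid in lwbs_ids or wait_of[nid] > eff_tol_of[nid]
        memory.reports[nid] = delayed
    for nid in memory.reports:
        if not memory.reports[nid] and nid in lwbs_ids:
            memory.reports[nid] = True
    return memory


def lwbs_decision(wait: float,
                  effective_tol: float,
                  n_delayed: int,
                  n_normal: int,
                  ever_had_neighbor: bool,
                  extension_deadline: Optional[float],
                  now: float) -> Decision:
    """Leave / extend / stay decision for a waiting patient.

    Before the adjusted tolerance is reached the patient stays.  At or
    past it: a patient who never had a neighbour leaves immediately; one
    whose delayed reports are at least as many as the normal ones leaves
    (ties resolve to leaving); otherwise a single extension is granted and
    the patient leaves once the extension deadline passes unserved.
    """
    if math.isinf(effective_tol):
        return "stay"
    if wait < effective_tol:
        return "stay"
    if not ever_had_neighbor:
        return "leave"
    if n_delayed >= n_normal:
        return "leave"
    if extension_deadline is None:
        return "extend"
    if now >= extension_deadline:
        return "leave"
    return "stay"
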