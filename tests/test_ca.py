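"""Cellular-automaton abandonment model: neighborhoods, tolerance mixture,
crowding modulation, and the leave/extend decision rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import edcasim as e
from edcasim.ca import ReportMemory, SeatGrid, grid_shape
from edcasim.config import CAParams
from edcasim.metrics import run_once
from edcasim.fixtures import small_test_config


# -- independent oracles ----------------------------------------------------

def brute_force_neighbors(rows, cols, seat, scheme, r):
    """Distance enumeration over every seat of the grid."""
    r0, c0 = seat
    out = set()
    for x in range(rows):
        for y in range(cols):
            if (x, y) == seat:
                continue
            if scheme == "moore":
                d = max(abs(x - r0), abs(y - c0))
            else:
                d = abs(x - r0) + abs(y - c0)
            if d <= r:
                out.add((x, y))
    return out


def decision_oracle(wait, tol, nd, nn, ever, deadline, now):
    """Exhaustively coded restatement of the abandonment rule."""
    if math.isinf(tol) or wait < tol:
        return "stay"
    if not ever:
        return "leave"
    if nd >= nn:
        return "leave"
    if deadline is None:
        return "extend"
    return "leave" if now >= deadline else "stay"


# -- neighborhoods ----------------------------------------------------------

class TestNeighbors:
    @pytest.mark.parametrize("scheme", ["moore", "neumann"])
    @pytest.mark.parametrize("r", [0, 1, 2, 3])
    def test_matches_distance_enumeration_everywhere(self, scheme, r):
        grid = SeatGrid(6, 5)
        for row in range(6):
            for col in range(5):
                got = set(e.neighbors(grid, (row, col), scheme, r))
                assert got == brute_force_neighbors(6, 5, (row, col), scheme, r)

    def test_interior_counts(self):
        # four-seat diamond; (2r+1)^2 - 1 square
        grid = SeatGrid(6, 5)
        assert len(e.neighbors(grid, (2, 2), "neumann", 1)) == 4
        assert len(e.neighbors(grid, (2, 2), "moore", 1)) == 8
        assert len(e.neighbors(grid, (2, 2), "moore", 2)) == 24

    def test_corner_clipping(self):
        grid = SeatGrid(6, 5)
        assert len(e.neighbors(grid, (0, 0), "neumann", 1)) == 2
        assert len(e.neighbors(grid, (0, 0), "moore", 1)) == 3

    def test_out_of_bounds_seat_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            e.neighbors(SeatGrid(6, 5), (6, 0), "moore", 1)

    def test_grid_shape_near_square(self):
        assert grid_shape(30) == (6, 5)
        assert grid_shape(40) == (8, 5)


# -- tolerance mixture ------------------------------------------------------

class TestToleranceSampler:
    def test_bin_frequencies(self):
        rng = np.random.default_rng(42)
        ca = CAParams()
        draws = np.array([e.sample_tolerance(rng, ca) for _ in range(100_000)])
        finite = draws[np.isfinite(draws)]
        assert np.mean(draws <= 120) == pytest.approx(0.51, abs=0.01)
        assert np.mean((draws > 120) & np.isfinite(draws)) == pytest.approx(0.17, abs=0.01)
        assert np.mean(np.isinf(draws)) == pytest.approx(0.32, abs=0.01)
        assert finite.max() <= 480 and finite.min() > 0

    def test_degenerate_short_bin(self):
        rng = np.random.default_rng(0)
        ca = CAParams(tol_probs=(1.0, 0.0, 0.0))
        draws = [e.sample_tolerance(rng, ca) for _ in range(500)]
        assert all(0 < d <= 120 for d in draws)


# -- crowding modulation and extension --------------------------------------

class TestModulation:
    def test_uncrowded_boosts_by_30pct(self):
        assert e.effective_tolerance(100.0, 0.0, CAParams()) == pytest.approx(130.0)

    def test_saturated_crowding_cuts_by_30pct(self):
        assert e.effective_tolerance(100.0, 200.0, CAParams()) == pytest.approx(70.0)

    def test_infinite_stays_infinite(self):
        assert math.isinf(e.effective_tolerance(math.inf, 150.0, CAParams()))

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            e.effective_tolerance(100.0, 250.0, CAParams())

    @given(st.floats(0, 200), st.floats(0, 200))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_decreasing_in_crowding(self, n1, n2):
        ca = CAParams()
        lo, hi = sorted((n1, n2))
        assert (e.effective_tolerance(100.0, lo, ca)
                >= e.effective_tolerance(100.0, hi, ca))

    @pytest.mark.parametrize("tol,expected", [(120.0, 12.0), (0.0, 0.0), (480.0, 48.0)])
    def test_extension_is_tenth_of_tolerance(self, tol, expected):
        assert e.extension_time(tol, CAParams()) == pytest.approx(expected)

    def test_extension_undefined_for_infinite(self):
        with pytest.raises(ValueError):
            e.extension_time(math.inf, CAParams())


# -- decision rule ----------------------------------------------------------

class TestDecisionRule:
    def test_exhaustive_truth_table(self):
        """Every reachable decision tuple agrees with the coded oracle,
        including the no-neighbor case and the tie resolving to leave."""
        now = 200.0
        for tol in (60.0, 120.0, math.inf):
            for wait in (0.0, 59.0, 60.0, 120.0, 180.0):
                for nd in range(3):
                    for nn in range(3):
                        for ever in (False, True):
                            if not ever and (nd or nn):
                                continue  # unreachable by invariant
                            for deadline in (None, 190.0, 200.0, 210.0):
                                got = e.lwbs_decision(wait, tol, nd, nn, ever,
                                                      deadline, now)
                                want = decision_oracle(wait, tol, nd, nn, ever,
                                                       deadline, now)
                                assert got == want, (wait, tol, nd, nn, ever, deadline)

    def test_solo_patient_leaves_exactly_at_tolerance(self):
        assert e.lwbs_decision(120.0, 120.0, 0, 0, False, None, 0) == "leave"
        assert e.lwbs_decision(119.0, 120.0, 0, 0, False, None, 0) == "stay"

    def test_tie_is_inclusive_leave(self):
        assert e.lwbs_decision(120.0, 120.0, 1, 1, True, None, 0) == "leave"

    def test_normal_majority_grants_single_extension(self):
        assert e.lwbs_decision(120.0, 120.0, 0, 2, True, None, 100.0) == "extend"
        # past the granted deadline the patient walks
        assert e.lwbs_decision(132.0, 120.0, 0, 2, True, 132.0, 132.0) == "leave"
        assert e.lwbs_decision(125.0, 120.0, 0, 2, True, 132.0, 125.0) == "stay"


# -- report memory ----------------------------------------------------------

class TestCollectReports:
    def test_no_neighbors_leaves_memory_empty(self):
        mem = e.collect_reports(ReportMemory(), [], {}, {})
        assert (mem.n_delayed, mem.n_normal, mem.ever_had_neighbor) == (0, 0, False)

    def test_overdue_neighbor_classified_delayed(self):
        mem = e.collect_reports(ReportMemory(), [7], {7: 90.0}, {7: 60.0})
        assert mem.n_delayed == 1 and mem.n_normal == 0

    def test_reports_deduplicated_per_neighbor(self):
        mem = ReportMemory()
        for _ in range(5):
            e.collect_reports(mem, [7], {7: 10.0}, {7: 60.0})
        assert mem.n_normal == 1 and mem.n_delayed == 0

    def test_walkout_flips_memorised_report_via_blackboard(self):
        mem = e.collect_reports(ReportMemory(), [7], {7: 10.0}, {7: 60.0})
        assert mem.n_normal == 1
        e.collect_reports(mem, [], {}, {}, lwbs_ids={7})
        assert mem.n_delayed == 1 and mem.n_normal == 0

    def test_delayed_report_is_sticky(self):
        mem = e.collect_reports(ReportMemory(), [7], {7: 90.0}, {7: 60.0})
        e.collect_reports(mem, [7], {7: 91.0}, {7: math.inf})
        assert mem.n_delayed == 1


# -- grid -------------------------------------------------------------------

class TestSeatGrid:
    def test_seating_and_release(self):
        grid = SeatGrid.for_capacity(30)
        rng = np.random.default_rng(0)
        seat = grid.seat_patient(1, rng)
        assert seat is not None and grid.occupancy[seat] == 1
        assert grid.n_free == 29
        grid.release(1)
        assert grid.n_free == 30 and grid.seat_of(1) is None

    def test_full_grid_signals_overflow(self):
        grid = SeatGrid(2, 2)
        rng = np.random.default_rng(0)
        for pid in range(4):
            assert grid.seat_patient(pid, rng) is not None
        assert grid.seat_patient(99, rng) is None

    def test_seeded_seat_sequence_reproducible(self):
        seats1 = [SeatGrid(6, 5).seat_patient(0, np.random.default_rng(5))]
        seats2 = [SeatGrid(6, 5).seat_patient(0, np.random.default_rng(5))]
        assert seats1 == seats2


# -- system-level CA properties ---------------------------------------------

class TestSystemProperties:
    def test_all_infinite_tolerance_means_no_walkouts(self):
        cfg = small_test_config(
            ca_params=CAParams(tol_probs=(0.0, 0.0, 1.0)))
        rec, _ = run_once(cfg, 11)
        assert rec.n_lwbs == 0

    def test_stochastically_larger_tolerance_does_not_raise_lwbs(self):
        """Doubling the short-tolerance bin's upper bound (stochastically
        larger waits accepted) should not increase expected walkouts on a
        common-random-number arrival stream."""
        base = small_test_config(hourly_rates=(8.0,) * 24, run_length=1440,
                                 warm_up=240)
        patient_cfg = base.replace(
            ca_params=CAParams(tol_short_range=(0.0, 240.0)))
        n_base = np.mean([run_once(base, s)[0].n_lwbs for s in range(8)])
        n_patient = np.mean([run_once(patient_cfg, s)[0].n_lwbs for s in range(8)])
        assert n_patient <= n_base

    def test_abandonment_relieves_congestion(self, hrtn_config):
        """Mean LOS with the abandonment model enabled is below the
        no-abandonment counterfactual (leavers free capacity), paired over
        common random numbers."""
        diffs = []
        for i in range(10):
            seed = int(np.random.SeedSequence((7, i)).generate_state(1)[0] % 2**31)
            on, _ = run_once(hrtn_config, seed)
            off, _ = run_once(hrtn_config.replace(lwbs_enabled=False), seed)
            diffs.append(off.overall_los - on.overall_los)
        assert np.mean(diffs) > 0
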