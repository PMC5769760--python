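# Methods

## Model overview

`edcasim` is a time-stepped (1-minute tick) agent-based model of an
emergency department. Agents are patients and staff (receptionists,
triage nurses, section doctors, nurse technicians); they interact
through three message types (one-to-one, one-to-n, one-to-location,
including timed location postings) and through a shared blackboard
holding the waiting-room count, the history of walkouts, queue lengths
and the current overcrowding index. The blackboard is refreshed at the
end of every tick, so all agents act on the same global state at the
next tick.

Within a tick, events are processed in a fixed order — departures,
service starts, triage, admissions, arrivals, abandonment decisions,
blackboard refresh — which, together with named random substreams,
makes a run bit-reproducible from its seed. Two scenarios run with the
same root seed share arrival, acuity and tolerance draws (common random
numbers), sharpening policy contrasts.

## Patient pathway and resources

* **Arrivals.** Non-homogeneous Poisson process via thinning against the
  peak hourly rate; the 24-value profile repeats daily. Arrival mode is
  walk-in / ambulance / police custody; police-custody patients skip
  admission. Ambulances register like walk-ins — the flow distinguishes
  only police custody.
* **Admission and triage** are single-queue multi-server stations (FIFO)
  with lognormal service times. Triage assigns the MTS category and the
  treatment section (sampled from per-category section weights).
* **Waiting room.** Patients take a uniformly random free seat on the
  lattice (6×5 at the default capacity 30). If the room is full they
  stand — still waiting, counted in the crowding index, but with no
  lattice neighbours — and take the first freed seat in arrival order.
* **Treatment.** Starting service requires a free bed *and* a free
  doctor in the section; patients are called by (acuity, arrival time,
  id). The doctor is occupied for a fixed fraction
  (`doctor_time_fraction`, default 0.25) of the service duration — the
  consultation — while the bed is held for all of it. This keeps
  physician-hours realistic for multi-hour treatment episodes.
  With probability `diagnostics_prob` a diagnostics delay (pure delay;
  labs/imaging are not capacitated) is inserted after the consultation;
  the patient keeps the bed and resumes in the same section.
  Disposition is a per-section Bernoulli draw
  (discharge vs hospitalization).
* **Fast track** (policy 2 only): MTS 4–5 patients enter a dedicated
  FIFO queue after triage, served by a dedicated doctor with a short
  consultation distribution and no bed requirement.

## The abandonment (LWBS) model

Each patient draws a tolerance time from the three-bin mixture
(0.51 uniform on (0, 120], 0.17 uniform on (120, 480], 0.32 infinite;
within-bin uniformity is our choice — only the bin masses are given in
the source literature). The patient's *perceived wait* runs from ED
arrival: queueing at admission and triage is part of the experience
that exhausts patience, not just the seated wait. Abandonment
decisions, however, are evaluated only while the patient is in the
waiting room (patients mid-registration or mid-triage do not walk out;
a patient whose patience expired earlier leaves at the first decision
tick after being seated).

The effective tolerance is the nominal draw times a linear function of
the overcrowding index: ×1.30 at index 0 falling to ×0.70 at 200
(`crowding_boost`/`crowding_floor`; only the +30% end and the
decreasing direction are anchored by the source, the floor is symmetric
by choice). By default the modulation is **continuous** — re-evaluated
every tick from the current index — so patience genuinely tracks how
crowded the department looks; `ca_params.modulation = "at_seating"`
freezes it at seating time instead.

Neighbour memory: one report per distinct neighbour, re-examined every
tick. A neighbour is remembered as *delayed* once it is observed
waiting past its own effective tolerance or once it appears in the
blackboard's walkout history (reports are sticky). The decision rule at
or past the effective tolerance: no neighbour ever → leave; delayed ≥
normal → leave (the rule is inclusive, so ties leave); otherwise a
single extension of `0.1 × tolerance` minutes, after which an unserved
patient leaves. Decisions are taken sequentially in patient-arrival
order within a tick; a walkout is visible to later deciders from the
next tick.

## Overcrowding index

A linear score clamped to [0, 200] with the six standard verbal
categories (cutpoints 20/60/100/140/180; boundaries belong to the upper
category). Predictors and default weights:

| predictor | default weight | note |
|---|---|---|
| census / ED beds | 85.8 | published occupancy term |
| boarders / hospital beds | 600 | present but 0 here (no boarding model) |
| waiting count / waiting capacity | 200 | replaces the ventilator term |
| longest boarding wait (h) | 0.93 | 0 here |
| last bed wait (min) | 0.094 | 5.64/h |
| intercept | −20 | |

The waiting-room term uses the *fill ratio* rather than the raw count
so that the index responds to how full the room looks relative to its
size — the mechanism by which a bigger waiting room (policy 3) can
relieve perceived crowding. With the default weight, a half-full room
contributes +100. All weights, the clamp and the cutpoints are
config-exposed.

## The bundled scenario (synthetic-data generator)

`default_hrtn_config()` emulates a public tertiary ED receiving 162
patients/day on average: a two-peak day/evening rate profile summing to
exactly 162, six sections, one triage nurse, two receptionists, a
30-seat waiting room. The acuity mix (3/15/35/35/12% for MTS 1–5),
mode mix (72/25/3%), per-category section weights, staffing and
lognormal service-time parameters are the implementer's choices,
iterated with `scripts/calibrate_fixture.py` until two published
targets hold simultaneously under the 3-day / 2-day-warm-up protocol:

* each section's mean simulated LOS falls inside its reference 95%
  confidence interval (pediatrics ≈ 305, yellow zone ≈ 390,
  orthopedics ≈ 191, surgical ≈ 422, clinical ≈ 482, suturing ≈ 192
  minutes over 30 replications), and
* the baseline LWBS rate lies in the reference 8.64–10.12% band
  (≈ 9.3–9.6% across root seeds).

What the generator does **not** emulate: day-of-week or seasonal
structure, patient covariates (age, insurance, arrival acuity drift),
boarding of admitted patients, capacitated diagnostics, staff shifts
and breaks, or balking at the door. Passing tests therefore show that
the mechanism behaves correctly under these stylised conditions, not
that it forecasts any particular real department.

## Run protocol and metrics

Runs last 4320 min (3 days); the first 2880 min are warm-up, because
the empty-department start biases every statistic. Only patients
arriving after warm-up contribute: LWBS% = walkouts/arrivals, LOS =
disposition − arrival for treated patients (patients still in the
system at the end count as arrivals but contribute no LOS — the same
right-censoring any terminating-run protocol has, and the calibration
targets were measured under the identical protocol). Weekly throughput
scales the post-warm-up discharge count to 7 days. Daily LWBS rates
partition post-warm-up time into 1440-min days.

Replication *i* of root seed *s* uses the seed derived from `(s, i)`,
so scenario comparisons are paired. The policy regression pools daily
LWBS rates across scenarios — intercept plus one indicator per policy,
baseline as reference — over 30 replications of an extended 12-day run
(2 warm-up + 10 observed days, 300 day-observations per scenario);
the longer panel stabilises day-level rates, which are noisy at ~162
arrivals/day. OLS is delegated to statsmodels behind the module
surface and cross-checked against an explicit pseudoinverse solve in
the tests.

## Numerical and design choices

* 1-minute ticks; durations are continuous draws taking effect at the
  next whole-minute boundary (sub-minute idle slivers are absorbed).
* Lognormal service times (positive, right-skewed), parameterised by
  natural-scale mean/SD.
* Tie-breaks: service calls by (MTS, arrival time, id); staff taken
  from pools lowest-id first; degenerate Welch tests (both samples
  constant, equal means) report p = 1.
* Extra model parameters beyond the obvious ones: `admission_time`
  (registration needs a duration for receptionists to matter),
  `fast_track_time` (the fast-track consultation), and
  `doctor_time_fraction` (see Treatment above).
* `improvement_pct(base, x) = 100·(base − x)/base` is asymmetric by
  construction: reversing the comparison rescales to the other
  baseline.

## Known limitations

* **Policy 3 is ~null here.** Enlarging the waiting room leaves LOS
  unchanged (as expected) and moves LWBS by ≈ 0 ± 0.3 percentage
  points. Structural reason: most walkouts happen during saturation
  episodes in which the number of patients treated is capacity-limited,
  so a patience boost (the lower crowding index a bigger room yields)
  mostly reshuffles *who* abandons rather than how many; unlike the
  other three policies, p3 adds no capacity. Its indicator is
  accordingly not significant in the policy regression, while p1, p2
  and p4 are (p < 10⁻⁵ on the pooled panel).
* The fast track's LOS improvement is large (≈ 40%) because MTS 4–5
  treatment is modelled as a short consultation; the LWBS ordering, not
  the LOS magnitude, is the robust output.
* No boarding model: two crowding-index predictors are structurally 0.
* Seat choice is uniformly random; real patients cluster, which would
  strengthen neighbour effects.
* Abandonment is modelled only in the waiting room, not in pre-triage
  queues, although expired patience is acted on immediately at seating.
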