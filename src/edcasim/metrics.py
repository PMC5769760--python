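"""Warm-up-aware metric collection, replications, and output analysis.

A run's event log is reduced to a :class:`MetricsRecord`: per-section and
overall mean length of stay (LOS, arrival to disposition), the LWBS rate
(percent of arrivals that left without being seen), a weekly-equivalent
throughput, and daily LWBS rates.  Only patients arriving after the
warm-up period contribute — the initially empty department would
otherwise bias every statistic downward.

Scenario comparison follows standard simulation output analysis:
independent replications, percentage improvements against a baseline,
and an ordinary least squares regression of the daily LWBS rate on
policy indicator variables to test each policy's significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import SimConfig
from .core import Stage
from .engine import Engine, EngineResult

__all__ = [
    "MetricsRecord", "OlsResult", "collect_metrics", "replicate",
    "improvement_pct", "average_improvements", "ols_fit",
    "ci_check", "welch_ttest", "policy_report", "event_log_frame",
]

DAY = 1440.0


@dataclass
class MetricsRecord:
    """Per-replication outputs over post-warm-up arrivals."""

    section_los: dict[str, float]
    overall_los: float
    lwbs_rate: float                 # percent
    weekly_throughput: float         # discharged-equivalent per 7 days
    daily_lwbs_rates: list[float]
    n_arrivals: int
    n_lwbs: int
    replication_seed: int = 0
    valid: bool = True               # False when no post-warm-up arrivals


def event_log_frame(event_log: Sequence[dict]) -> pd.DataFrame:
    """Event log as a flat DataFrame (detail dict expanded)."""
    rows = []
    for e in event_log:
        row = {k: e[k] for k in ("time", "patient_id", "event", "stage")}
        row.update(e.get("detail") or {})
        rows.append(row)
    return pd.DataFrame(rows)


def collect_metrics(event_log: Sequence[dict], config: SimConfig,
                    replication_seed: int = 0) -> MetricsRecord:
    """Reduce an event log to a :class:`MetricsRecord`.

    LOS = disposition time − arrival time, per patient; the LWBS rate is
    100 × (patients leaving unseen) / arrivals.  Both are restricted to
    patients arriving after ``config.warm_up``; patients still in the
    system at the end of the run count in the arrival denominator but
    contribute no LOS.
    """
    arrivals: dict[int, float] = {}
    section: dict[int, str] = {}
    dispo: dict[int, float] = {}
    lwbs: dict[int, float] = {}
    for e in event_log:
        pid, ev = e["patient_id"], e["event"]
        if ev == "arrival":
            arrivals[pid] = e["time"]
        elif ev == "triage":
            section[pid] = e["detail"]["section"]
        elif ev in (Stage.DISCHARGED, Stage.HOSPITALIZED):
            dispo[pid] = e["time"]
            section.setdefault(pid, e["detail"].get("section", ""))
        elif ev == "lwbs":
            lwbs[pid] = e["time"]

    post = {pid: t for pid, t in arrivals.items() if t >= config.warm_up}
    if not post:
        return MetricsRecord(section_los={}, overall_los=math.nan,
                             lwbs_rate=math.nan, weekly_throughput=math.nan,
                             daily_lwbs_rates=[], n_arrivals=0, n_lwbs=0,
                             replication_seed=replication_seed, valid=False)

    los_by_sec: dict[str, list[float]] = {s.name: [] for s in config.sections}
    all_los: list[float] = []
    n_lwbs = 0
    n_discharged = 0
    for pid, t0 in post.items():
        if pid in lwbs:
            n_lwbs += 1
        elif pid in dispo:
            los = dispo[pid] - t0
            all_los.append(los)
            sec = section.get(pid)
            if sec in los_by_sec:
                los_by_sec[sec].append(los)
            n_discharged += 1

    window = config.run_length - config.warm_up
    n_days = max(1, int(round(window / DAY)))
    daily = []
    for k in range(n_days):
        lo = config.warm_up + k * DAY
        hi = lo + DAY
        day_arr = [pid for pid, t in post.items() if lo <= t < hi]
        if day_arr:
            daily.append(100.0 * sum(1 for pid in day_arr if pid in lwbs)
                         / len(day_arr))

    return MetricsRecord(
        section_los={name: float(np.mean(v)) if v else math.nan
                     for name, v in los_by_sec.items()},
        overall_los=float(np.mean(all_los)) if all_los else math.nan,
        lwbs_rate=100.0 * n_lwbs / len(post),
        weekly_throughput=n_discharged * (7 * DAY) / window,
        daily_lwbs_rates=daily,
        n_arrivals=len(post), n_lwbs=n_lwbs,
        replication_seed=replication_seed)


def run_once(config: SimConfig, seed: int) -> tuple[MetricsRecord, EngineResult]:
    """One replication: run the engine and reduce the log."""
    result = Engine(config, seed=seed).run()
    return collect_metrics(result.event_log, config, replication_seed=seed), result


def replicate(config: SimConfig, n: Optional[int] = None,
              seed: Optional[int] = None) -> list[MetricsRecord]:
    """``n`` independent replications on derived seed substreams.

    Replication ``i`` always uses the seed derived from ``(seed, i)``, so
    two scenarios replicated with the same root seed share arrival
    streams (common random numbers).
    """
    n = config.replications if n is None else n
    seed = config.seed if seed is None else seed
    if n < 1:
        raise ValueError("need at least one replication")
    out = []
    for i in range(n):
        rep_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
        rec, _ = run_once(config, rep_seed)
        out.append(rec)
    return out


def improvement_pct(baseline_value: float, scenario_value: float) -> float:
    """Percentage improvement of a scenario over the baseline.

    Positive when the scenario value is lower (shorter stays, fewer
    walkouts); negative when the scenario made things worse.
    """
    if baseline_value <= 0:
        raise ValueError("baseline value must be > 0")
    return 100.0 * (baseline_value - scenario_value) / baseline_value


def average_improvements(values: Sequence[float]) -> float:
    """Arithmetic mean of improvement percentages."""
    if len(values) == 0:
        raise ValueError("need at least one improvement value")
    return float(np.mean(values))


@dataclass
class OlsResult:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    n: int
    rsquared: float
    names: list[str] = field(default_factory=list)


def ols_fit(y, X, names: Optional[Sequence[str]] = None) -> OlsResult:
    """Ordinary least squares of ``y`` on design ``X`` (no implicit
    intercept); two-sided p-values from the t distribution on n−k df.

    Rejects rank-deficient designs outright rather than silently dropping
    columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != len(X):
        raise ValueError("y and X must have the same number of rows")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient "
                         "(duplicated or collinear columns)")
    fit = sm.OLS(y, X).fit()
    return OlsResult(params=np.asarray(fit.params),
                     bse=np.asarray(fit.bse),
                     tvalues=np.asarray(fit.tvalues),
                     pvalues=np.asarray(fit.pvalues),
                     n=int(fit.nobs), rsquared=float(fit.rsquared),
                     names=list(names) if names else
                     [f"x{i}" for i in range(X.shape[1])])


def policy_ols(daily_rates_by_scenario: dict[str, Sequence[float]],
               baseline_key: str = "baseline") -> OlsResult:
    """Pooled regression of daily LWBS rates on policy indicators.

    One row per post-warm-up day per replication; intercept plus one
    indicator column per non-baseline scenario, baseline as the reference
    level.  A negative significant coefficient means the policy lowers
    the daily LWBS rate.
    """
    scenarios = [baseline_key] + sorted(k for k in daily_rates_by_scenario
                                        if k != baseline_key)
    y, rows = [], []
    k = len(scenarios) - 1
    for si, name in enumerate(scenarios):
        for v in daily_rates_by_scenario[name]:
            y.append(v)
            ind = [0.0] * k
            if si > 0:
                ind[si - 1] = 1.0
            rows.append([1.0] + ind)
    return ols_fit(np.array(y), np.array(rows),
                   names=["intercept"] + scenarios[1:])


def ci_check(sample_mean: float, interval: tuple[float, float]) -> bool:
    """Is the mean inside the closed interval?"""
    lo, hi = interval
    if not lo < hi:
        raise ValueError("interval must satisfy lo < hi")
    return lo <= sample_mean <= hi


def welch_ttest(sample_a, sample_b, alpha: float = 0.05
                ) -> tuple[float, float, bool]:
    """Welch two-sample t-test (Satterthwaite df): (t, p, reject).

    Degenerate case — both samples constant with equal means — returns
    p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), bool(p < alpha)


def policy_report(baseline_recs: Sequence[MetricsRecord],
                  per_policy_recs: dict[str, Sequence[MetricsRecord]]
                  ) -> pd.DataFrame:
    """Scenario table: mean LOS, mean LWBS rate, and improvements over
    baseline, one row per scenario (baseline first)."""
    if not baseline_recs:
        raise ValueError("need at least one baseline replication")

    def mean_of(recs, attr):
        vals = [getattr(r, attr) for r in recs if r.valid]
        return float(np.nanmean(vals)) if vals else math.nan

    base_los = mean_of(baseline_recs, "overall_los")
    base_lwbs = mean_of(baseline_recs, "lwbs_rate")
    rows = [{"scenario": "baseline", "los_min": base_los,
             "lwbs_pct": base_lwbs, "improvement_los_pct": 0.0,
             "improvement_lwbs_pct": 0.0,
             "n_replications": len(baseline_recs)}]
    for name, recs in per_policy_recs.items():
        los = mean_of(recs, "overall_los")
        lwbs = mean_of(recs, "lwbs_rate")
        rows.append({"scenario": name, "los_min": los, "lwbs_pct": lwbs,
                     "improvement_los_pct": improvement_pct(base_los, los),
                     "improvement_lwbs_pct": improvement_pct(base_lwbs, lwbs),
                     "n_replications": len(recs)})
    return pd.DataFrame(rows)
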