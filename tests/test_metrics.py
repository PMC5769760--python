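"""Metric collection, replication machinery, and output statistics."""

import math

import numpy as np
import pytest

import edcasim as e
from edcasim.metrics import policy_ols, run_once
from edcasim.fixtures import small_test_config


def ev(time, pid, event, stage="", **detail):
    return {"time": time, "patient_id": pid, "event": event,
            "stage": stage, "detail": detail}


def synthetic_log(config, n_arrivals=20, n_lwbs=2, los=100.0):
    """Hand-built event log: arrivals just after warm-up, a fixed LOS for
    the treated, and the first ``n_lwbs`` patients walking out."""
    t0 = config.warm_up + 1
    log = []
    for pid in range(n_arrivals):
        log.append(ev(t0 + pid, pid, "arrival", mode="self"))
        log.append(ev(t0 + pid + 5, pid, "triage", mts=3, section="suturing"))
        if pid < n_lwbs:
            log.append(ev(t0 + pid + 60, pid, "lwbs", minutes_waited=60.0))
        else:
            log.append(ev(t0 + pid + los, pid, "discharged",
                          section="suturing"))
    return log


class TestCollectMetrics:
    def test_lwbs_rate_from_counts(self, small_config):
        rec = e.collect_metrics(synthetic_log(small_config), small_config)
        assert rec.lwbs_rate == pytest.approx(10.0)
        assert rec.n_arrivals == 20 and rec.n_lwbs == 2

    def test_los_is_disposition_minus_arrival(self, small_config):
        rec = e.collect_metrics(synthetic_log(small_config, los=123.0),
                                small_config)
        assert rec.overall_los == pytest.approx(123.0)
        assert rec.section_los["suturing"] == pytest.approx(123.0)

    def test_pre_warm_up_arrivals_excluded(self, small_config):
        log = synthetic_log(small_config)
        log.append(ev(small_config.warm_up - 10, 999, "arrival", mode="self"))
        log.append(ev(small_config.warm_up + 50, 999, "lwbs",
                      minutes_waited=60.0))
        rec = e.collect_metrics(log, small_config)
        assert rec.n_arrivals == 20 and rec.n_lwbs == 2

    def test_empty_log_flagged_invalid(self, small_config):
        rec = e.collect_metrics([], small_config)
        assert not rec.valid and math.isnan(rec.lwbs_rate)

    def test_zero_warm_up_admits_more_patients(self, hrtn_config):
        _, res = run_once(hrtn_config, 5)
        full = e.collect_metrics(res.event_log, hrtn_config.replace(warm_up=0))
        part = e.collect_metrics(res.event_log, hrtn_config)
        assert full.n_arrivals > part.n_arrivals


class TestReplicate:
    def test_single_replication_matches_direct_run(self, small_config):
        recs = e.replicate(small_config, 1, seed=6)
        direct, _ = run_once(small_config, recs[0].replication_seed)
        assert recs[0] == direct

    def test_same_seed_twice_identical(self, small_config):
        a = e.replicate(small_config, 3, seed=2)
        b = e.replicate(small_config, 3, seed=2)
        assert a == b

    def test_lwbs_toggle_gives_paired_lists(self, small_config):
        on = e.replicate(small_config, 2, seed=4)
        off = e.replicate(small_config.replace(lwbs_enabled=False), 2, seed=4)
        assert [r.replication_seed for r in on] == [r.replication_seed for r in off]
        assert all(r.n_lwbs == 0 for r in off)


class TestImprovementArithmetic:
    # printed reference values: (baseline, scenario) -> improvement %
    LWBS_PAIRS = [(10.53, 5.01, 52.42), (10.53, 4.12, 60.87),
                  (10.53, 9.10, 13.58), (10.53, 6.14, 41.69)]
    LOS_PAIRS = [(285.0, 270.0, 5.26), (285.0, 251.0, 11.93),
                 (285.0, 289.0, -1.40), (285.0, 261.0, 8.42)]

    @pytest.mark.parametrize("base,scen,expected", LWBS_PAIRS + LOS_PAIRS)
    def test_reference_pairs(self, base, scen, expected):
        assert e.improvement_pct(base, scen) == pytest.approx(expected, abs=0.01)

    def test_no_change_is_zero(self):
        assert e.improvement_pct(7.0, 7.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            e.improvement_pct(0.0, 1.0)

    def test_column_averages(self):
        assert e.average_improvements([52.42, 60.87, 13.58, 41.69]) == \
            pytest.approx(42.14, abs=0.005)
        assert e.average_improvements([5.26, 11.92, -1.40, 8.42]) == \
            pytest.approx(6.05, abs=0.005)

    def test_single_value_average(self):
        assert e.average_improvements([7.0]) == 7.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            e.average_improvements([])

    def test_documented_asymmetry(self):
        # improvement is relative to its own baseline, so reversing the
        # direction does not negate it exactly
        fwd = e.improvement_pct(10.0, 8.0)
        rev = e.improvement_pct(8.0, 10.0)
        assert fwd == pytest.approx(20.0) and rev == pytest.approx(-25.0)


def pinv_ols_oracle(y, X):
    """Independent least-squares via explicit pseudoinverse + t CDF."""
    from scipy import stats
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p


class TestOls:
    def test_exact_linear_data(self):
        x = np.arange(10.0)
        y = 2.0 + 3.0 * x
        X = np.column_stack([np.ones(10), x])
        fit = e.ols_fit(y, X)
        assert fit.params == pytest.approx([2.0, 3.0], abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_pseudoinverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=20)
        fit = e.ols_fit(y, X)
        beta, se, t, p = pinv_ols_oracle(y, X)
        assert fit.params == pytest.approx(beta, abs=1e-8)
        assert fit.bse == pytest.approx(se, abs=1e-8)
        assert fit.tvalues == pytest.approx(t, abs=1e-8)
        assert fit.pvalues == pytest.approx(p, abs=1e-8)

    def test_duplicated_column_rejected(self):
        x = np.arange(12.0)
        X = np.column_stack([np.ones(12), x, x])
        with pytest.raises(ValueError, match="rank deficient"):
            e.ols_fit(x, X)

    def test_policy_design_layout(self):
        daily = {"baseline": [10.0, 11.0], "p1": [8.0, 9.0], "p2": [7.0, 7.5]}
        fit = policy_ols(daily)
        assert fit.names == ["intercept", "p1", "p2"]
        assert fit.n == 6
        assert fit.params[0] == pytest.approx(10.5)
        assert fit.params[1] == pytest.approx(8.5 - 10.5)


class TestValidationStats:
    def test_ci_check_reference_rows(self):
        assert e.ci_check(189.35, (177.32, 199.47))
        assert not e.ci_check(280.25, (286.65, 342.54))

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            e.ci_check(1.0, (5.0, 5.0))

    def test_welch_identical_samples_never_reject(self):
        t, p, reject = e.welch_ttest([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0 and not reject

    def test_welch_detects_separated_means(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(2, 1, 40)
        t, p, reject = e.welch_ttest(a, b)
        assert reject and p < 1e-6

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            e.welch_ttest([1.0], [2.0, 3.0])


class TestPolicyReport:
    def _rec(self, los, lwbs, seed=0):
        return e.MetricsRecord(section_los={}, overall_los=los, lwbs_rate=lwbs,
                               weekly_throughput=0.0, daily_lwbs_rates=[lwbs],
                               n_arrivals=100, n_lwbs=int(lwbs),
                               replication_seed=seed)

    def test_baseline_only_improvements_zero(self):
        df = e.policy_report([self._rec(280, 10.0)], {})
        assert df.improvement_los_pct.tolist() == [0.0]

    def test_two_scenarios_match_hand_computation(self):
        base = [self._rec(280, 10.0), self._rec(290, 11.0)]
        pol = {"p4": [self._rec(260, 8.0), self._rec(266, 9.0)]}
        df = e.policy_report(base, pol).set_index("scenario")
        assert df.loc["p4", "los_min"] == pytest.approx(263.0)
        assert df.loc["p4", "improvement_los_pct"] == pytest.approx(
            100 * (285 - 263) / 285)
        assert df.loc["p4", "improvement_lwbs_pct"] == pytest.approx(
            100 * (10.5 - 8.5) / 10.5)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            e.policy_report([], {})
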