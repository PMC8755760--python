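import numpy as np
import pandas as pd
import pytest

from stopthink.behavior import (
    cohen_d_from_t,
    estimate_ssrt_integration,
    go_rt_run_slope,
    group_one_sample_test,
    one_tailed_p_from_t,
    score_sif,
)
from stopthink.synth import RaceModelParams, make_population, simulate_stop_signal


class TestSSRTIntegration:
    def test_hand_worked_example(self, toy_stop_trials):
        # p(respond|stop)=0.5, rank 5 of ten go RTs -> 600; mean SSD 275
        s = estimate_ssrt_integration(toy_stop_trials)
        assert s.p_respond_stop == 0.5
        assert s.mean_ssd_ms == 275.0
        assert s.ssrt_ms == 325.0
        assert s.p_go_omission == 0.0
        assert s.race_assumption_ok  # failed-stop RTs 500/520 < mean go 625

    def test_all_stops_responded_uses_max_go_rt(self, toy_stop_trials):
        t = toy_stop_trials.copy()
        stop = t["trial_type"] == "stop"
        t.loc[stop, "rt_ms"] = 500.0
        t.loc[stop, "response"] = "press"
        t.loc[stop, "correct"] = False
        s = estimate_ssrt_integration(t)
        assert s.p_respond_stop == 1.0
        assert s.ssrt_ms == 850.0 - 275.0

    def test_go_omissions_replaced_by_max_go_rt(self, toy_stop_trials):
        t = toy_stop_trials.copy()
        # omit the slowest go trial; its replacement is the new max (800)
        t.loc[t["rt_ms"] == 850.0, ["rt_ms", "response"]] = [np.nan, "none"]
        s = estimate_ssrt_integration(t)
        assert s.p_go_omission == pytest.approx(0.1)
        assert s.ssrt_ms == 325.0  # rank 5 unchanged

    def test_order_invariance(self, toy_stop_trials):
        shuffled = toy_stop_trials.sample(frac=1, random_state=0)
        assert estimate_ssrt_integration(shuffled).ssrt_ms == 325.0

    def test_larger_mean_ssd_lowers_ssrt(self, toy_stop_trials):
        t = toy_stop_trials.copy()
        t.loc[t["trial_type"] == "stop", "ssd_ms"] += 50.0
        assert estimate_ssrt_integration(t).ssrt_ms == 275.0

    def test_errors(self, toy_stop_trials):
        with pytest.raises(ValueError, match="no stop trials"):
            estimate_ssrt_integration(
                toy_stop_trials[toy_stop_trials["trial_type"] == "go"])
        t = toy_stop_trials.copy()
        stop = t["trial_type"] == "stop"
        t.loc[stop, "rt_ms"] = np.nan
        t.loc[stop, "response"] = "none"
        with pytest.raises(ValueError, match="zero respond rate"):
            estimate_ssrt_integration(t)

    def test_recovers_planted_ssrt_across_seeds(self):
        errs = []
        for seed in range(40):
            pop = make_population(1, -0.5, seed=seed)
            pop.true_mean_ssrt[:] = 280.0
            trials = simulate_stop_signal(pop, n_trials=384, seed=seed)
            errs.append(estimate_ssrt_integration(trials).ssrt_ms - 280.0)
        assert abs(np.mean(errs)) <= 15.0


class TestRunSlope:
    @staticmethod
    def _table(rts_by_run, subject="s1"):
        rows = []
        for run, rts in rts_by_run.items():
            for i, rt in enumerate(rts):
                rows.append((subject, run, i, "go", np.nan, rt, "press", True))
        return pd.DataFrame(rows, columns=["subject", "run", "trial_index",
                                           "trial_type", "ssd_ms", "rt_ms",
                                           "response", "correct"])

    def test_constant_rts_have_zero_slope(self):
        t = self._table({r: [600.0, 600.0] for r in range(1, 9)})
        assert go_rt_run_slope(t)[0] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_input(self):
        t = self._table({r: [600.0 - 3 * r] * 3 for r in range(1, 9)})
        assert go_rt_run_slope(t)[0] == pytest.approx(-3.0, abs=1e-9)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match=">= 2 runs"):
            go_rt_run_slope(self._table({1: [600.0, 610.0]}))

    def test_recovers_planted_group_slope(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(24):
            base = rng.normal(600, 30)
            for run in range(1, 9):
                for i in range(10):
                    rows.append((f"s{s}", run, i, "go", np.nan,
                                 base - 2.5 * run + rng.normal(0, 40),
                                 "press", True))
        t = pd.DataFrame(rows, columns=["subject", "run", "trial_index",
                                        "trial_type", "ssd_ms", "rt_ms",
                                        "response", "correct"])
        slope, test, _ = go_rt_run_slope(t)
        assert slope == pytest.approx(-2.5, abs=1.0)
        assert test.df == 23


class TestSIF:
    @staticmethod
    def _recall(rows):
        return pd.DataFrame(rows, columns=["subject", "pair_id", "condition",
                                           "learned", "sp_correct", "ip_correct"])

    def test_reference_proportions(self):
        rows = []
        for cond, k in (("Baseline", 77), ("No-Think", 72), ("Think", 80)):
            for i in range(100):
                rows.append(("s1", f"{cond}{i}", cond, True, i < k, i < k))
        s = score_sif(self._recall(rows))
        assert s.recall_baseline == pytest.approx(0.77)
        assert s.recall_nothink == pytest.approx(0.72)
        assert s.sif == pytest.approx(0.05)

    def test_identical_recall_gives_zero_sif(self):
        rows = [("s1", f"p{i}", c, True, True, False)
                for c in ("Baseline", "No-Think", "Think") for i in range(4)]
        assert score_sif(self._recall(rows)).sif == 0.0

    def test_conditionalization_matches_hand_count(self):
        # 6 pairs, 2 unlearned; probes scored separately then averaged
        rows = [
            ("s1", "p1", "Baseline", True, True, True),    # 1, 1
            ("s1", "p2", "Baseline", True, False, True),   # 0, 1
            ("s1", "p3", "Baseline", False, True, True),   # excluded
            ("s1", "p4", "No-Think", True, False, False),  # 0, 0
            ("s1", "p5", "No-Think", True, True, False),   # 1, 0
            ("s1", "p6", "No-Think", False, False, False), # excluded
            ("s1", "p7", "Think", True, True, True),
        ]
        s = score_sif(self._recall(rows))
        assert s.recall_baseline == pytest.approx((0.5 + 1.0) / 2)
        assert s.recall_nothink == pytest.approx((0.5 + 0.0) / 2)
        assert s.sif == pytest.approx(0.75 - 0.25)

    def test_fillers_and_unlearned_are_ignored_when_all_learned(self):
        rows = [("s1", f"p{i}", c, True, i % 2 == 0, i % 2 == 0)
                for c in ("Baseline", "No-Think", "Think") for i in range(4)]
        rows += [("s1", "f1", "filler", True, True, True)]
        s = score_sif(self._recall(rows))
        assert s.recall_baseline == 0.5  # fillers untouched

    def test_zero_learned_condition_raises_with_name(self):
        rows = [("s1", "p1", "Baseline", True, True, True),
                ("s1", "p2", "No-Think", False, True, True),
                ("s1", "p3", "Think", True, True, True)]
        with pytest.raises(ValueError, match="No-Think"):
            score_sif(self._recall(rows))


class TestGroupTest:
    def test_all_equal_to_mu0(self):
        res = group_one_sample_test(np.full(10, 2.0), tail="one", mu0=2.0)
        assert res.t == 0.0
        assert res.p == pytest.approx(0.5)
        assert res.d == 0.0

    def test_d_identity_and_one_tailed_p(self):
        # printed-statistic arithmetic: d = t / sqrt(n); upper-tail p
        assert cohen_d_from_t(2.55, 24) == pytest.approx(0.521, abs=1e-3)
        assert cohen_d_from_t(13.89, 24) == pytest.approx(2.835, abs=1e-3)
        assert cohen_d_from_t(5.89, 24) == pytest.approx(1.202, abs=1e-3)
        assert one_tailed_p_from_t(2.55, 23) == pytest.approx(0.009, abs=5e-4)

    def test_matches_scipy_two_tailed(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 1, 24)
        res = group_one_sample_test(x, tail="two")
        ref = stats.ttest_1samp(x, 0.0)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.d == pytest.approx(res.t / np.sqrt(24), abs=1e-12)

    def test_rejects_n_below_two(self):
        with pytest.raises(ValueError):
            group_one_sample_test([1.0], tail="two")
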