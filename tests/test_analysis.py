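import numpy as np
import pytest

from placenav.agents import default_params, simulate_session
from placenav.analysis import (
    SessionSummary,
    compare_conditions,
    evaluate_criteria,
    find_pre_post,
    merge_pbs,
    summarize_session,
)
from placenav.circstats import MeanVector

from conftest import make_session, straight_ray_trial


def build_session(n_high, n_low, n_timeout=0, subject_id="r0", condition="expert", day=0):
    """A session assembled from straight-ray trials with forced outcomes."""
    trials = (
        [straight_ray_trial(180.0, trial_id=i) for i in range(n_high)]
        + [straight_ray_trial(10.0, trial_id=n_high + i) for i in range(n_low)]
        + [
            straight_ray_trial(90.0, end_radius=0.4, outcome="timeout",
                               trial_id=n_high + n_low + i)
            for i in range(n_timeout)
        ]
    )
    return make_session(trials, subject_id=subject_id, condition=condition, day=day)


def fake_summary(subject_id="r0", condition="PBS", day=0, **overrides):
    values = dict(
        n_trials=40, n_completed=40, high_visit_pct=90.0,
        high_visit_pct_completed=90.0, low_visit_pct=10.0, timeout_pct=0.0,
        mean_speed=12.0, mean_crossings=1.1,
        dd_mean_vector=MeanVector(direction=180.0, length=0.9, n=40),
        pcd_mean_vector=MeanVector(direction=180.0, length=0.9, n=40),
        mean_dd_deviation=15.0, mean_pcd_deviation=15.0, mean_excess=0.2,
        session_duration=600.0,
        dd_angles=np.full(40, 180.0), pcd_angles=np.full(40, 180.0),
    )
    values.update(overrides)
    return SessionSummary(subject_id=subject_id, condition=condition, day=day, **values)


class TestSummarizeSession:
    def test_all_high(self, main_arena):
        s = summarize_session(build_session(40, 0), main_arena)
        assert s.high_visit_pct == 100.0

    def test_30_high_10_low(self, main_arena):
        s = summarize_session(build_session(30, 10), main_arena)
        assert s.high_visit_pct == 75.0
        assert s.low_visit_pct == 25.0

    def test_visit_percentages_sum_to_100(self, main_arena):
        s = summarize_session(build_session(20, 10, 10), main_arena)
        assert s.high_visit_pct + s.low_visit_pct + s.timeout_pct == pytest.approx(100.0)
        # completed-trial denominator differs
        assert s.high_visit_pct_completed == pytest.approx(100 * 20 / 30)

    def test_noise_free_expert_session(self, main_arena):
        import math
        p = default_params("expert", kappa_align=math.inf, kappa_run=math.inf)
        sess = simulate_session(p, main_arena, 12, seed=0)
        s = summarize_session(sess, main_arena)
        assert s.mean_dd_deviation == pytest.approx(0.0, abs=1e-6)
        assert s.dd_mean_vector.length == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self, main_arena):
        with pytest.raises(ValueError):
            summarize_session(make_session([]), main_arena)


class TestEvaluateCriteria:
    def test_pre_training_pass(self):
        s = fake_summary(n_trials=60, high_visit_pct_completed=80.0,
                         mean_excess=0.5, session_duration=2000.0)
        assert evaluate_criteria(s, "pre_training").passed

    def test_pre_training_visit_boundary(self):
        s = fake_summary(n_trials=60, high_visit_pct_completed=74.0,
                         mean_excess=0.5, session_duration=2000.0)
        rep = evaluate_criteria(s, "pre_training")
        assert not rep.passed
        assert any("visit percentage" in r for r in rep.reasons)

    def test_75_exactly_fails_strict(self):
        s = fake_summary(n_trials=60, high_visit_pct_completed=75.0,
                         mean_excess=0.5, session_duration=2000.0)
        assert not evaluate_criteria(s, "pre_training").passed

    def test_probe_strict_excess(self):
        s = fake_summary(n_trials=40, mean_excess=0.1)
        assert not evaluate_criteria(s, "probe").passed
        s2 = fake_summary(n_trials=40, mean_excess=0.099)
        assert evaluate_criteria(s2, "probe").passed

    def test_post_training_thresholds(self):
        s = fake_summary(n_trials=40, high_visit_pct_completed=80.0, mean_excess=0.9)
        assert evaluate_criteria(s, "post_training").passed
        s2 = fake_summary(n_trials=40, high_visit_pct_completed=80.0, mean_excess=1.0)
        assert not evaluate_criteria(s2, "post_training").passed

    def test_pre_training_duration_limit(self):
        s = fake_summary(n_trials=60, high_visit_pct_completed=80.0,
                         mean_excess=0.5, session_duration=2500.0)
        assert not evaluate_criteria(s, "pre_training").passed

    def test_unknown_phase(self):
        with pytest.raises(ValueError, match="phase"):
            evaluate_criteria(fake_summary(), "post_hoc")


class TestFindPrePost:
    def test_fffpp_pattern(self):
        days = [
            fake_summary(day=i, high_visit_pct_completed=pct)
            for i, pct in enumerate([50.0, 60.0, 70.0, 80.0, 90.0])
        ]
        split = find_pre_post(days)
        assert split.pre_days == (1, 2)
        assert split.post_days == (3, 4)

    def test_early_pass_has_no_pre_window(self):
        days = [fake_summary(day=i, high_visit_pct_completed=90.0) for i in range(4)]
        with pytest.raises(ValueError, match="pre-learning"):
            find_pre_post(days)

    def test_no_qualifying_pair(self):
        days = [
            fake_summary(day=i, high_visit_pct_completed=pct)
            for i, pct in enumerate([50.0, 80.0, 60.0, 80.0, 70.0])
        ]
        with pytest.raises(ValueError, match="consecutive"):
            find_pre_post(days)

    def test_simulated_learning_series(self, main_arena):
        # novice days then expert days: POST deviation < PRE deviation
        days = []
        for d in range(3):
            sess = simulate_session(default_params("novice"), main_arena, 24,
                                    seed=400 + d, day=d)
            days.append(summarize_session(sess, main_arena))
        for d in range(3, 5):
            sess = simulate_session(default_params("expert"), main_arena, 24,
                                    seed=400 + d, day=d)
            days.append(summarize_session(sess, main_arena))
        split = find_pre_post(days)
        post_dev = np.mean([s.mean_dd_deviation for s in split.post])
        pre_dev = np.mean([s.mean_dd_deviation for s in split.pre])
        assert post_dev < pre_dev


class TestMergePBS:
    def subjects(self, n=8):
        return [f"r{i}" for i in range(n)]

    def test_identical_sessions_merge_unchanged(self):
        d = [fake_summary(subject_id=s, condition="dPBS") for s in self.subjects()]
        i = [fake_summary(subject_id=s, condition="iPBS") for s in self.subjects()]
        res = merge_pbs(d, i, metrics=("mean_crossings", "high_visit_pct"))
        assert res.refused == []
        assert np.allclose(res.merged["mean_crossings"], 1.1)

    def test_per_subject_average(self):
        d = [fake_summary(subject_id=s, mean_crossings=1.0) for s in self.subjects()]
        rng = np.random.default_rng(0)
        # jitter so the Wilcoxon gate sees symmetric noise, not a shift
        i = [
            fake_summary(subject_id=s, mean_crossings=3.0 + e)
            for s, e in zip(self.subjects(), rng.normal(0, 2.0, 8))
        ]
        res = merge_pbs(d, i, metrics=("mean_crossings",))
        if "mean_crossings" in res.merged:
            row = res.merged.set_index("subject_id").loc["r0", "mean_crossings"]
            i0 = [x for x in i if x.subject_id == "r0"][0]
            assert row == pytest.approx((1.0 + i0.mean_crossings) / 2)

    def test_strong_difference_refused(self):
        d = [fake_summary(subject_id=s, mean_crossings=1.0) for s in self.subjects()]
        i = [fake_summary(subject_id=s, mean_crossings=5.0 + k * 0.1)
             for k, s in enumerate(self.subjects())]
        res = merge_pbs(d, i, metrics=("mean_crossings",))
        assert "mean_crossings" in res.refused
        assert "dPBS_mean_crossings" in res.merged.columns
        assert "iPBS_mean_crossings" in res.merged.columns

    def test_unpaired_subjects_rejected(self):
        d = [fake_summary(subject_id="r0")]
        i = [fake_summary(subject_id="r1")]
        with pytest.raises(ValueError, match="paired"):
            merge_pbs(d, i)

    def test_idempotent_on_merged_input(self):
        merged = [fake_summary(subject_id=s, mean_crossings=2.0) for s in self.subjects()]
        res = merge_pbs(merged, [fake_summary(subject_id=s, mean_crossings=2.0)
                                 for s in self.subjects()],
                        metrics=("mean_crossings",))
        assert res.refused == []
        assert np.allclose(res.merged["mean_crossings"], 2.0)


class TestCompareConditions:
    def _summaries(self, condition, seed0, n_subjects=4, **param_overrides):
        cfg_params = default_params(condition, **param_overrides)
        out = []
        from placenav.environment import build_main_arena
        arena = build_main_arena()
        for i in range(n_subjects):
            sess = simulate_session(cfg_params, arena, 24, seed=seed0 + i,
                                    subject_id=f"r{i}")
            out.append(summarize_session(sess, arena))
        return out

    def test_identical_conditions_null(self):
        base = {
            c: [fake_summary(subject_id=f"r{i}", condition=c,
                             mean_crossings=1.0 + 0.1 * i) for i in range(6)]
            for c in ("PBS", "dMUS", "iMUS")
        }
        rep = compare_conditions(base, scalar_metrics=("mean_crossings",),
                                 angular=False)
        res = rep.scalar["mean_crossings"]
        assert res.p_value == pytest.approx(1.0)
        assert all(h.p_value == pytest.approx(1.0) for h in res.posthoc)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_conditions({"PBS": [fake_summary()]})

    def test_mismatched_subjects_rejected(self):
        a = [fake_summary(subject_id="r0"), fake_summary(subject_id="r1")]
        b = [fake_summary(subject_id="r0"), fake_summary(subject_id="r2")]
        with pytest.raises(ValueError, match="mismatched"):
            compare_conditions({"PBS": a, "iMUS": b})

    def test_simulated_condition_ordering(self):
        by_cond = {
            "PBS": self._summaries("expert", 1000),
            "dMUS": self._summaries("dMUS", 1000),
            "iMUS": self._summaries("iMUS", 1000),
        }
        rep = compare_conditions(by_cond, scalar_metrics=("mean_crossings",),
                                 n_perm=200, seed=0)
        means = {
            c: np.mean([s.mean_crossings for s in by_cond[c]]) for c in by_cond
        }
        assert means["PBS"] < means["dMUS"] < means["iMUS"]
        dd = rep.angular["dd"]
        assert dd.pairwise_ww[("PBS", "dMUS")].applicable is True
        assert dd.mean_vectors["PBS"].length > dd.mean_vectors["iMUS"].length

    def test_gate_blocks_dispersed_mus_pair(self):
        # with both inactivation conditions dispersed enough, the mean-
        # direction comparison between them is flagged non-interpretable
        by_cond = {
            "dMUS": self._summaries("dMUS", 2000, kappa_align=1.8),
            "iMUS": self._summaries("iMUS", 2000, kappa_align=0.0),
        }
        rep = compare_conditions(by_cond, scalar_metrics=("mean_crossings",),
                                 n_perm=200, seed=0)
        dd = rep.angular["dd"]
        assert dd.omnibus.applicable is False
        assert dd.pairwise_ww[("dMUS", "iMUS")].applicable is False
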