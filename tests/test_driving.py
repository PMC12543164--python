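"""Course construction, environment stepping and the closed loop."""

import numpy as np
import pandas as pd
import pytest

from biorc.culture import CultureParams, generate_culture
from biorc.driving import (
    AccuracyReport,
    DrivingEnv,
    TrialLog,
    build_course,
    run_closed_loop,
    score,
)
from biorc.force import ForceController


@pytest.fixture(scope="module")
def loop_setup(default_culture):
    rng = np.random.default_rng(99)
    left = rng.choice(default_culture.region_masks["left_execution"], 15,
                      replace=False)
    right = rng.choice(default_culture.region_masks["right_execution"], 15,
                       replace=False)
    return default_culture, left, right


class TestBuildCourse:
    def test_balanced_lane_assignment(self):
        course = build_course(10, balance=True, seed=0)
        lanes = [lane for lane, _ in course.obstacles]
        assert lanes.count("left") == 5 and lanes.count("right") == 5

    def test_deterministic_per_seed(self):
        assert build_course(8, seed=3) == build_course(8, seed=3)

    def test_spacing_guard(self):
        with pytest.raises(ValueError, match="spacing"):
            build_course(5, spacing=5.0, trigger_distance=5.0, lane_change_s=1.5)


class TestDrivingEnv:
    def test_passive_car_collides_with_challenge_obstacle(self):
        env = DrivingEnv(build_course(1, seed=0), challenge=True)
        outcomes = []
        for _ in range(150):
            for ev in env.step("straight", 0.1):
                if ev[0] == "outcome":
                    outcomes.append(ev)
        assert outcomes == [("outcome", "right", False)]  # car starts right

    def test_prompt_turn_succeeds(self):
        env = DrivingEnv(build_course(1, seed=0), challenge=True)
        outcomes = []
        for _ in range(150):
            action = "left" if env.stim_side == "right" else (
                "right" if env.stim_side == "left" else "straight")
            for ev in env.step(action, 0.1):
                if ev[0] == "outcome":
                    outcomes.append(ev)
        assert outcomes and outcomes[0][2] is True

    def test_stimulation_off_when_lane_change_completes(self):
        env = DrivingEnv(build_course(1, seed=0), challenge=True)
        log = []
        for _ in range(150):
            action = "left" if env.stim_side is not None else "straight"
            for ev in env.step(action, 0.1):
                log.append((round(env.car.position, 1), ev))
        kinds = [ev[0] for _, ev in log]
        assert kinds.index("stimulation_off") < kinds.index("outcome")
        # the off event arrives ~1.5 s (one lane change) after the trigger
        t_on = next(p for p, ev in log if ev[0] == "stimulation_on")
        t_off = next(p for p, ev in log if ev[0] == "stimulation_off")
        assert t_off - t_on == pytest.approx(1.6, abs=0.2)

    def test_static_courses_keep_their_lane_assignment(self):
        course = build_course(4, seed=5)
        env = DrivingEnv(course, challenge=False)
        seen = []
        for _ in range(600):
            for ev in env.step("straight", 0.1):
                if ev[0] == "outcome":
                    seen.append(ev[1])
        assert seen == [lane for lane, _ in course.obstacles]


class TestClosedLoop:
    def test_before_phase_keeps_weights_frozen(self, loop_setup):
        culture, left, right = loop_setup
        ctrl = ForceController(left, right, seed=1)
        w0 = ctrl.weight_snapshot()
        course = build_course(10, seed=1)
        log = run_closed_loop(culture, ctrl, course,
                              {"before_s": 30.0, "learn_s": 0.0, "fixed_s": 30.0},
                              seed=1)
        start, end = log.weight_trace["before"]
        for side in ("left", "right"):
            assert np.array_equal(start[side], w0[side])
            assert np.array_equal(start[side], end[side])
        assert log.weight_updates["before"] == 0
        assert log.weight_updates["fixed"] == 0

    def test_learning_error_shrinks(self, default_culture):
        # FORCE reduces the output-target mismatch within one learning phase
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            left = rng.choice(default_culture.region_masks["left_execution"], 15,
                              replace=False)
            right = rng.choice(default_culture.region_masks["right_execution"], 15,
                               replace=False)
            ctrl = ForceController(left, right, seed=s)
            course = build_course(12, seed=s)
            log = run_closed_loop(default_culture, ctrl, course,
                                  {"before_s": 0.0, "learn_s": 110.0,
                                   "fixed_s": 0.0}, seed=s)
            ln = log.frames
            # tracking error over pulse-active frames (where the output
            # must follow the target) early vs late in the learning phase
            active = ((ln.target_left > 0) | (ln.target_right > 0)).to_numpy()
            err = (np.abs(ln.out_left - ln.target_left)
                   + np.abs(ln.out_right - ln.target_right)).to_numpy()
            early = err[(ln.time < 20).to_numpy() & active].mean()
            late = err[(ln.time >= 90).to_numpy() & active].mean()
            if late < early:
                wins += 1
        assert wins >= 9

    def test_closed_loop_bit_deterministic(self, loop_setup):
        culture, left, right = loop_setup
        logs = []
        for _ in range(2):
            ctrl = ForceController(left, right, seed=2)
            logs.append(run_closed_loop(
                culture, ctrl, build_course(8, seed=2),
                {"before_s": 5.0, "learn_s": 30.0, "fixed_s": 40.0}, seed=2))
        pd.testing.assert_frame_equal(logs[0].frames, logs[1].frames)
        pd.testing.assert_frame_equal(logs[0].outcomes, logs[1].outcomes)

    def test_oracle_controller_is_perfect(self, loop_setup):
        culture, left, right = loop_setup
        ctrl = ForceController(left, right, seed=3)
        log = run_closed_loop(culture, ctrl, build_course(12, seed=3),
                              {"before_s": 0.0, "learn_s": 0.0, "fixed_s": 125.0},
                              seed=3, oracle=True)
        assert score(log, "fixed").total == 1.0

    def test_dead_controller_fails_everything(self, loop_setup):
        culture, left, right = loop_setup
        ctrl = ForceController(left, right, seed=4)
        log = run_closed_loop(culture, ctrl, build_course(12, seed=4),
                              {"before_s": 0.0, "learn_s": 0.0, "fixed_s": 125.0},
                              seed=4, dead=True)
        assert score(log, "fixed").total == 0.0


class TestScore:
    def _log_from_counts(self, left, right):
        rows = []
        for i in range(left[1]):
            rows.append({"time": float(i), "side": "left",
                         "success": i < left[0], "phase": "fixed"})
        for i in range(right[1]):
            rows.append({"time": 100.0 + i, "side": "right",
                         "success": i < right[0], "phase": "fixed"})
        return TrialLog(frames=pd.DataFrame(), outcomes=pd.DataFrame(rows),
                        phases={}, weight_updates={}, weight_trace={})

    def test_published_worked_example(self):
        # 16/16 left and 15/17 right successes -> ~93.9% overall, ~88% right
        rep = score(self._log_from_counts((16, 16), (15, 17)))
        assert rep.total == pytest.approx(31 / 33)
        assert rep.left == 1.0
        assert rep.right == pytest.approx(15 / 17)

    def test_all_failures(self):
        rep = score(self._log_from_counts((0, 5), (0, 5)))
        assert rep.total == 0.0

    def test_totals_match_recount(self, loop_setup):
        culture, left, right = loop_setup
        ctrl = ForceController(left, right, seed=5)
        log = run_closed_loop(culture, ctrl, build_course(10, seed=5),
                              {"before_s": 0.0, "learn_s": 0.0, "fixed_s": 105.0},
                              seed=5, oracle=True)
        rep = score(log, "fixed")
        fx = log.outcomes[log.outcomes.phase == "fixed"]
        assert rep.counts["left"][1] + rep.counts["right"][1] == len(fx)
        assert rep.counts["left"][0] + rep.counts["right"][0] == int(fx.success.sum())

    def test_empty_phase_rejected(self):
        with pytest.raises(ValueError):
            score(self._log_from_counts((0, 0), (0, 0)))
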