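"""Virtual two-lane driving task and closed-loop orchestration.

The car advances at constant speed down a two-lane course with obstacles in
either lane.  When the car comes within the trigger distance of the next
obstacle, a ring stimulus is switched on over the matching stimulation
perception area of the culture; the FORCE readouts over the execution areas
decide lane changes via the half-max rule; the stimulus is switched off once
the car completes a lane change or passes the obstacle.  A session is split
into three phases -- before-learning (weights frozen), learning (RLS updates
every frame) and fixed-weights (frozen again) -- and obstacle outcomes are
scored per phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .culture import CalciumParams, Culture, CultureSimulator, generate_culture
from .force import ForceController, decide_turn, smooth_plateau_pulse

__all__ = [
    "Course",
    "CarState",
    "TrialLog",
    "AccuracyReport",
    "ExperimentConfig",
    "build_course",
    "DrivingEnv",
    "run_closed_loop",
    "score",
    "run_experiment_suite",
]


@dataclass(frozen=True)
class Course:
    obstacles: tuple  # ((lane, position_m), ...) strictly increasing positions
    length: float
    trigger_distance: float

    def __post_init__(self) -> None:
        pos = [p for _, p in self.obstacles]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("obstacle positions must be strictly increasing")


@dataclass
class CarState:
    position: float = 0.0
    lane: str = "right"  # occupied lane (source lane until a change passes halfway)
    lane_change_progress: float = 0.0
    speed: float = 1.0
    target_lane: Optional[str] = None

    @property
    def occupied_lane(self) -> str:
        if self.target_lane is not None and self.lane_change_progress >= 0.5:
            return self.target_lane
        return self.lane


def build_course(
    n_obstacles: int,
    spacing: float = 10.0,
    trigger_distance: float = 5.0,
    balance: bool = True,
    seed: int = 0,
    speed: float = 1.0,
    lane_change_s: float = 1.5,
) -> Course:
    """Evenly spaced obstacles with balanced (or random) lane assignment."""
    if n_obstacles < 1:
        raise ValueError("need at least one obstacle")
    min_spacing = trigger_distance + speed * lane_change_s
    if spacing < min_spacing:
        raise ValueError(
            f"spacing {spacing} m is too small: the car cannot complete a lane "
            f"change after the trigger (minimum {min_spacing} m)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if balance:
        lanes = ["left"] * (n_obstacles // 2) + ["right"] * (n_obstacles - n_obstacles // 2)
        rng.shuffle(lanes)
    else:
        lanes = list(rng.choice(["left", "right"], size=n_obstacles))
    positions = spacing * (1 + np.arange(n_obstacles))
    obstacles = tuple(zip(lanes, positions.tolist()))
    return Course(
        obstacles=obstacles,
        length=float(positions[-1] + spacing),
        trigger_distance=trigger_distance,
    )


class DrivingEnv:
    """Stateful environment stepping: position, lane changes, events.

    Events emitted by :meth:`step`:
      ("stimulation_on", side)   trigger distance reached for the next obstacle
      ("stimulation_off",)       lane change completed or obstacle passed
      ("outcome", side, success) obstacle passed; success iff the occupied
                                 lane differs from the obstacle lane
    """

    def __init__(self, course: Course, speed: float = 1.0, lane_change_s: float = 1.5,
                 start_lane: str = "right", challenge: bool = True):
        self.course = course
        self.lane_change_s = lane_change_s
        self.car = CarState(speed=speed, lane=start_lane)
        self.next_idx = 0
        self.stim_side: Optional[str] = None
        # challenge placement: each obstacle materialises in the car's
        # occupied lane at trigger time, so every encounter is a genuine
        # avoidance trial (a passive car collides with every obstacle)
        self.challenge = challenge
        self._lanes = [lane for lane, _ in course.obstacles]
        self._triggered = [False] * len(course.obstacles)

    @property
    def done(self) -> bool:
        return self.next_idx >= len(self.course.obstacles)

    def step(self, action: str, dt: float) -> list:
        if dt <= 0:
            raise ValueError("dt must be positive")
        car = self.car
        events = []
        car.position += car.speed * dt

        # lane-change kinematics
        if car.target_lane is None and action in ("left", "right") and action != car.lane:
            car.target_lane = action
            car.lane_change_progress = 1e-9  # change engaged this frame
        if car.target_lane is not None:
            car.lane_change_progress += dt / self.lane_change_s
            if car.lane_change_progress >= 1.0:
                car.lane = car.target_lane
                car.target_lane = None
                car.lane_change_progress = 0.0
                if self.stim_side is not None:
                    self.stim_side = None
                    events.append(("stimulation_off",))

        if not self.done:
            _, pos = self.course.obstacles[self.next_idx]
            lane = self._lanes[self.next_idx]
            if self.stim_side is None and not self._triggered[self.next_idx] \
                    and car.position >= pos - self.course.trigger_distance \
                    and car.position < pos:
                # an obstacle triggers stimulation exactly once; after the
                # lane change completes the stimulus stays off
                self._triggered[self.next_idx] = True
                if self.challenge:
                    lane = car.occupied_lane
                    self._lanes[self.next_idx] = lane
                self.stim_side = lane
                events.append(("stimulation_on", lane))
            if car.position >= pos:
                success = car.occupied_lane != lane
                events.append(("outcome", lane, bool(success)))
                if self.stim_side is not None:
                    self.stim_side = None
                    events.append(("stimulation_off",))
                self.next_idx += 1
        return events


@dataclass
class TrialLog:
    """Frame-level record of one closed-loop session plus per-obstacle outcomes."""

    frames: pd.DataFrame
    outcomes: pd.DataFrame  # columns: time, side, success, phase
    phases: dict  # phase name -> (t_start, t_end)
    weight_updates: dict  # phase name -> number of RLS updates applied
    weight_trace: dict  # phase name -> (w_start, w_end) snapshots per side


@dataclass
class AccuracyReport:
    total: float
    left: float
    right: float
    counts: dict  # side -> (successes, trials)


def score(log: TrialLog, phase_filter: str = "fixed") -> AccuracyReport:
    """Per-side and total success fractions over the filtered phase."""
    if len(log.outcomes) == 0:
        raise ValueError("no obstacle outcomes in the requested phase")
    sel = log.outcomes[log.outcomes["phase"] == phase_filter] if phase_filter else log.outcomes
    if len(sel) == 0:
        raise ValueError("no obstacle outcomes in the requested phase")
    counts = {}
    for side in ("left", "right"):
        sub = sel[sel["side"] == side]
        counts[side] = (int(sub["success"].sum()), int(len(sub)))
    ls, lt = counts["left"]
    rs, rt = counts["right"]
    return AccuracyReport(
        total=(ls + rs) / (lt + rt),
        left=ls / lt if lt else float("nan"),
        right=rs / rt if rt else float("nan"),
        counts=counts,
    )


def run_closed_loop(
    culture: Culture,
    controller: ForceController,
    course: Course,
    phases: dict,
    seed: int = 0,
    calcium: CalciumParams = CalciumParams(),
    speed: float = 1.0,
    lane_change_s: float = 1.5,
    target_width_s: float = 5.0,
    drive_amplitude: float = 3.0,
    challenge: bool = True,
    oracle: bool = False,
    dead: bool = False,
) -> TrialLog:
    """Run the 3-phase closed loop (stimulate, simulate, read out, decide, move).

    ``phases`` maps {"before_s", "learn_s", "fixed_s"} to durations in
    seconds.  The target for each side is a raised-cosine pulse of width
    ``target_width_s`` opened when that side's stimulation triggers.  With
    ``oracle=True`` the car is driven by the targets themselves (upper
    bound); with ``dead=True`` both outputs are forced to zero.
    """
    for side in ("left", "right"):
        idx = controller.sides[side].neuron_indices
        n = culture.n_neurons
        if idx.size == 0 or idx.min() < 0 or idx.max() >= n:
            raise ValueError("controller neuron indices do not match the culture")

    before_s = float(phases.get("before_s", 0.0))
    learn_s = float(phases.get("learn_s", 0.0))
    fixed_s = float(phases.get("fixed_s", 0.0))
    if min(before_s, learn_s, fixed_s) < 0:
        raise ValueError("phase durations must be non-negative")
    total_s = before_s + learn_s + fixed_s

    ss = np.random.SeedSequence(seed).spawn(1)[0]
    sim = CultureSimulator(culture, calcium, seed=ss.generate_state(1)[0] % (2**31))
    env = DrivingEnv(course, speed=speed, lane_change_s=lane_change_s,
                     challenge=challenge)
    frame_dt = 1.0 / calcium.sample_rate
    n_frames = int(round(total_s / frame_dt))

    patterns = {
        "left": culture.stimulus_for_region("left_perception", drive_amplitude),
        "right": culture.stimulus_for_region("right_perception", drive_amplitude),
    }
    phase_bounds = {
        "before": (0.0, before_s),
        "learning": (before_s, before_s + learn_s),
        "fixed": (before_s + learn_s, total_s),
    }
    target_open = {"left": -np.inf, "right": -np.inf}  # window start per side
    weight_updates = {"before": 0, "learning": 0, "fixed": 0}
    w_start = {ph: None for ph in phase_bounds}
    w_end = {ph: None for ph in phase_bounds}

    cols = {k: [] for k in (
        "time", "phase", "stim_left", "stim_right", "out_left", "out_right",
        "target_left", "target_right", "position", "lane", "action",
    )}
    outcome_rows = []

    def phase_at(t: float) -> str:
        if t < before_s:
            return "before"
        if t < before_s + learn_s:
            return "learning"
        return "fixed"

    prev_phase = None
    for k in range(n_frames):
        t = k * frame_dt
        phase = phase_at(t)
        if phase != prev_phase:
            if prev_phase is not None:
                w_end[prev_phase] = controller.weight_snapshot()
            w_start[phase] = controller.weight_snapshot()
            prev_phase = phase

        active = [patterns[env.stim_side]] if env.stim_side is not None else []
        dff = sim.step(active)

        # the pulse runs its full course even if the stimulus ends early:
        # learning keeps pushing the output toward the peak, so trained
        # outputs clear the half-max threshold with margin
        tgt = {
            side: float(
                smooth_plateau_pulse(
                    np.array([t]), target_open[side], 1.0,
                    target_width_s - 1.0, target_width_s, controller.pulse_peak,
                )[0]
            )
            for side in ("left", "right")
        }
        # outputs (and the car's action) use the pre-update weights; the
        # RLS step is applied afterwards, so the logged error is the FORCE
        # pre-update error e- that learning drives down
        if dead:
            out_l, out_r = 0.0, 0.0
        elif oracle:
            out_l, out_r = tgt["left"], tgt["right"]
        else:
            out_l, out_r = controller.outputs(dff)
        action = decide_turn(out_l, out_r, controller.pulse_peak)
        if phase == "learning":
            controller.learn(dff, tgt["left"], tgt["right"])
            weight_updates["learning"] += 1

        events = env.step(action, frame_dt)
        for ev in events:
            if ev[0] == "stimulation_on":
                target_open[ev[1]] = t + frame_dt
            elif ev[0] == "outcome":
                outcome_rows.append(
                    {"time": t, "side": ev[1], "success": ev[2], "phase": phase}
                )

        cols["time"].append(t)
        cols["phase"].append(phase)
        cols["stim_left"].append(env.stim_side == "left")
        cols["stim_right"].append(env.stim_side == "right")
        cols["out_left"].append(out_l)
        cols["out_right"].append(out_r)
        cols["target_left"].append(tgt["left"])
        cols["target_right"].append(tgt["right"])
        cols["position"].append(env.car.position)
        cols["lane"].append(env.car.occupied_lane)
        cols["action"].append(action)

    if prev_phase is not None:
        w_end[prev_phase] = controller.weight_snapshot()

    return TrialLog(
        frames=pd.DataFrame(cols),
        outcomes=pd.DataFrame(outcome_rows, columns=["time", "side", "success", "phase"]),
        phases=phase_bounds,
        weight_updates=weight_updates,
        weight_trace={ph: (w_start[ph], w_end[ph]) for ph in phase_bounds},
    )


# --------------------------------------------------------------------------- #
# experiment suite
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ExperimentConfig:
    neuron_counts: tuple = (2, 5, 10, 15, 20)
    training_times: tuple = (50.0, 100.0, 150.0, 200.0)
    seeds: tuple = (1, 2, 3, 4, 5)
    min_encounters: int = 40
    spacing: float = 10.0
    trigger_distance: float = 5.0
    speed: float = 1.0
    lane_change_s: float = 1.5
    pz: float = 0.5
    drive_amplitude: float = 4.5
    before_s: float = 0.0


def _readout_subset(rng: np.random.Generator, mask: np.ndarray, k: int) -> np.ndarray:
    if k > mask.size:
        raise ValueError(
            f"requested {k} readout neurons but the execution area has only {mask.size}"
        )
    return rng.choice(mask, size=k, replace=False)


def run_experiment_suite(config: ExperimentConfig = ExperimentConfig(),
                         culture_params=None, calcium: CalciumParams = CalciumParams(),
                         ) -> dict:
    """Accuracy versus readout size and training time (plus integral ratios).

    For every (neuron count, training time, seed) cell a fresh pair of
    readouts over a random subset of each execution area is FORCE-trained
    for the given time on a fresh culture, then scored over at least
    ``min_encounters`` fixed-weight obstacle encounters.

    Returns {"accuracy": DataFrame, "integral_ratio": DataFrame}.
    """
    from .culture import CultureParams

    rows = []
    ratio_rows = []
    for seed in config.seeds:
        params = culture_params if culture_params is not None else CultureParams(seed=seed)
        params = params if params.seed == seed else type(params)(
            **{**params.__dict__, "seed": seed}
        )
        culture = generate_culture(params)
        left_mask = culture.region_masks["left_execution"]
        right_mask = culture.region_masks["right_execution"]
        cell_ss = np.random.SeedSequence([seed, 77])
        for count in config.neuron_counts:
            for train_s in config.training_times:
                child = np.random.SeedSequence([seed, count, int(train_s * 10)])
                rng = np.random.default_rng(child)
                left_idx = _readout_subset(rng, left_mask, count)
                right_idx = _readout_subset(rng, right_mask, count)
                controller = ForceController(
                    left_idx, right_idx, pz=config.pz,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                fixed_s = config.min_encounters * config.spacing / config.speed
                total_s = config.before_s + train_s + fixed_s
                n_obstacles = int(np.ceil(total_s * config.speed / config.spacing)) + 1
                course = build_course(
                    n_obstacles, spacing=config.spacing,
                    trigger_distance=config.trigger_distance, balance=True,
                    seed=seed, speed=config.speed, lane_change_s=config.lane_change_s,
                )
                log = run_closed_loop(
                    culture, controller, course,
                    phases={"before_s": config.before_s, "learn_s": train_s,
                            "fixed_s": fixed_s},
                    seed=seed, calcium=calcium, speed=config.speed,
                    lane_change_s=config.lane_change_s,
                    drive_amplitude=config.drive_amplitude,
                )
                rep = score(log, "fixed")
                rows.append({
                    "neuron_count": count, "training_s": train_s, "seed": seed,
                    "accuracy": rep.total, "accuracy_left": rep.left,
                    "accuracy_right": rep.right,
                    "n_left": rep.counts["left"][1], "n_right": rep.counts["right"][1],
                })
                for rr in integral_ratios(log):
                    ratio_rows.append({
                        "neuron_count": count, "training_s": train_s, "seed": seed, **rr
                    })
    return {
        "accuracy": pd.DataFrame(rows),
        "integral_ratio": pd.DataFrame(ratio_rows),
    }


def integral_ratios(log: TrialLog, phase: str = "learning") -> list:
    """Per-obstacle ratio of the output integral to the target integral.

    Computed for the side whose target pulse is active around each obstacle
    encounter in the given phase; the series tracks how learning improves
    the match between output and target across avoidance trials.
    """
    frames = log.frames
    out = []
    trials = log.outcomes[log.outcomes["phase"] == phase]
    for i, row in enumerate(trials.itertuples()):
        side = row.side
        sel = frames[
            (frames["time"] >= row.time - 10.0) & (frames["time"] <= row.time)
        ]
        tgt = sel[f"target_{side}"].to_numpy()
        outp = np.clip(sel[f"out_{side}"].to_numpy(), 0.0, None)
        denom = tgt.sum()
        if denom > 1e-9:
            out.append({"trial": i, "side": side, "ratio": float(outp.sum() / denom)})
    return out
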