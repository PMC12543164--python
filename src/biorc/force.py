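"""FORCE learning: readout initialisation, recursive-least-squares updates,
target-signal construction and the half-max turn decision.

The readout is linear, y(t) = w^T r(t), with r(t) the dF/F vector of the
selected execution-area neurons.  During learning the weights are updated at
each interval by recursive least squares:

    e-   = w^T r - f                      (pre-update error)
    P'   = P - (P r r^T P) / (1 + r^T P r)
    w'   = w - e- P' r

which guarantees the post-update error e+ = e- / (1 + r^T P r).  P is the
running inverse covariance, initialised to I / alpha and re-symmetrised
periodically for numerical hygiene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ReadoutWeights",
    "RLSState",
    "TargetSignal",
    "init_weights",
    "force_update",
    "make_target",
    "raised_cosine_pulse",
    "smooth_plateau_pulse",
    "decide_turn",
    "SideReadout",
    "ForceController",
]


@dataclass
class ReadoutWeights:
    w: np.ndarray
    pz: float
    n_features: int


@dataclass
class RLSState:
    P: np.ndarray
    dt_update: float = 0.1  # seconds between weight updates (10-Hz frames)
    steps: int = 0
    resym_every: int = 100

    @classmethod
    def identity(cls, n: int, alpha: float = 1.0, dt_update: float = 0.1) -> "RLSState":
        return cls(P=np.eye(n) / alpha, dt_update=dt_update)


@dataclass
class TargetSignal:
    values: np.ndarray
    pulse_peak: float
    trough: float = 0.0


def init_weights(
    n_features: int, pz: float, seed: int = 0, sqrt_norm: bool = False
) -> ReadoutWeights:
    """Initialise readout weights: unit normals / S, then Bernoulli-zeroed.

    The normalisation factor is S = pz * N (``sqrt_norm=True`` switches to
    the conventional S = sqrt(pz * N)).  Each entry is kept nonzero with
    probability pz.
    """
    if not (0 < pz <= 1):
        raise ValueError("pz must lie in (0, 1]; pz = 0 gives an all-zero readout")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    s = np.sqrt(pz * n_features) if sqrt_norm else pz * n_features
    w = rng.standard_normal(n_features) / s
    w[rng.random(n_features) >= pz] = 0.0
    return ReadoutWeights(w=w, pz=pz, n_features=n_features)


def force_update(
    w: np.ndarray, P: np.ndarray, r: np.ndarray, f: float
) -> tuple:
    """One recursive-least-squares step; returns (w', P', e_minus)."""
    w = np.asarray(w, dtype=float)
    r = np.asarray(r, dtype=float)
    if not (np.isfinite(w).all() and np.isfinite(P).all()
            and np.isfinite(r).all() and np.isfinite(f)):
        raise ValueError("non-finite input to force_update")
    e_minus = float(w @ r - f)
    Pr = P @ r
    denom = 1.0 + float(r @ Pr)
    P_new = P - np.outer(Pr, Pr) / denom
    w_new = w - e_minus * (P_new @ r)
    return w_new, P_new, e_minus


def raised_cosine_pulse(t: np.ndarray, t0: float, t1: float, peak: float) -> np.ndarray:
    """Smooth pulse: 0 outside (t0, t1), rising to ``peak`` mid-window."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape)
    inside = (t > t0) & (t < t1)
    out[inside] = peak * 0.5 * (1.0 - np.cos(2 * np.pi * (t[inside] - t0) / (t1 - t0)))
    return out


def smooth_plateau_pulse(
    t: np.ndarray, t0: float, rise: float, hold_until: float, end: float,
    peak: float = 1.0,
) -> np.ndarray:
    """Cosine-flanked plateau pulse used as the closed-loop steering target.

    Rises smoothly over ``rise`` seconds from ``t0``, holds at ``peak``
    until ``t0 + hold_until``, then falls back to the trough by
    ``t0 + end``.  Not a square wave, but wide enough that the culture's
    ramp-and-plateau stimulus response can realise it.
    """
    t = np.asarray(t, dtype=float) - t0
    out = np.zeros(t.shape)
    r = (t >= 0) & (t < rise)
    out[r] = peak * 0.5 * (1.0 - np.cos(np.pi * t[r] / rise))
    out[(t >= rise) & (t < hold_until)] = peak
    d = (t >= hold_until) & (t < end)
    out[d] = peak * 0.5 * (1.0 + np.cos(np.pi * (t[d] - hold_until) / (end - hold_until)))
    return out


def make_target(
    obstacle_windows: Sequence,
    duration: float,
    sample_rate: float = 10.0,
    pulse_peak: float = 1.0,
) -> dict:
    """Per-side target signals from (side, t_start, t_end) obstacle windows.

    The target is not a square wave: each window contributes a raised-cosine
    pulse peaking at ``pulse_peak`` mid-window, and the signal sits at the
    trough (0) during normal driving.  Same-side windows must not overlap.
    """
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    sides = sorted({side for side, _, _ in obstacle_windows} | {"left", "right"})
    out = {}
    for side in sides:
        wins = sorted((t0, t1) for s, t0, t1 in obstacle_windows if s == side)
        for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping {side}-side obstacle windows")
        values = np.zeros(t.shape)
        for t0, t1 in wins:
            values += raised_cosine_pulse(t, t0, t1, pulse_peak)
        out[side] = TargetSignal(values=values, pulse_peak=pulse_peak)
    return out


def decide_turn(left_out: float, right_out: float, pulse_peak: float = 1.0) -> str:
    """Half-max threshold rule mapping the two readouts to a car action.

    A left-side output above half the target peak commands a right turn
    (away from the left obstacle) and vice versa; if both exceed threshold
    the larger excess wins and exact ties go straight.
    """
    if not (np.isfinite(left_out) and np.isfinite(right_out)):
        raise ValueError("non-finite readout output")
    thr = pulse_peak / 2.0
    left_hit = left_out > thr
    right_hit = right_out > thr
    if left_hit and right_hit:
        if left_out > right_out:
            return "right"
        if right_out > left_out:
            return "left"
        return "straight"
    if left_hit:
        return "right"
    if right_hit:
        return "left"
    return "straight"


# --------------------------------------------------------------------------- #
# closed-loop controller
# --------------------------------------------------------------------------- #


@dataclass
class SideReadout:
    """Weights, RLS state and neuron selection for one side's readout."""

    neuron_indices: np.ndarray
    w: np.ndarray
    rls: RLSState

    def output(self, dff: np.ndarray) -> float:
        return float(self.w @ dff[self.neuron_indices])

    def learn(self, dff: np.ndarray, target: float) -> float:
        r = dff[self.neuron_indices]
        self.w, self.rls.P, e = force_update(self.w, self.rls.P, r, target)
        self.rls.steps += 1
        if self.rls.steps % self.rls.resym_every == 0:
            self.rls.P = (self.rls.P + self.rls.P.T) / 2.0
        return e


class ForceController:
    """Two independent FORCE readouts (left/right execution areas)."""

    def __init__(
        self,
        left_indices: Sequence[int],
        right_indices: Sequence[int],
        pz: float = 0.5,
        seed: int = 0,
        pulse_peak: float = 1.0,
        alpha: float = 1.0,
        dt_update: float = 0.1,
        sqrt_norm: bool = False,
    ):
        ss = np.random.SeedSequence(seed).spawn(2)
        self.pulse_peak = pulse_peak
        self.sides = {}
        for name, idx, child in (
            ("left", left_indices, ss[0]),
            ("right", right_indices, ss[1]),
        ):
            idx = np.asarray(idx, dtype=int)
            w0 = init_weights(idx.size, pz, seed=child.generate_state(1)[0] % (2**31),
                              sqrt_norm=sqrt_norm).w
            self.sides[name] = SideReadout(
                neuron_indices=idx,
                w=w0,
                rls=RLSState.identity(idx.size, alpha=alpha, dt_update=dt_update),
            )

    def outputs(self, dff: np.ndarray) -> tuple:
        return self.sides["left"].output(dff), self.sides["right"].output(dff)

    def learn(self, dff: np.ndarray, target_left: float, target_right: float) -> tuple:
        return (
            self.sides["left"].learn(dff, target_left),
            self.sides["right"].learn(dff, target_right),
        )

    def decide(self, dff: np.ndarray) -> str:
        l, r = self.outputs(dff)
        return decide_turn(l, r, self.pulse_peak)

    def weight_snapshot(self) -> dict:
        return {name: side.w.copy() for name, side in self.sides.items()}
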