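"""Synthetic neuronal culture: a stand-in reservoir with culture-like dynamics.

The model is a recurrent network of leaky rate units with per-neuron
short-term input adaptation and a Poisson spike readout:

    tau dx_i/dt = -x_i + [W tanh(x)]_i + g(s_i) * u_i(t) + noise
    rate_i      = max_rate * max(0, tanh(x_i))
    ds_i/dt     = (1 - s_i)/tau_rec - d_rate * (rate_i / max_rate) * s_i

``u_i`` is the optogenetic drive (nonzero for neurons whose soma lies inside
an active stimulation pattern) and ``s_i`` is a synaptic-resource variable
that gates the drive through a hysteresis switch: the gate opens once the
resource has recovered past ``adapt_gate_threshold`` and stays open during
the evoked response until depletion pulls the resource below
``adapt_gate_close``, after which the neuron is refractory until the
resource recovers again.  This relaxation-oscillator structure gives the
network the hallmark behaviour of dissociated cortical cultures: an
all-or-none response event to the first effective stimulus after a quiet
period, then strongly depressed responses for several seconds.  That single
mechanism lets the culture be simultaneously highly reproducible across
trials (response events are locked to the input history) and a weak
*linear* memory (individual input symbols are encoded sparsely and
nonlinearly, so a linear readout recovers little of them).

Spikes are drawn as an inhomogeneous Poisson process from the rectified
rates, and fluorescence is synthesised by convolving the spikes with a
jRCaMP1b-like double-exponential kernel (half-rise < 50 ms, ~0.6 s decay)
sampled at 10 Hz as dF/F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from . import kernels

__all__ = [
    "CultureParams",
    "CalciumParams",
    "Culture",
    "StimulusPattern",
    "InputSequence",
    "IntervalTimeline",
    "ActivityRecord",
    "TraceSet",
    "ConfigurationError",
    "GeometryError",
    "DEFAULT_REGIONS",
    "generate_culture",
    "make_binary_input",
    "simulate",
    "spikes_to_fluorescence",
    "render_movie",
    "CultureSimulator",
]


class ConfigurationError(ValueError):
    """Raised when a culture configuration violates its stated constraints."""


class GeometryError(ValueError):
    """Raised when a stimulus pattern falls outside the unit square."""


# --------------------------------------------------------------------------- #
# parameters and domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class CultureParams:
    """Generator and dynamics parameters of the synthetic culture.

    The defaults are the package's reference calibration: they are chosen so
    the synthetic culture reproduces the physiology the analysis modules are
    built for -- localized ring responses, trial-to-trial reproducibility of
    driven activity, and a short (< 1 s) linear memory.
    """

    n_neurons: int = 350
    connect_prob: float = 0.1
    weight_gain: float = 1.0
    spectral_radius_target: float = 0.9
    membrane_tau: float = 0.05  # seconds
    dt_sim: float = 0.01  # seconds
    max_rate: float = 1600.0  # spikes/s at full drive (population-event scale)
    rate_threshold: float = 0.1  # activation (tanh scale) below which no spikes fire
    noise_sd: float = 0.01  # state-noise intensity (1/sqrt(s))
    burst_enabled: bool = False
    seed: int = 0
    # short-term input adaptation (synaptic resource with hysteresis gate)
    adapt_rec_tau: float = 6.0  # resource recovery time constant, s
    adapt_depletion: float = 12.0  # depletion rate at maximal firing, 1/s
    adapt_gate_threshold: float = 0.75  # resource level at which the gate opens
    adapt_gate_close: float = 0.2  # resource level at which the gate shuts
    adapt_leak: float = 0.085  # residual (sub-event) drive fraction
    adapt_leak_tau: float = 0.3  # slow synaptic filter for the residual drive, s
    burst_amplitude: float = 1.5  # optional slow global drive (qualitative)

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ConfigurationError("n_neurons must be >= 2")
        if not (0 < self.connect_prob <= 1):
            raise ConfigurationError("connect_prob must lie in (0, 1]")
        if not (0 < self.spectral_radius_target < 1):
            raise ConfigurationError("spectral_radius_target must lie in (0, 1)")
        if self.dt_sim <= 0:
            raise ConfigurationError("dt_sim must be positive")
        if self.membrane_tau <= 0:
            raise ConfigurationError("membrane_tau must be positive")


@dataclass(frozen=True)
class CalciumParams:
    """jRCaMP1b-like indicator model and acquisition settings."""

    rise_tau: float = 0.05  # s, gives a fluorescent half-rise under 50 ms
    decay_tau: float = 0.6  # s
    amplitude: float = 0.1  # peak dF/F contributed by one spike
    noise_sd: float = 0.03  # additive dF/F measurement noise
    sample_rate: float = 10.0  # Hz
    baseline_f0: float = 1.0  # resting fluorescence used for synthesis
    saturation: float = 0.8  # indicator ceiling: dF/F = S*tanh(linear/S); inf = linear

    def __post_init__(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise ConfigurationError("require decay_tau > rise_tau > 0")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")


#: Default region geometry (unit-square coordinates): two ring-shaped
#: stimulation perception areas in the upper half, two rectangular
#: calculation execution areas in the lower half.
DEFAULT_REGIONS = {
    "left_perception": {
        "kind": "annulus",
        "center": (0.28, 0.72),
        "outer_radius": 0.20,
        "inner_radius": 0.08,
    },
    "right_perception": {
        "kind": "annulus",
        "center": (0.72, 0.72),
        "outer_radius": 0.20,
        "inner_radius": 0.08,
    },
    "left_execution": {"kind": "rect", "x": (0.05, 0.45), "y": (0.05, 0.35)},
    "right_execution": {"kind": "rect", "x": (0.55, 0.95), "y": (0.05, 0.35)},
}


def _region_mask(positions: np.ndarray, spec: dict) -> np.ndarray:
    if spec["kind"] == "annulus":
        c = np.asarray(spec["center"])
        r = np.hypot(*(positions - c).T)
        inside = (r <= spec["outer_radius"]) & (r >= spec.get("inner_radius", 0.0))
    elif spec["kind"] == "rect":
        x0, x1 = spec["x"]
        y0, y1 = spec["y"]
        inside = (
            (positions[:, 0] >= x0)
            & (positions[:, 0] <= x1)
            & (positions[:, 1] >= y0)
            & (positions[:, 1] <= y1)
        )
    else:  # pragma: no cover - guarded by DEFAULT_REGIONS structure
        raise ConfigurationError(f"unknown region kind {spec['kind']!r}")
    return np.flatnonzero(inside)


@dataclass
class Culture:
    """A generated synthetic culture (the physical reservoir)."""

    positions: np.ndarray  # (N, 2) soma centres in the unit square
    recurrent_weights: sp.csr_array  # rescaled to the target spectral radius
    region_masks: dict  # name -> neuron index array
    params: CultureParams
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    def stimulus_for_region(
        self, name: str, drive_amplitude: float = 3.0, power_density: float = 1.0
    ) -> "StimulusPattern":
        """Build the ring/disc stimulus matching a configured region."""
        spec = self.regions[name]
        if spec["kind"] != "annulus":
            raise ConfigurationError(f"region {name!r} is not ring-shaped")
        return StimulusPattern(
            shape="ring",
            center=tuple(spec["center"]),
            outer_radius=spec["outer_radius"],
            inner_radius=spec["inner_radius"],
            power_density=power_density,
            drive_amplitude=drive_amplitude,
        )


@dataclass(frozen=True)
class StimulusPattern:
    """Ring- or disc-shaped optogenetic stimulation pattern."""

    shape: str  # "ring" | "disc"
    center: tuple
    outer_radius: float
    inner_radius: float = 0.0
    power_density: float = 1.0  # mW/mm^2
    drive_amplitude: float = 3.0

    def __post_init__(self) -> None:
        if self.shape not in ("ring", "disc"):
            raise ConfigurationError("shape must be 'ring' or 'disc'")
        if self.shape == "ring" and not (self.inner_radius < self.outer_radius):
            raise ConfigurationError("ring requires inner_radius < outer_radius")
        if self.power_density <= 0:
            raise ConfigurationError("power_density must be positive")

    def validate_geometry(self) -> None:
        cx, cy = self.center
        r = self.outer_radius
        if not (0 <= cx - r and cx + r <= 1 and 0 <= cy - r and cy + r <= 1):
            raise GeometryError(f"stimulus at {self.center} (r={r}) leaves the unit square")

    def membership(self, positions: np.ndarray) -> np.ndarray:
        dist = np.hypot(*(positions - np.asarray(self.center)).T)
        if self.shape == "ring":
            return (dist <= self.outer_radius) & (dist >= self.inner_radius)
        return dist <= self.outer_radius


@dataclass(frozen=True)
class InputSequence:
    """Binary symbol sequence v(t); each 1-symbol drives one light pulse.

    A symbol occupies ``symbol_period`` seconds; a 1 illuminates for the
    first ``on_duration`` seconds of its slot (default 200 ms on / 300 ms
    dark at 0.5-s symbols).
    """

    symbols: np.ndarray
    symbol_period: float = 0.5
    on_duration: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.on_duration < self.symbol_period):
            raise ConfigurationError("require 0 < on_duration < symbol_period")

    @property
    def duration(self) -> float:
        return len(self.symbols) * self.symbol_period

    def active(self, times: np.ndarray) -> np.ndarray:
        """Boolean illumination state at each requested time."""
        times = np.asarray(times, dtype=float)
        k = np.floor(times / self.symbol_period).astype(int)
        in_range = (k >= 0) & (k < len(self.symbols))
        phase = times - k * self.symbol_period
        out = np.zeros(times.shape, dtype=bool)
        ki = np.clip(k, 0, len(self.symbols) - 1)
        out[in_range] = (np.asarray(self.symbols)[ki[in_range]] > 0) & (
            phase[in_range] < self.on_duration
        )
        return out

    def on_grid(self, times: np.ndarray) -> np.ndarray:
        """Symbol value v(t) sampled by zero-order hold (targets, not light)."""
        k = np.clip(
            np.floor(np.asarray(times) / self.symbol_period).astype(int),
            0,
            len(self.symbols) - 1,
        )
        return np.asarray(self.symbols, dtype=float)[k]


@dataclass(frozen=True)
class IntervalTimeline:
    """On/off timeline given as a list of (t_on, t_off) intervals."""

    intervals: tuple

    def active(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        out = np.zeros(times.shape, dtype=bool)
        for t0, t1 in self.intervals:
            out |= (times >= t0) & (times < t1)
        return out


@dataclass
class ActivityRecord:
    """Spiking and rate output of one simulation."""

    spike_times: list  # per-neuron sorted arrays of spike times (s)
    rates: Optional[np.ndarray]  # (N, K) rectified rates, spikes/s
    rate_times: Optional[np.ndarray]
    duration: float
    states: Optional[np.ndarray] = None  # (N, K) membrane state, if recorded
    resources: Optional[np.ndarray] = None  # (N, K) adaptation resource


@dataclass
class TraceSet:
    """Per-neuron dF/F fluorescence series on a uniform grid."""

    data: np.ndarray  # (N, T)
    sample_rate: float

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def select(self, indices) -> "TraceSet":
        return TraceSet(self.data[np.asarray(indices)], self.sample_rate)


# --------------------------------------------------------------------------- #
# generation
# --------------------------------------------------------------------------- #


def generate_culture(params: CultureParams, regions: Optional[dict] = None) -> Culture:
    """Generate a culture: soma positions, recurrent weights, region masks.

    Deterministic for a fixed ``params.seed``.  The recurrent matrix is
    rescaled so its spectral radius equals ``spectral_radius_target`` (to
    within 1e-6), which makes the autonomous dynamics contracting and gives
    the echo-state property by construction.
    """
    regions = dict(DEFAULT_REGIONS if regions is None else regions)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_neurons

    positions = rng.random((n, 2))

    mask = rng.random((n, n)) < params.connect_prob
    np.fill_diagonal(mask, False)
    w = rng.standard_normal((n, n)) * params.weight_gain
    w[~mask] = 0.0
    if np.any(mask):
        rho = np.max(np.abs(np.linalg.eigvals(w)))
        if rho > 0:
            w *= params.spectral_radius_target / rho

    masks = {name: _region_mask(positions, spec) for name, spec in regions.items()}
    for name, idx in masks.items():
        if "perception" in name and idx.size <= 20:
            raise ConfigurationError(
                f"stimulation perception area {name!r} contains only {idx.size} "
                "neurons; it must encompass more than 20"
            )

    return Culture(
        positions=positions,
        recurrent_weights=sp.csr_array(w),
        region_masks=masks,
        params=params,
        regions=regions,
    )


def make_binary_input(
    n_symbols: int,
    p_on: float = 0.5,
    seed: int = 0,
    symbol_period: float = 0.5,
    on_duration: float = 0.2,
) -> InputSequence:
    """Draw an i.i.d. random binary input sequence v(t) in {0, 1}."""
    if not (0 <= p_on <= 1):
        raise ValueError("p_on must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    symbols = (rng.random(n_symbols) < p_on).astype(np.uint8)
    return InputSequence(symbols=symbols, symbol_period=symbol_period, on_duration=on_duration)


# --------------------------------------------------------------------------- #
# dynamics
# --------------------------------------------------------------------------- #


class _Dynamics:
    """Shared one-step integrator used by ``simulate`` and ``CultureSimulator``."""

    def __init__(self, culture: Culture, noise_rng: np.random.Generator,
                 spike_rng: np.random.Generator,
                 x0: Optional[np.ndarray] = None, s0: Optional[np.ndarray] = None):
        p = culture.params
        self.p = p
        self.W = culture.recurrent_weights
        # separate streams: the state-noise sequence is then identical for
        # any two runs with the same seed, even though the (rate-dependent)
        # Poisson sampling consumes a variable amount of randomness
        self.noise_rng = noise_rng
        self.spike_rng = spike_rng
        n = culture.n_neurons
        self.x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
        self.s = np.ones(n) if s0 is None else np.array(s0, dtype=float)
        self.gate_open = self.s >= p.adapt_gate_threshold
        self.q = np.zeros(n)  # slow residual-drive current
        self.t = 0.0
        if p.burst_enabled:
            self.burst_period = noise_rng.uniform(5.0, 20.0)
        else:
            self.burst_period = None

    def step(self, drive: np.ndarray) -> np.ndarray:
        """Advance one dt_sim; returns rectified rates (spikes/s)."""
        p = self.p
        dt = p.dt_sim
        # hysteresis: open on recovery past the threshold, shut on depletion
        self.gate_open |= self.s >= p.adapt_gate_threshold
        self.gate_open &= self.s > p.adapt_gate_close
        # depression attenuates rather than abolishes transmission: besides
        # the gated fast drive, a small residual drive passes through a slow
        # synaptic filter and sustains graded sub-event responsiveness
        self.q += (dt / p.adapt_leak_tau) * (p.adapt_leak * drive - self.q)
        u = drive * self.gate_open + self.q
        if self.burst_period is not None:
            b = math.sin(2 * math.pi * self.t / self.burst_period)
            if b > 0:
                u = u + p.burst_amplitude * b**3 * gate
        # recurrent input passes through the same gate (input-side synaptic
        # depression): refractory neurons do not join population events
        rec = (self.W @ np.tanh(self.x)) * self.gate_open
        dx = (dt / p.membrane_tau) * (-self.x + rec + u)
        if p.noise_sd > 0:
            dx += p.noise_sd * math.sqrt(dt) * self.noise_rng.standard_normal(self.x.size)
        self.x += dx
        # thresholded rectification: small fluctuations around rest stay silent
        act = np.maximum(np.tanh(self.x) - p.rate_threshold, 0.0) / (1.0 - p.rate_threshold)
        rate = p.max_rate * act
        # depletion is quadratic in the normalised rate: only full response
        # events consume the resource, weak sub-threshold activity does not
        self.s += dt * ((1.0 - self.s) / p.adapt_rec_tau
                        - p.adapt_depletion * act**2 * self.s)
        np.clip(self.s, 0.0, 1.0, out=self.s)
        self.t += dt
        return rate

    def draw_spikes(self, rate: np.ndarray, t0: float, dt: float):
        """Poisson spike counts for one step; returns (neuron_ids, times)."""
        counts = self.spike_rng.poisson(rate * dt)
        nz = np.flatnonzero(counts)
        if nz.size == 0:
            return None
        ids = np.repeat(nz, counts[nz])
        ts = t0 + self.spike_rng.random(ids.size) * dt
        return ids, ts


def _drive_matrix(culture: Culture, patterns: Sequence[StimulusPattern]) -> np.ndarray:
    rows = []
    for pat in patterns:
        pat.validate_geometry()
        rows.append(
            pat.membership(culture.positions).astype(float)
            * pat.drive_amplitude
            * pat.power_density
        )
    if not rows:
        return np.zeros((0, culture.n_neurons))
    return np.asarray(rows)


def simulate(
    culture: Culture,
    stimuli: Sequence,
    duration: float,
    seed: int = 0,
    x0: Optional[np.ndarray] = None,
    record_rates: bool = True,
    record_states: bool = False,
    rate_stride: int = 1,
) -> ActivityRecord:
    """Integrate the culture under a set of stimuli.

    Parameters
    ----------
    stimuli : sequence of (StimulusPattern, timeline) pairs, where the
        timeline exposes ``active(times) -> bool array`` (``InputSequence``
        and ``IntervalTimeline`` both qualify).
    duration : simulated seconds (> 0)
    seed : controls state noise and Poisson spiking; two runs with the same
        seed are bit-identical.
    x0 : optional initial membrane state (defaults to rest, x = 0)
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    p = culture.params
    n_steps = int(round(duration / p.dt_sim))
    step_starts = np.arange(n_steps) * p.dt_sim

    patterns = [pat for pat, _ in stimuli]
    drive = _drive_matrix(culture, patterns)
    on = (
        np.asarray([tl.active(step_starts) for _, tl in stimuli])
        if stimuli
        else np.zeros((0, n_steps), dtype=bool)
    )
    for _, tl in stimuli:
        if isinstance(tl, IntervalTimeline):
            for t0, t1 in tl.intervals:
                if not (0 <= t0 <= t1 <= duration):
                    raise ValueError("stimulus timeline outside [0, duration)")

    child = np.random.SeedSequence(seed).spawn(2)
    dyn = _Dynamics(culture, np.random.default_rng(child[0]),
                    np.random.default_rng(child[1]), x0=x0)

    n_rec = (n_steps + rate_stride - 1) // rate_stride
    rates = np.empty((culture.n_neurons, n_rec)) if record_rates else None
    states = np.empty((culture.n_neurons, n_rec)) if record_states else None
    resources = np.empty((culture.n_neurons, n_rec)) if record_states else None
    rate_times = step_starts[::rate_stride] + p.dt_sim if record_rates else None

    spike_ids = []
    spike_ts = []
    for k in range(n_steps):
        u = drive.T @ on[:, k] if drive.size else np.zeros(culture.n_neurons)
        rate = dyn.step(u)
        drawn = dyn.draw_spikes(rate, step_starts[k], p.dt_sim)
        if drawn is not None:
            spike_ids.append(drawn[0])
            spike_ts.append(drawn[1])
        if k % rate_stride == 0:
            j = k // rate_stride
            if record_rates:
                rates[:, j] = rate
            if record_states:
                states[:, j] = dyn.x
                resources[:, j] = dyn.s

    if spike_ids:
        ids = np.concatenate(spike_ids)
        ts = np.concatenate(spike_ts)
        order = np.lexsort((ts, ids))
        ids, ts = ids[order], ts[order]
        bounds = np.searchsorted(ids, np.arange(culture.n_neurons + 1))
        spikes = [ts[bounds[i] : bounds[i + 1]] for i in range(culture.n_neurons)]
    else:
        spikes = [np.empty(0) for _ in range(culture.n_neurons)]

    return ActivityRecord(
        spike_times=spikes,
        rates=rates,
        rate_times=rate_times,
        duration=duration,
        states=states,
        resources=resources,
    )


def spikes_to_fluorescence(
    record: ActivityRecord, calcium: CalciumParams = CalciumParams(), seed: int = 0
) -> TraceSet:
    """Convert spike trains to dF/F traces sampled at the acquisition rate.

    Each spike contributes one double-exponential transient; the summed
    signal passes through the indicator's soft saturation (set
    ``saturation=inf`` for a purely linear indicator) and Gaussian
    measurement noise is added on the sampling grid.  The synthesis baseline
    is the configured resting fluorescence, so the returned dF/F is exact.
    """
    n_samples = int(round(record.duration * calcium.sample_rate))
    times = np.arange(n_samples) / calcium.sample_rate
    data = kernels.superpose_batch(
        record.spike_times, times, calcium.rise_tau, calcium.decay_tau, calcium.amplitude
    )
    if np.isfinite(calcium.saturation):
        data = calcium.saturation * np.tanh(data / calcium.saturation)
    if calcium.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        data = data + calcium.noise_sd * rng.standard_normal(data.shape)
    return TraceSet(data=data, sample_rate=calcium.sample_rate)


# --------------------------------------------------------------------------- #
# movie rendering
# --------------------------------------------------------------------------- #


def render_movie(
    traces: TraceSet,
    culture: Optional[Culture] = None,
    positions: Optional[np.ndarray] = None,
    frame_shape: tuple = (128, 128),
    blob_sigma_px: float = 2.0,
    baseline_f0: float = 100.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Render traces as a TIFF-compatible image stack (frames, rows, cols).

    Each neuron is an isotropic Gaussian blob whose amplitude follows
    ``baseline_f0 * (1 + dF/F)``.  Overlapping (even identical) positions are
    allowed; their intensities add.  Pixel indices are 0-based row-major:
    x maps to columns, y to rows, no vertical flip.
    """
    h, w = frame_shape
    if h < 64 or w < 64:
        raise ValueError("frame_shape must be at least 64x64")
    if positions is None:
        if culture is None:
            positions = np.zeros((0, 2))
        else:
            positions = culture.positions
    n = positions.shape[0]
    if n != traces.n_neurons and n > 0:
        raise ValueError("positions/traces neuron count mismatch")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    T = traces.n_samples
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    basis = np.zeros((n, h * w), dtype=np.float32)
    for i in range(n):
        cx = positions[i, 0] * (w - 1)
        cy = positions[i, 1] * (h - 1)
        g = np.exp(-(((rows - cy) ** 2) + ((cols - cx) ** 2)) / (2 * blob_sigma_px**2))
        basis[i] = g.ravel()

    amp = baseline_f0 * (1.0 + traces.data.T).astype(np.float32)  # (T, N)
    frames = amp @ basis if n else np.zeros((T, h * w), dtype=np.float32)
    frames = frames.reshape(T, h, w)
    if noise_sd > 0:
        frames = frames + noise_sd * rng.standard_normal(frames.shape).astype(np.float32)
    return frames.astype(np.float32)


# --------------------------------------------------------------------------- #
# frame-by-frame simulator (closed loop)
# --------------------------------------------------------------------------- #


class CultureSimulator:
    """Step the culture one acquisition frame at a time.

    Used by the closed-loop controller: each call to :meth:`step` integrates
    one frame (``1 / sample_rate`` seconds) of dynamics under the currently
    active stimulation patterns and returns the per-neuron dF/F sample at
    the frame boundary.  Fully deterministic for a fixed seed and call
    sequence.
    """

    def __init__(
        self,
        culture: Culture,
        calcium: CalciumParams = CalciumParams(),
        seed: int = 0,
        x0: Optional[np.ndarray] = None,
    ):
        self.culture = culture
        self.calcium = calcium
        child = np.random.SeedSequence(seed).spawn(3)
        self.dyn = _Dynamics(culture, np.random.default_rng(child[0]),
                             np.random.default_rng(child[1]), x0=x0)
        self.rng = np.random.default_rng(child[2])  # measurement noise
        p = culture.params
        self.frame_dt = 1.0 / calcium.sample_rate
        self.n_sub = int(round(self.frame_dt / p.dt_sim))
        if self.n_sub < 1 or abs(self.n_sub * p.dt_sim - self.frame_dt) > 1e-9:
            raise ConfigurationError("dt_sim must divide the frame period")
        n = culture.n_neurons
        self._d = np.zeros(n)
        self._r = np.zeros(n)
        self._alpha_d = math.exp(-p.dt_sim / calcium.decay_tau)
        self._alpha_r = math.exp(-p.dt_sim / calcium.rise_tau)
        self._peak = kernels.kernel_peak_value(calcium.rise_tau, calcium.decay_tau)
        self.t = 0.0

    def step(self, active_patterns: Sequence[StimulusPattern] = ()) -> np.ndarray:
        """Advance one frame; returns the dF/F sample (N,) at frame end."""
        cult = self.culture
        p = cult.params
        drive = _drive_matrix(cult, list(active_patterns))
        u = drive.sum(axis=0) if drive.size else np.zeros(cult.n_neurons)
        cal = self.calcium
        for _ in range(self.n_sub):
            t0 = self.dyn.t
            rate = self.dyn.step(u)
            self._d *= self._alpha_d
            self._r *= self._alpha_r
            drawn = self.dyn.draw_spikes(rate, t0, p.dt_sim)
            if drawn is not None:
                ids, ts = drawn
                lag = (t0 + p.dt_sim) - ts
                np.add.at(self._d, ids, np.exp(-lag / cal.decay_tau))
                np.add.at(self._r, ids, np.exp(-lag / cal.rise_tau))
        self.t += self.frame_dt
        dff = cal.amplitude * (self._d - self._r) / self._peak
        if np.isfinite(cal.saturation):
            dff = cal.saturation * np.tanh(dff / cal.saturation)
        if cal.noise_sd > 0:
            dff = dff + cal.noise_sd * self.rng.standard_normal(dff.size)
        return dff
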