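"""Echo-state-property and short-term-memory assessment.

Two diagnostics for a driven reservoir recorded as dF/F traces:

* **Trial reproducibility** — the maximum normalised cross-correlation (and
  its lag) between corresponding sliding windows of two trials given the
  same input.  When the reservoir has the echo state property the max
  correlation climbs toward 1 and the lag collapses toward 0 as the initial
  condition washes out.

* **Memory function / capacity** — for each delay tau a linear readout
  W_tau = Y^T X (X^T X + lambda I)^(-1) is fitted to reconstruct v(t - tau)
  from the state x(t); f_tau is the squared Pearson correlation between the
  reconstruction and the true delayed input, and MC = sum_tau f_tau over the
  evaluated delay grid.  An exponential fitted to f_tau above the noise
  floor gives the memory decay constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .culture import InputSequence, TraceSet

__all__ = [
    "SlidingParams",
    "WindowSeries",
    "MemoryResult",
    "sliding_xcorr",
    "trial_reproducibility",
    "ridge_readout",
    "memory_profile",
    "fit_memory_decay",
    "select_responsive",
    "denoise",
]


@dataclass(frozen=True)
class SlidingParams:
    window_len: int = 300  # Lw: 30-s windows at 10 Hz
    step: int = 10  # Ls: 1-s steps
    max_lag: int = 50  # samples

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window_len):
            raise ValueError("require 0 < step <= window_len")
        if not (0 <= self.max_lag < self.window_len):
            raise ValueError("require max_lag < window_len")


@dataclass
class WindowSeries:
    """Per-window maximum cross-correlation and the lag attaining it."""

    max_corr: np.ndarray
    lag: np.ndarray  # signed samples; positive = second trace lags the first
    window_starts: np.ndarray


@dataclass
class MemoryResult:
    f_tau: dict  # delay (s) -> memory function value in [0, 1]
    mc: float  # capacity: sum of f_tau over symbol-aligned delays
    decay_tau_fit: float  # seconds; nan when no decay could be fitted
    weights: dict  # delay (s) -> readout weight vector
    lam: float
    mc_grid: float = float("nan")  # sum of f_tau over the full delay grid


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx <= 1e-12 or sy <= 1e-12:
        return 0.0
    return float(np.dot(x - x.mean(), y - y.mean()) / (len(x) * sx * sy))


def sliding_xcorr(a: np.ndarray, b: np.ndarray,
                  params: SlidingParams = SlidingParams()) -> WindowSeries:
    """Windowed normalised cross-correlation between two equal-length traces.

    For window h the correlation at lag l compares a[k] with b[k + l] over
    the overlapping samples inside the window; the returned series holds the
    maximising value and lag per window.  Zero-variance windows yield 0 with
    a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must have equal length")
    Lw, Ls, M = params.window_len, params.step, params.max_lag
    if a.size < Lw:
        raise ValueError("traces shorter than the window")

    starts = np.arange(0, a.size - Lw + 1, Ls)
    max_corr = np.zeros(starts.size)
    lags = np.zeros(starts.size, dtype=int)
    warned = False
    for h, s0 in enumerate(starts):
        sa = a[s0 : s0 + Lw]
        sb = b[s0 : s0 + Lw]
        if sa.std() <= 1e-12 or sb.std() <= 1e-12:
            if not warned:
                warnings.warn("zero-variance window: max_corr recorded as 0", RuntimeWarning)
                warned = True
            continue
        best_c, best_l = -np.inf, 0
        for l in range(-M, M + 1):
            if l >= 0:
                x, y = sa[: Lw - l], sb[l:]
            else:
                x, y = sa[-l:], sb[: Lw + l]
            c = _pearson(x, y)
            if c > best_c:
                best_c, best_l = c, l
        max_corr[h] = best_c
        lags[h] = best_l
    return WindowSeries(max_corr=max_corr, lag=lags, window_starts=starts)


def trial_reproducibility(
    traces_a: TraceSet,
    traces_b: TraceSet,
    neurons: Sequence[int],
    params: SlidingParams = SlidingParams(),
    denoise_window_s: float = 1.0,
) -> WindowSeries:
    """Average sliding max cross-correlation over a cohort of neurons.

    Traces are moving-average denoised before the window analysis.  Returns
    a WindowSeries whose ``max_corr``/``lag`` are cohort means.
    """
    da = denoise(traces_a, denoise_window_s)
    db = denoise(traces_b, denoise_window_s)
    series = [
        sliding_xcorr(da.data[n], db.data[n], params) for n in neurons
    ]
    return WindowSeries(
        max_corr=np.mean([s.max_corr for s in series], axis=0),
        lag=np.mean([s.lag for s in series], axis=0),
        window_starts=series[0].window_starts,
    )


def ridge_readout(states: np.ndarray, target: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge weights w = (X^T X + lambda I)^(-1) X^T y."""
    X = np.asarray(states, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("states must be (samples, features) aligned with target")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("states/target contain non-finite values")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    g = X.T @ X + lam * np.eye(X.shape[1])
    if lam == 0.0:
        if np.linalg.matrix_rank(g) < g.shape[0]:
            raise np.linalg.LinAlgError("X^T X is singular and lambda is zero")
    return np.linalg.solve(g, X.T @ y)


def select_responsive(
    traces: TraceSet,
    input_seq: InputSequence,
    k: int = 10,
    rise_tau: float = 0.05,
    decay_tau: float = 0.6,
) -> np.ndarray:
    """Indices of the k neurons most responsive to the light input.

    Responsiveness is the covariance between each dF/F trace and the
    illumination envelope filtered with the calcium impulse response: a
    matched filter for stimulus-locked transients that weights response
    amplitude, so sparse all-or-none responders rank above weakly but
    continuously co-active neurons.
    """
    from . import kernels

    on = input_seq.active(traces.times).astype(float)
    if on.sum() == 0 or (on == 1).all():
        raise ValueError("input must contain both illuminated and dark samples")
    kern = kernels.evaluate_kernel(
        np.arange(0.0, 5 * decay_tau, 1.0 / traces.sample_rate), rise_tau, decay_tau
    )
    ref = np.convolve(on, kern)[: traces.n_samples]
    refz = (ref - ref.mean()) / ref.std()
    data = traces.data
    dev = data - data.mean(axis=1, keepdims=True)
    score = (dev @ refz) / traces.n_samples
    return np.argsort(-score)[:k]


def denoise(traces: TraceSet, window_s: float = 1.0) -> TraceSet:
    """Moving-average smoothing of each trace (the package's denoiser)."""
    win = max(1, int(round(window_s * traces.sample_rate)))
    return TraceSet(
        data=uniform_filter1d(traces.data, size=win, axis=1, mode="nearest"),
        sample_rate=traces.sample_rate,
    )


def memory_profile(
    traces,
    input_seq: InputSequence,
    delays: Optional[np.ndarray] = None,
    lam: float = 0.01,
    eval_mode: str = "crossfit",
    noise_floor: float = 0.01,
) -> MemoryResult:
    """Memory function f_tau, capacity MC and fitted decay constant.

    The input symbols are upsampled to the trace grid by zero-order hold.
    For each delay a ridge readout reconstructing v(t - tau) from x(t) is
    evaluated as the squared Pearson correlation between reconstruction and
    true delayed input.  ``eval_mode="crossfit"`` (default) fits on each
    half of the recording and scores on the other, averaging the two
    fold-wise correlations, which keeps f_tau free of the upward in-sample
    bias of order n_features / n_samples; ``eval_mode="insample"`` scores on
    the training samples instead.

    f_tau is evaluated on the full delay grid (default 0.1-3.0 s in 0.1-s
    steps) for the decay fit, but the capacity ``mc`` sums f_tau only over
    *symbol-aligned* delays (multiples of the input's symbol period): with
    zero-order-hold upsampling, sub-symbol delays reconstruct the same
    input symbol and would be multiply counted.  The sum over the full grid
    is also reported as ``mc_grid``.  The decay constant is a least-squares
    line fit to log f_tau from the peak of f_tau onward, restricted to
    values above ``noise_floor``.
    """
    if eval_mode not in ("crossfit", "insample"):
        raise ValueError("eval_mode must be 'crossfit' or 'insample'")
    X = traces.data.T if isinstance(traces, TraceSet) else np.asarray(traces, dtype=float)
    rate = traces.sample_rate if isinstance(traces, TraceSet) else 10.0
    if delays is None:
        delays = np.round(np.arange(0.1, 3.0 + 1e-9, 0.1), 10)
    v = input_seq.on_grid(np.arange(X.shape[0]) / rate)
    if v.std() <= 1e-12:
        raise ValueError("constant input: memory function undefined")

    f_tau: dict = {}
    weights: dict = {}
    for tau in delays:
        d = int(round(tau * rate))
        if d >= X.shape[0] - 4:
            raise ValueError("delay grid exceeds the record length")
        Xd = X[d:]
        yd = v[: X.shape[0] - d]
        n = Xd.shape[0]
        if eval_mode == "insample":
            w = ridge_readout(Xd, yd, lam)
            f = _pearson(Xd @ w, yd) ** 2
        else:
            half = n // 2
            fs = []
            for tr, te in (((0, half), (half, n)), ((half, n), (0, half))):
                w = ridge_readout(Xd[tr[0]: tr[1]], yd[tr[0]: tr[1]], lam)
                fs.append(_pearson(Xd[te[0]: te[1]] @ w, yd[te[0]: te[1]]) ** 2)
            f = float(np.mean(fs))
            w = ridge_readout(Xd, yd, lam)
        f_tau[float(tau)] = f
        weights[float(tau)] = w

    taus = np.asarray(list(f_tau.keys()))
    vals = np.asarray(list(f_tau.values()))
    period = input_seq.symbol_period
    aligned = np.isclose(np.mod(taus + 1e-9, period), 0, atol=1e-6) | np.isclose(
        np.mod(taus + 1e-9, period), period, atol=1e-6
    )
    mc = float(vals[aligned].sum()) if aligned.any() else float(vals.sum())
    mc_grid = float(vals.sum())

    peak = int(np.argmax(vals))
    sel = np.zeros(vals.size, dtype=bool)
    sel[peak:] = vals[peak:] > noise_floor
    # stop at the first sub-floor delay: beyond it f is estimation noise
    below = np.flatnonzero(~sel[peak:])
    if below.size:
        sel[peak + below[0]:] = False
    if sel.sum() >= 3:
        slope, _ = np.polyfit(taus[sel], np.log(vals[sel]), 1)
        decay = -1.0 / slope if slope < 0 else float("nan")
    else:
        decay = float("nan")
    return MemoryResult(f_tau=f_tau, mc=mc, decay_tau_fit=float(decay),
                        weights=weights, lam=lam, mc_grid=mc_grid)


def fit_memory_decay(results: Sequence[MemoryResult]) -> float:
    """Exponential decay constant fitted to pooled memory functions.

    Mirrors the practice of fitting a single exponential to the memory
    coefficients of several independent experiments: the f_tau profiles are
    averaged per delay, the estimator's noise floor (mean of the last five
    delays, where the memory has decayed) is subtracted, and
    A * exp(-(tau - tau_peak) / theta) is fitted by nonlinear least squares
    from the profile's peak onward.  Returns theta in seconds.
    """
    from scipy.optimize import curve_fit

    taus = np.asarray(list(results[0].f_tau.keys()))
    mean_f = np.mean([list(r.f_tau.values()) for r in results], axis=0)
    floor = mean_f[-5:].mean()
    f = np.clip(mean_f - floor, 1e-5, None)
    # anchor at the first delay reaching 90% of the maximum: robust to a
    # secondary bump from population-event correlations at longer delays
    pk = int(np.argmax(f >= 0.9 * f.max()))
    t0 = taus[pk]
    m = taus >= t0 - 1e-9
    popt, _ = curve_fit(
        lambda t, amp, theta: amp * np.exp(-(t - t0) / theta),
        taus[m], f[m], p0=(max(f[pk], 1e-3), 0.5), maxfev=20000,
    )
    return float(popt[1])
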