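"""Double-exponential calcium impulse response and exact event superposition.

The fluorescence transient evoked by a single spike (or detected event) is
modelled as a difference of exponentials,

    k(t) = A * (exp(-t / tau_d) - exp(-t / tau_r)) / k_peak,   t >= 0,

normalised so that the per-event peak equals ``amplitude``.  Superposition of
many events on a uniform sampling grid is evaluated *exactly* (no binning of
event times) with a pair of first-order recursions, which keeps long
recordings numerically stable.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "kernel_peak_time",
    "kernel_peak_value",
    "evaluate_kernel",
    "superpose",
    "superpose_batch",
]


def _check_taus(rise_tau: float, decay_tau: float) -> None:
    if not (decay_tau > rise_tau > 0):
        raise ValueError(
            f"require decay_tau > rise_tau > 0, got rise={rise_tau}, decay={decay_tau}"
        )


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the maximum of the un-normalised difference of exponentials."""
    _check_taus(rise_tau, decay_tau)
    return np.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)


def kernel_peak_value(rise_tau: float, decay_tau: float) -> float:
    tp = kernel_peak_time(rise_tau, decay_tau)
    return np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)


def evaluate_kernel(
    t: np.ndarray, rise_tau: float, decay_tau: float, amplitude: float = 1.0
) -> np.ndarray:
    """Evaluate the normalised kernel at times ``t`` (zero for t < 0)."""
    _check_taus(rise_tau, decay_tau)
    t = np.asarray(t, dtype=float)
    out = np.where(
        t >= 0.0,
        np.exp(-np.maximum(t, 0.0) / decay_tau) - np.exp(-np.maximum(t, 0.0) / rise_tau),
        0.0,
    )
    return amplitude * out / kernel_peak_value(rise_tau, decay_tau)


def _grid_dt(times: np.ndarray) -> float:
    if times.size < 2:
        return 1.0
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("superposition requires a uniform sampling grid")
    return float(dt[0])


def superpose(
    event_times: np.ndarray,
    times: np.ndarray,
    rise_tau: float,
    decay_tau: float,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Exact kernel superposition of ``event_times`` sampled at ``times``."""
    return superpose_batch([event_times], times, rise_tau, decay_tau, amplitude)[0]


def superpose_batch(
    event_lists,
    times: np.ndarray,
    rise_tau: float,
    decay_tau: float,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Superpose kernels for several event trains at once.

    Parameters
    ----------
    event_lists : sequence of 1-D arrays of event times (seconds)
    times : uniform sampling grid (seconds)

    Returns
    -------
    (n_trains, n_samples) array of noiseless traces.
    """
    _check_taus(rise_tau, decay_tau)
    times = np.asarray(times, dtype=float)
    n = len(event_lists)
    T = times.size
    dt = _grid_dt(times)

    contrib_d = np.zeros((n, T))
    contrib_r = np.zeros((n, T))
    for i, ev in enumerate(event_lists):
        ev = np.asarray(ev, dtype=float)
        if ev.size == 0:
            continue
        ev = ev[ev <= times[-1]]
        if ev.size == 0:
            continue
        idx = np.searchsorted(times, ev, side="left")
        lag = times[idx] - ev  # >= 0 by construction
        np.add.at(contrib_d[i], idx, np.exp(-lag / decay_tau))
        np.add.at(contrib_r[i], idx, np.exp(-lag / rise_tau))

    alpha_d = np.exp(-dt / decay_tau)
    alpha_r = np.exp(-dt / rise_tau)
    d = lfilter([1.0], [1.0, -alpha_d], contrib_d, axis=1)
    r = lfilter([1.0], [1.0, -alpha_r], contrib_r, axis=1)
    return amplitude * (d - r) / kernel_peak_value(rise_tau, decay_tau)
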