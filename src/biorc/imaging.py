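"""Calcium-movie analysis: ROI detection, dF/F extraction, event detection.

ROI detection follows a low-computational-cost cell-detection recipe: the
movie is cut into short chunks, each chunk is detrended with a temporal
moving average, the per-pixel maximum of the residual is contrast-equalised
(CLAHE), binarised with Otsu's threshold and segmented into 4-connected
components, which are then filtered by elliptical-shape criteria
(eccentricity and the component-to-fitted-ellipse area ratio) and merged
across chunks by discarding heavily overlapping detections.

Spike events are detected by sliding a normalised double-exponential
calcium template along each dF/F trace and keeping well-separated local
maxima of the correlation; detected events can be converted back to
noiseless simulated calcium curves for correlation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import percentile_filter, uniform_filter1d
from scipy.signal import find_peaks
from skimage.exposure import equalize_adapthist
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from . import kernels
from .culture import TraceSet

__all__ = [
    "ROI",
    "EventTrain",
    "LccdParams",
    "detect_rois",
    "extract_dff",
    "detect_events",
    "events_to_calcium",
]


@dataclass
class ROI:
    """A detected neuron footprint (4-connected pixel set)."""

    pixels: np.ndarray  # (k, 2) array of (row, col)
    centroid: tuple  # (row, col), float
    area: int
    eccentricity: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.size == 0:
            raise ValueError("ROI pixel set must be non-empty")
        self.area = int(self.pixels.shape[0])

    def pixel_set(self) -> set:
        return set(map(tuple, self.pixels))


@dataclass(frozen=True)
class EventTrain:
    """Strictly increasing event (spike) times for one neuron."""

    times: np.ndarray
    neuron: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class LccdParams:
    chunk_len: int = 100  # frames per chunk
    ma_window: int = 20  # moving-average detrend window, frames
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    ecc_max: float = 0.95
    area_min: int = 4  # pixels
    area_max: int = 400
    overlap_max: float = 0.3  # fraction of a candidate overlapping an accepted ROI
    area_ratio_min: float = 0.5  # component area / fitted-ellipse area

    def __post_init__(self) -> None:
        if not (0 < self.ma_window < self.chunk_len):
            raise ValueError("require 0 < ma_window < chunk_len")
        if not (0 <= self.overlap_max <= 1):
            raise ValueError("overlap_max must lie in [0, 1]")


def _chunk_candidates(chunk: np.ndarray, params: LccdParams) -> list:
    trend = uniform_filter1d(chunk, size=params.ma_window, axis=0, mode="nearest")
    img = (chunk - trend).max(axis=0)
    lo, hi = img.min(), img.max()
    if hi - lo <= 1e-12:
        return []
    norm = (img - lo) / (hi - lo)
    ks = max(8, min(img.shape) // params.clahe_tiles)
    eq = equalize_adapthist(norm, kernel_size=ks, clip_limit=params.clahe_clip)
    if eq.max() - eq.min() <= 1e-12:
        return []
    bw = eq > threshold_otsu(eq)
    lbl = label(bw, connectivity=1)
    out = []
    for rp in regionprops(lbl):
        if not (params.area_min <= rp.area <= params.area_max):
            continue
        if rp.eccentricity > params.ecc_max:
            continue
        if rp.axis_major_length > 0 and rp.axis_minor_length > 0:
            ellipse = np.pi * rp.axis_major_length * rp.axis_minor_length / 4.0
            if rp.area / ellipse < params.area_ratio_min:
                continue
        out.append(
            ROI(
                pixels=rp.coords.copy(),
                centroid=tuple(rp.centroid),
                area=int(rp.area),
                eccentricity=float(rp.eccentricity),
            )
        )
    return out


def detect_rois(stack: np.ndarray, params: LccdParams = LccdParams()) -> list:
    """Detect neuron ROIs in a (frames, rows, cols) image stack.

    Returns an empty list (not an error) for featureless input.  The merge
    step is idempotent: re-detections of the same cell in later chunks
    overlap the accepted footprint and are discarded.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    if stack.shape[0] < params.chunk_len:
        raise ValueError("stack must contain at least chunk_len frames")

    candidates = []
    n_chunks = stack.shape[0] // params.chunk_len
    for c in range(n_chunks):
        chunk = stack[c * params.chunk_len : (c + 1) * params.chunk_len]
        candidates.extend(_chunk_candidates(chunk, params))

    candidates.sort(key=lambda r: (-r.area, r.centroid))
    accepted: list = []
    occupied: set = set()
    for cand in candidates:
        px = cand.pixel_set()
        overlap = len(px & occupied) / len(px)
        if overlap > params.overlap_max:
            continue
        accepted.append(cand)
        occupied |= px
    return accepted


def merge_manual_rois(detected: Sequence[ROI], manual: Sequence[ROI],
                      overlap_max: float = 0.3) -> list:
    """Supplement detections with user-supplied ROIs (skipping duplicates)."""
    out = list(detected)
    occupied = set()
    for r in detected:
        occupied |= r.pixel_set()
    for r in manual:
        px = r.pixel_set()
        if len(px & occupied) / len(px) <= overlap_max:
            out.append(r)
            occupied |= px
    return out


def extract_dff(
    stack: np.ndarray,
    rois: Sequence[ROI],
    percentile: float = 10.0,
    window_s: float = 30.0,
    sample_rate: float = 10.0,
) -> TraceSet:
    """Mean ROI intensity per frame, baselined by a rolling percentile.

    dF/F = (F - F0) / F0 with F0 the rolling ``percentile`` of F over a
    ``window_s`` window.  A non-positive baseline anywhere is an error.
    """
    stack = np.asarray(stack, dtype=float)
    T, H, W = stack.shape
    win = max(1, int(round(window_s * sample_rate)))
    data = np.empty((len(rois), T))
    flat = stack.reshape(T, H * W)
    for i, roi in enumerate(rois):
        r, c = roi.pixels[:, 0], roi.pixels[:, 1]
        if r.min() < 0 or r.max() >= H or c.min() < 0 or c.max() >= W:
            raise ValueError(f"ROI {i} outside frame bounds")
        f = flat[:, r * W + c].mean(axis=1)
        f0 = percentile_filter(f, percentile, size=win, mode="nearest")
        if np.any(f0 <= 0):
            raise ValueError(f"degenerate baseline (F0 <= 0) for ROI {i}")
        data[i] = (f - f0) / f0
    return TraceSet(data=data, sample_rate=sample_rate)


def _template(rise_tau: float, decay_tau: float, length_s: float, rate: float) -> np.ndarray:
    t = np.arange(int(round(length_s * rate))) / rate
    return kernels.evaluate_kernel(t, rise_tau, decay_tau)


def detect_events(
    trace: np.ndarray,
    sample_rate: float = 10.0,
    rise_tau: float = 0.05,
    decay_tau: float = 0.6,
    length_s: float = 2.0,
    corr_threshold: float = 0.85,
    min_separation_s: float = 0.5,
    neuron: int = 0,
) -> EventTrain:
    """Template-correlation event detector.

    Slides a double-exponential calcium template along the trace, computes
    the Pearson correlation at each offset, and emits an event at the onset
    of each local maximum above ``corr_threshold`` separated by at least
    ``min_separation_s``.  An empty train is a legitimate result.
    """
    trace = np.asarray(trace, dtype=float)
    tpl = _template(rise_tau, decay_tau, length_s, sample_rate)
    L = tpl.size
    if trace.size < L:
        raise ValueError("trace shorter than the template")
    tz = tpl - tpl.mean()
    tnorm = np.linalg.norm(tz)

    windows = np.lib.stride_tricks.sliding_window_view(trace, L)
    mu = windows.mean(axis=1, keepdims=True)
    dev = windows - mu
    denom = np.linalg.norm(dev, axis=1) * tnorm
    num = dev @ tz
    corr = np.zeros(num.shape)
    ok = denom > 1e-12
    corr[ok] = num[ok] / denom[ok]

    dist = max(1, int(round(min_separation_s * sample_rate)))
    peaks, _ = find_peaks(corr, height=corr_threshold, distance=dist)
    return EventTrain(times=peaks / sample_rate, neuron=neuron)


def events_to_calcium(
    events: EventTrain,
    duration: float,
    sample_rate: float = 10.0,
    rise_tau: float = 0.05,
    decay_tau: float = 0.6,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Noiseless kernel superposition of an event train on the sampling grid."""
    if len(events) and (events.times.min() < 0 or events.times.max() >= duration):
        raise ValueError("events must lie within [0, duration)")
    n = int(round(duration * sample_rate))
    times = np.arange(n) / sample_rate
    return kernels.superpose(events.times, times, rise_tau, decay_tau, amplitude)
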