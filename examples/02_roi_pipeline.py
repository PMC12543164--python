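"""Detect neurons in a rendered calcium movie and recover their activity.

Renders a synthetic movie of 20 flashing cells, runs the chunked
detrend/CLAHE/Otsu ROI detector, extracts dF/F with a rolling-percentile
baseline, and detects calcium events by template correlation.
"""

import numpy as np

import biorc
from biorc.culture import ActivityRecord
from biorc.imaging import LccdParams, detect_events, detect_rois, extract_dff

rng = np.random.default_rng(11)
n = 20
gx, gy = np.meshgrid(np.linspace(0.12, 0.88, 5), np.linspace(0.12, 0.88, 4))
positions = np.c_[gx.ravel(), gy.ravel()] + rng.uniform(-0.02, 0.02, (n, 2))
spikes = [np.sort(rng.uniform(0, 60.0, rng.integers(20, 40))) for _ in range(n)]
record = ActivityRecord(spike_times=spikes, rates=None, rate_times=None,
                        duration=60.0)
cal = biorc.CalciumParams(amplitude=0.5, noise_sd=0.0, saturation=np.inf)
traces_true = biorc.spikes_to_fluorescence(record, cal, seed=0)
stack = biorc.render_movie(traces_true, positions=positions,
                           frame_shape=(128, 128), baseline_f0=100.0,
                           noise_sd=5.0, seed=3)
print(f"movie: {stack.shape[0]} frames of {stack.shape[1]}x{stack.shape[2]} px")

rois = detect_rois(stack, LccdParams())
print(f"detected {len(rois)} ROIs (ground truth: {n} cells)")

traces = extract_dff(stack, rois)
events = [detect_events(traces.data[i], neuron=i) for i in range(len(rois))]
counts = [len(e) for e in events]
print(f"events per detected cell: median {int(np.median(counts))}, "
      f"range {min(counts)}-{max(counts)}")
print("each event marks one detected calcium transient; the trains feed the "
      "functional-connectivity analysis")
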