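import numpy as np
import pytest

from biorc.culture import (
    CalciumParams,
    CultureParams,
    generate_culture,
    make_binary_input,
    render_movie,
    simulate,
    spikes_to_fluorescence,
    TraceSet,
)


@pytest.fixture(scope="session")
def default_culture():
    """The reference synthetic culture (seed 1)."""
    return generate_culture(CultureParams(seed=1))


@pytest.fixture(scope="session")
def blob_benchmark():
    """Synthetic movie of 20 well-separated flashing cells with ground truth.

    600 frames at 10 Hz, 128x128 px, high SNR: the standard ROI-detection
    benchmark used across the imaging tests.
    """
    rng = np.random.default_rng(11)
    n = 20
    # positions on a jittered grid, well separated
    gx, gy = np.meshgrid(np.linspace(0.12, 0.88, 5), np.linspace(0.12, 0.88, 4))
    positions = np.c_[gx.ravel(), gy.ravel()] + rng.uniform(-0.02, 0.02, (n, 2))
    duration = 60.0
    spikes = [np.sort(rng.uniform(0, duration, rng.integers(20, 40))) for _ in range(n)]
    from biorc.culture import ActivityRecord

    rec = ActivityRecord(spike_times=spikes, rates=None, rate_times=None, duration=duration)
    cal = CalciumParams(amplitude=0.5, noise_sd=0.0, saturation=np.inf)
    traces = spikes_to_fluorescence(rec, cal, seed=0)
    stack = render_movie(
        traces, positions=positions, frame_shape=(128, 128),
        blob_sigma_px=2.0, baseline_f0=100.0, noise_sd=5.0, seed=3,
    )
    return {"stack": stack, "positions": positions, "traces": traces}
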