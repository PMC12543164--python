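"""Synthetic-culture generator and dynamics."""

import numpy as np
import pytest

from biorc import kernels
from biorc.culture import (
    CalciumParams,
    ConfigurationError,
    CultureParams,
    CultureSimulator,
    GeometryError,
    InputSequence,
    IntervalTimeline,
    StimulusPattern,
    generate_culture,
    make_binary_input,
    render_movie,
    simulate,
    spikes_to_fluorescence,
)


#: ring/rectangle geometry scaled for small (<150 neuron) test cultures
SMALL_REGIONS = {
    "left_perception": {"kind": "annulus", "center": (0.5, 0.6),
                        "outer_radius": 0.35, "inner_radius": 0.05},
    "left_execution": {"kind": "rect", "x": (0.05, 0.95), "y": (0.02, 0.2)},
}


class TestGenerateCulture:
    def test_deterministic_per_seed(self):
        a = generate_culture(CultureParams(n_neurons=80, seed=1), regions=SMALL_REGIONS)
        b = generate_culture(CultureParams(n_neurons=80, seed=1), regions=SMALL_REGIONS)
        assert np.array_equal(a.positions, b.positions)
        assert (a.recurrent_weights != b.recurrent_weights).nnz == 0
        for name in a.region_masks:
            assert np.array_equal(a.region_masks[name], b.region_masks[name])

    @pytest.mark.parametrize("target", [0.5, 0.9])
    def test_spectral_radius_rescaled(self, target):
        c = generate_culture(CultureParams(n_neurons=120, seed=3,
                                           spectral_radius_target=target),
                             regions=SMALL_REGIONS)
        rho = np.max(np.abs(np.linalg.eigvals(c.recurrent_weights.toarray())))
        assert rho == pytest.approx(target, abs=1e-6)

    def test_perception_areas_exceed_twenty_neurons(self, default_culture):
        for name in ("left_perception", "right_perception"):
            assert default_culture.region_masks[name].size > 20

    def test_small_perception_area_raises(self):
        regions = {
            "left_perception": {"kind": "annulus", "center": (0.3, 0.7),
                                "outer_radius": 0.04, "inner_radius": 0.02},
        }
        with pytest.raises(ConfigurationError, match="left_perception"):
            generate_culture(CultureParams(n_neurons=100, seed=0), regions=regions)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            CultureParams(n_neurons=1)
        with pytest.raises(ConfigurationError):
            CultureParams(spectral_radius_target=1.2)
        with pytest.raises(ConfigurationError):
            CultureParams(dt_sim=0.0)


class TestBinaryInput:
    def test_degenerate_probabilities(self):
        assert not make_binary_input(50, 0.0, seed=1).symbols.any()
        assert make_binary_input(50, 1.0, seed=1).symbols.all()

    def test_mean_fraction_of_ones(self):
        # Monte-Carlo oracle: across many seeds the fraction of ones is p_on
        fracs = [make_binary_input(240, 0.5, seed=s).symbols.mean()
                 for s in range(10_000)]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.01)

    def test_illumination_window(self):
        seq = InputSequence(symbols=np.array([1, 0, 1]), symbol_period=0.5,
                            on_duration=0.2)
        t = np.array([0.0, 0.1, 0.3, 0.6, 1.0, 1.15, 1.3, 2.0])
        assert list(seq.active(t)) == [True, True, False, False, True, True,
                                       False, False]


class TestSimulate:
    def test_quiescent_without_noise_or_stimulus(self):
        p = CultureParams(n_neurons=60, seed=2, noise_sd=0.0, burst_enabled=False)
        rec = simulate(generate_culture(p, regions=SMALL_REGIONS), [], 5.0, seed=0)
        assert sum(len(ts) for ts in rec.spike_times) == 0

    def test_same_seed_identical_spikes(self, default_culture):
        inp = make_binary_input(20, 0.5, seed=4)
        pat = default_culture.stimulus_for_region("left_perception")
        a = simulate(default_culture, [(pat, inp)], 10.0, seed=9)
        b = simulate(default_culture, [(pat, inp)], 10.0, seed=9)
        for x, y in zip(a.spike_times, b.spike_times):
            assert np.array_equal(x, y)

    def test_ring_response_localized(self, default_culture):
        # in-ring neurons respond > 5x more strongly than distant neurons
        inp = make_binary_input(120, 0.5, seed=5)
        pat = default_culture.stimulus_for_region("left_perception")
        rec = simulate(default_culture, [(pat, inp)], 60.0, seed=5,
                       record_rates=True, rate_stride=10)
        on = inp.active(rec.rate_times)
        ring = default_culture.region_masks["left_perception"]
        d = np.hypot(*(default_culture.positions - np.asarray(pat.center)).T)
        far = np.flatnonzero(d > 2 * pat.outer_radius)
        ratio = rec.rates[ring][:, on].mean() / rec.rates[far][:, on].mean()
        assert ratio > 5.0

    def test_stimulus_outside_unit_square_rejected(self, default_culture):
        bad = StimulusPattern(shape="disc", center=(0.95, 0.5), outer_radius=0.2)
        tl = IntervalTimeline(intervals=((0.0, 1.0),))
        with pytest.raises(GeometryError):
            simulate(default_culture, [(bad, tl)], 2.0, seed=0)

    def test_initial_state_differences_wash_out(self):
        # echo state property by construction: with identical input and
        # noise, trajectories from different initial states converge.  The
        # difference decays immediately, can flare transiently when residual
        # adaptation-phase offsets hit a population event, and is
        # extinguished within a few event cycles.
        p = CultureParams(n_neurons=80, seed=6)
        culture = generate_culture(p, regions=SMALL_REGIONS)
        inp = make_binary_input(80, 0.5, seed=6)
        pat = culture.stimulus_for_region("left_perception")
        for s in range(10):
            rng = np.random.default_rng(s)
            x0a = rng.normal(0, 0.5, 80)
            x0b = rng.normal(0, 0.5, 80)
            ra = simulate(culture, [(pat, inp)], 40.0, seed=s, x0=x0a,
                          record_rates=False, record_states=True, rate_stride=100)
            rb = simulate(culture, [(pat, inp)], 40.0, seed=s, x0=x0b,
                          record_rates=False, record_states=True, rate_stride=100)
            diff = np.vstack([ra.states - rb.states, ra.resources - rb.resources])
            norms = np.linalg.norm(diff, axis=0)
            # fast initial contraction within 2 s ...
            assert norms[2] < 0.2 * norms[0]
            # ... transient flares stay bounded well below the initial gap ...
            assert norms[2:].max() < 0.25 * norms[0]
            # ... and the difference is extinguished by the end
            assert norms[-5:].max() < 0.05 * norms[0]
            assert norms[-1] < 0.02 * norms[0]


class TestFluorescence:
    def test_zero_spikes_zero_trace(self):
        from biorc.culture import ActivityRecord
        rec = ActivityRecord(spike_times=[np.empty(0)] * 3, rates=None,
                             rate_times=None, duration=5.0)
        ts = spikes_to_fluorescence(rec, CalciumParams(noise_sd=0.0), seed=0)
        assert np.all(ts.data == 0)

    def test_single_spike_peak_and_decay_slope(self):
        from biorc.culture import ActivityRecord
        rec = ActivityRecord(spike_times=[np.array([0.0])], rates=None,
                             rate_times=None, duration=6.0)
        cal = CalciumParams(noise_sd=0.0, saturation=np.inf, amplitude=0.2)
        tr = spikes_to_fluorescence(rec, cal, seed=0).data[0]
        t = np.arange(tr.size) / 10.0
        t_peak = t[np.argmax(tr)]
        assert 0.05 <= t_peak <= 0.3
        # post-peak log-linear slope equals -1/decay_tau within 5%
        sel = (t >= 1.0) & (t <= 3.0)
        slope = np.polyfit(t[sel], np.log(tr[sel]), 1)[0]
        assert slope == pytest.approx(-1 / 0.6, rel=0.05)

    def test_linear_superposition_without_saturation(self):
        from biorc.culture import ActivityRecord
        cal = CalciumParams(noise_sd=0.0, saturation=np.inf)
        a = np.array([0.3, 1.7, 2.2])
        b = np.array([0.9, 1.1])
        mk = lambda ev: spikes_to_fluorescence(
            ActivityRecord(spike_times=[ev], rates=None, rate_times=None,
                           duration=5.0), cal, seed=0).data[0]
        union = np.sort(np.concatenate([a, b]))
        assert np.allclose(mk(union), mk(a) + mk(b), atol=1e-12)

    def test_autocorrelation_decay_matches_indicator(self):
        # filtered-Poisson trace: autocorrelation decays with decay_tau
        from biorc.culture import ActivityRecord
        rng = np.random.default_rng(12)
        spikes = [np.sort(rng.uniform(0, 600.0, 1200))]
        cal = CalciumParams(noise_sd=0.0, saturation=np.inf, sample_rate=20.0)
        tr = spikes_to_fluorescence(
            ActivityRecord(spike_times=spikes, rates=None, rate_times=None,
                           duration=600.0), cal, seed=0).data[0]
        x = tr - tr.mean()
        ac = np.correlate(x, x, "full")[x.size - 1:] / np.dot(x, x)
        lags = np.arange(ac.size) / 20.0
        sel = (lags >= 0.2) & (lags <= 1.2)
        tau = -1 / np.polyfit(lags[sel], np.log(ac[sel]), 1)[0]
        assert tau == pytest.approx(0.6, rel=0.10)

    def test_frame_simulator_matches_batch_pipeline_scale(self, default_culture):
        # stepping simulator produces dF/F on the same scale as the batch path
        cal = CalciumParams(noise_sd=0.0)
        sim = CultureSimulator(default_culture, cal, seed=21)
        pat = default_culture.stimulus_for_region("left_perception")
        peaks = []
        for k in range(80):
            dff = sim.step([pat] if k < 5 else [])
            peaks.append(dff.max())
        assert 0.3 < max(peaks) <= cal.saturation + 1e-9


class TestRenderMovie:
    def test_zero_neurons_pure_noise(self):
        from biorc.culture import TraceSet
        ts = TraceSet(data=np.zeros((0, 30)), sample_rate=10.0)
        stack = render_movie(ts, positions=np.zeros((0, 2)), noise_sd=2.0, seed=1)
        assert stack.shape == (30, 128, 128)
        assert abs(stack.mean()) < 0.5 and stack.std() > 1.0

    def test_same_seed_bit_identical(self, blob_benchmark):
        tr, pos = blob_benchmark["traces"], blob_benchmark["positions"]
        a = render_movie(tr, positions=pos, noise_sd=5.0, seed=3)
        b = render_movie(tr, positions=pos, noise_sd=5.0, seed=3)
        assert np.array_equal(a, b)

    def test_separated_blobs_give_expected_local_maxima(self, blob_benchmark):
        from skimage.feature import peak_local_max
        tr, pos = blob_benchmark["traces"], blob_benchmark["positions"]
        clean = render_movie(tr, positions=pos, noise_sd=0.0, seed=0)
        proj = clean.max(axis=0)
        peaks = peak_local_max(proj, min_distance=5,
                               threshold_abs=0.3 * proj.max())
        assert len(peaks) == 20
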