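# Methods

This note documents the models and procedures implemented in `biorc`: what
the synthetic culture does and does not emulate, the analysis pipelines,
the numerical choices, and the known limitations.

## The synthetic culture

The simulator stands in for a dissociated cortical culture expressing an
optogenetic actuator and a red calcium indicator. No mechanistic model of
such a culture is uniquely determined by the recordings the analyses are
built for, so the design goal was the *minimal* dynamics that jointly
reproduce four measured behaviours:

1. responses confined to the illuminated ring (localization ratio ≫ 5
   between in-ring and distant neurons);
2. high trial-to-trial reproducibility of driven activity (sliding-window
   max cross-correlation plateau ≈ 0.95–0.98);
3. *weak linear* short-term memory (memory capacity ≈ 0.13 with an
   f_τ decay constant ≈ 0.6 s);
4. reliable, discriminable left/right responses that a linear FORCE
   readout can steer a car with.

A plain leaky-tanh rate network cannot satisfy (2) and (3) together: any
linear-response reservoir reproducible at the 0.95 level is also linearly
decodable, giving MC ≫ 1. Cultured networks escape this because their
responses are strongly *nonlinear in the input history*: transmission
depresses after each population event and recovers over seconds, so
activity consists of near all-or-none events whose timing is a thresholded
function of many past inputs. The simulator implements exactly that:

```
τ  dx/dt = −x + gate · (W tanh x) + gate · u(t) + q(t) + ξ(t)
rate     = r_max · max(0, tanh x − θ) / (1 − θ)
ds/dt    = (1 − s)/τ_rec − d · (rate/r_max)² · s
dq/dt    = (α u(t) − q)/τ_q
```

with a per-neuron *hysteresis gate*: the gate opens when the synaptic
resource `s` has recovered past 0.75 and shuts when depletion pulls it
below 0.2, after which the neuron is refractory for several seconds
(`τ_rec = 6 s`). Both the optogenetic drive `u` and the recurrent input
pass through the gate (input-side depression), which prevents marginal
noise-seeded cascades from desynchronising repeated trials. A small
residual transmission (`α = 0.085`) through a slow synaptic filter
(`τ_q = 0.3 s`) carries a graded trace of recent input between events —
this is the linear memory channel, and its gain and time constant set MC
and the f_τ decay.

The recurrent weight matrix is sparse Gaussian (connection probability
0.1), rescaled to spectral radius 0.9 (< 1, echo-state property by
construction — the property test checks that state differences between
identically driven runs from different initial states wash out). Spikes
are inhomogeneous Poisson draws from the rectified rates (`r_max`
= 1600 s⁻¹ sets the spike count, and hence the shot noise, of a
population event; the rectification offset θ = 0.1 keeps the quiescent
state silent). Noise and spiking use separate seeded RNG streams so that
the state-noise sequence is identical across runs of the same seed
regardless of how much randomness the rate-dependent spike sampling
consumes.

Fluorescence is the double-exponential indicator response (rise 0.05 s,
decay 0.6 s, per-spike peak ΔF/F = 0.1) evaluated *exactly* (per-interval
exponential recursions, no event binning), passed through a soft indicator
saturation `ΔF/F = S·tanh(linear/S)` with `S = 0.8`, plus Gaussian
measurement noise (σ = 0.03), sampled at 10 Hz. Saturation matters: without
it, population events dominate trace variance ~40:1 and drown both the
memory estimates and the benefit of cohort averaging. The movie renderer
draws each neuron as an isotropic Gaussian blob whose amplitude follows
`F₀(1 + ΔF/F)`; pixel indices are 0-based row-major with x → columns.

Geometry: soma positions are uniform in the unit square; the two
stimulation perception areas are annuli (outer radius 0.2, inner 0.08)
centred at (0.28, 0.72) and (0.72, 0.72); the execution areas are
rectangles in the lower half. Ring membership is a centre-in-annulus test.
Each perception area must contain more than 20 neurons, which the default
geometry guarantees with large margin at n = 350. A slow global drive
oscillation (period drawn from 5–20 s) can be enabled to mimic spontaneous
synchronized bursting qualitatively; it is off by default and for all
quantitative results.

### Calibration

The defaults above were fixed once, by requiring the four behaviours
listed at the top on the fixed default-parameter culture, and then frozen;
they were validated across 8–12 independent input seeds and across
derived-seed batches. The long-run (24 pooled runs) values on the default
culture are: ESP plateau 0.96–0.98, memory-decay constant 0.587 s, memory
capacity 0.143, localization ratio ≈ 20.

## Imaging

ROI detection follows a low-computational-cost recipe: the movie is cut
into 100-frame chunks; each chunk is detrended by a 20-frame temporal
moving average; the per-pixel maximum of the residual is contrast-
equalised (CLAHE), binarised with Otsu's threshold and segmented into
4-connected components; components are kept if eccentricity ≤ 0.95, area
∈ [4, 400] px and component-to-fitted-ellipse area ratio ≥ 0.5; detections
from later chunks that overlap an accepted ROI by more than 30% are
discarded (which makes the merge idempotent). Manually supplied ROIs can
be merged through the same overlap rule. ΔF/F uses a rolling 10th-
percentile baseline over 30 s windows; a non-positive baseline is an
error. Event detection slides a 2-s double-exponential template along the
trace and emits events at local maxima of the Pearson correlation above
0.85, separated by ≥ 0.5 s; it is time-translation equivariant by
construction. Detected events are converted back to noiseless kernel
superpositions for correlation analysis.

## Functional connectivity and graph metrics

The pairwise statistic is the Pearson correlation `CC_ij` of event-derived
calcium curves. For each ordered pair, the null is built by redrawing
train *j*'s event times uniformly over the recording (count preserved)
500 times; the edge `A_ij = 1` iff the observed correlation *strictly
exceeds* the 99th percentile of the null, and the matrix is symmetrised by
OR (a significant direction suffices). Empty trains yield zero
rows/columns with a warning. On independent Poisson trains the realised
edge rate is ~1–2% (two directions OR-combined).

Metrics: global efficiency is the mean inverse shortest-path length with
1/d = 0 for disconnected pairs; modularity is maximised by seeded Louvain
with eight restarts keeping the best-Q partition (this reaches the
exhaustive-search optimum on all ≤ 8-node graphs we test, and makes the
result deterministic per seed); the clustering coefficient is the mean
local value with C(v) = 0 for degree < 2; density is the realised edge
fraction. The importance digraph links each neuron to its *p* most
correlated partners (ties to the lower index) and ranks neurons by
in-degree.

## Reservoir assessment

**ESP.** Two 120-s trials of the fixed default culture are driven by the
same i.i.d. binary sequence (0.5-s symbols, 200 ms light) from different
random initial states. Traces are denoised by a 1-s moving average (the
package's stand-in for a learned denoiser), and for the 10 most
stimulus-responsive neurons (ranked by covariance with the calcium-kernel-
filtered illumination envelope — a matched filter that favours large
stimulus-locked responses) the normalised cross-correlation is maximised
over lags |l| ≤ 50 samples inside 30-s windows stepped by 1 s. The plateau
statistic averages the final 20 windows and the cohort.

**Memory.** For each delay τ on the 0.1–3.0 s grid, a ridge readout
(λ = 0.01, the closed form `W_τ = Y_τᵀX(XᵀX+λI)⁻¹`) reconstructs `v(t−τ)`
(zero-order-hold upsampled) from the state `x(t)` — the 0.5-s-denoised
traces of the 30 most responsive neurons. The larger memory cohort lets
the readout cancel the shared population-event channel while keeping the
graded residual channel. `f_τ` is the squared Pearson correlation computed
by a 2-fold chronological cross-fit (fit on one half, score on the other,
average the folds); the in-sample variant is available but carries an
upward bias of order `n_features/n_samples` per delay, which at this
problem size would swamp the result. MC sums `f_τ` over *symbol-aligned*
delays (0.5, 1.0, …, 3.0 s): with zero-order-hold inputs, sub-symbol
delays reconstruct the same symbol and would be multiply counted (the
conventional capacity definition indexes delays by input symbols); the sum
over the full grid is also reported. The decay constant pools several
independent experiments (the reference protocol uses four 120-s runs):
f_τ profiles are averaged, the estimator's noise floor (mean of the last
five delays) subtracted, and a single exponential fitted from the first
delay reaching 90% of the peak — an anchoring that is robust to the
secondary bump that population-event correlations produce at ~1–2 s.
With four 120-s runs this estimator has a sampling spread of roughly
±0.15 s (decay) and ±0.04 (MC) around the long-run values.

## FORCE learning and the driving task

The two readouts are independent weight/P pairs over 15 randomly chosen
neurons of their execution areas. P is initialised to the identity
(P₀ = I/α, α = 1) and re-symmetrised every 100 updates; the weight update
uses the covariance-updated P (the standard ordering), which guarantees
the post-update error `e⁺ = e⁻/(1 + rᵀPr)`. The readout vector `r(t)` is
the execution neurons' ΔF/F at the 10-Hz frame — the fluorescence *is* the
observable state of this reservoir. Weight initialisation divides
standard-normal draws by `S = p_z·N` exactly as specified (a square-root
variant is available by flag).

Environment constants: speed 1 m/s, obstacle spacing 10 m, trigger
distance 5 m, lane change 1.5 s — chosen so the calcium timescale plus
decision latency fits comfortably inside the avoidance window; all are
configurable. By default each obstacle materialises in the car's occupied
lane at its (single) stimulation trigger, so every encounter is a genuine
avoidance trial: a passive car collides with every obstacle, an oracle
avoids all, and balanced left/right trials emerge from the trajectory of a
working controller. Static lane assignments are available
(`challenge=False`). Success means the car does not occupy the obstacle's
lane when passing it; during a lane change the car occupies the source
lane until the manoeuvre is half complete.

The steering target is a cosine-flanked plateau pulse (1-s rise, hold to
4 s, end at 5 s — the trigger window) that runs its full course even if
the stimulus terminates early. This shape is realisable by the culture's
ramp-and-plateau stimulus response, so trained outputs reach ~0.9–1.0
against the 0.5 half-max decision threshold; narrow pulse targets make the
closed loop self-limit exactly at threshold (the moment the output crosses
0.5, the turn truncates the stimulation and with it the training signal).
The standalone `make_target` builds classic raised-cosine pulses for
offline use. The task assays stimulate at drive amplitude 4.5 (the
ESP/memory assays use 3.0): stimulation power strong enough for robust
activation of the sustained response component.

The 3-phase session freezes weights before and after the learning phase;
the experiment suite re-runs the protocol over grids of readout sizes and
training durations with a fresh culture per seed and fresh random readout
subsets per cell, reporting per-side accuracies and the per-trial
output-to-target integral ratios during learning.

## What the synthetic data does and does not show

The generator emulates the *measurable statistics* of a driven culture —
localized all-or-none responses, trial-to-trial reproducibility, weak
sub-second linear memory, calcium indicator dynamics with saturation and
shot noise — but not its biophysics: there are no conductances, no
excitatory/inhibitory cell types, no synaptic plasticity during a session,
and no channelrhodopsin kinetics or phototoxicity. Passing results
therefore demonstrate that the analysis pipelines and the closed-loop
learning behave correctly on data with the right statistical structure;
they are not evidence about any particular biological culture. The graph
analyses are likewise validated against enumeration oracles on small
graphs and calibrated nulls, not against biological ground truth.

Other known limitations: the memory readout is linear only (no nonlinear
capacity expansions); λ is fixed rather than cross-validated; the event
detector is a single-template correlator, not a deconvolution method;
motion correction and neuropil decontamination are out of scope; courses
with more than two lanes are not modelled.
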