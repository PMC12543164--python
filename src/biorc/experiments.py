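"""Standard assays run on the default synthetic culture.

These functions encode the study conditions used throughout the package:
the echo-state-property trial-pair protocol, the short-term-memory protocol
and the closed-loop obstacle-avoidance protocol, each at its reference
problem size.  They are thin orchestrations of the library modules so that
tests, examples and reproduction scripts all run the identical procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .culture import (
    CalciumParams,
    CultureParams,
    generate_culture,
    make_binary_input,
    simulate,
    spikes_to_fluorescence,
)
from .driving import build_course, run_closed_loop, score
from .force import ForceController
from .reservoir import (
    MemoryResult,
    SlidingParams,
    denoise,
    fit_memory_decay,
    memory_profile,
    select_responsive,
    trial_reproducibility,
)

__all__ = [
    "ESP_COHORT_SIZE",
    "ESP_DENOISE_S",
    "MEMORY_COHORT_SIZE",
    "MEMORY_DENOISE_S",
    "esp_trial_pair",
    "memory_experiment",
    "avoidance_experiment",
]

#: cohort of neurons whose trial-pair correlations quantify the ESP
ESP_COHORT_SIZE = 10
#: moving-average window used to denoise traces before the ESP analysis, s
ESP_DENOISE_S = 1.0
#: state size for the linear memory readout (most stimulus-responsive neurons)
MEMORY_COHORT_SIZE = 30
#: moving-average window used before the memory readout, s
MEMORY_DENOISE_S = 0.5


def _spawn(seed: int, n: int) -> list:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def esp_trial_pair(
    seed: int = 1,
    duration_s: float = 120.0,
    culture_params: Optional[CultureParams] = None,
    calcium: CalciumParams = CalciumParams(),
    drive_amplitude: float = 3.0,
):
    """Drive the culture twice with the same input from different states.

    Returns ``(plateau, window_series, cohort)`` where ``plateau`` is the
    sliding-window maximum cross-correlation averaged over the final 20
    windows and the cohort of the most stimulus-responsive neurons.
    """
    _, s_inp, s_x0, s_t1, s_t2 = _spawn(seed, 5)
    # the reference culture is fixed; the seed steers inputs, initial
    # states and trial noise (repeated trials on one culture, as recorded)
    params = culture_params if culture_params is not None else CultureParams()
    culture = generate_culture(params)
    inp = make_binary_input(int(duration_s / 0.5), 0.5, seed=s_inp)
    pattern = culture.stimulus_for_region("left_perception", drive_amplitude)

    rng = np.random.default_rng(s_x0)
    traces = []
    for trial_seed in (s_t1, s_t2):
        x0 = rng.normal(0.0, 0.3, params.n_neurons)  # fresh random initial state
        rec = simulate(culture, [(pattern, inp)], duration_s, seed=trial_seed,
                       x0=x0, record_rates=False)
        traces.append(spikes_to_fluorescence(rec, calcium, seed=trial_seed))

    cohort = select_responsive(traces[0], inp, ESP_COHORT_SIZE)
    series = trial_reproducibility(
        traces[0], traces[1], cohort, SlidingParams(), denoise_window_s=ESP_DENOISE_S
    )
    plateau = float(series.max_corr[-20:].mean())
    return plateau, series, cohort


def memory_experiment(
    seed: int = 1,
    n_runs: int = 4,
    duration_s: float = 120.0,
    culture_params: Optional[CultureParams] = None,
    calcium: CalciumParams = CalciumParams(),
    lam: float = 0.01,
    drive_amplitude: float = 3.0,
):
    """Memory function, capacity and pooled decay constant over seeded runs.

    Each run drives the default culture with a fresh 120-s i.i.d. binary
    input, computes f_tau by ridge readout (lambda = 0.01) over the
    0.1-3.0 s delay grid from the most stimulus-responsive neurons, and
    sums the symbol-aligned values into MC.  A single exponential is fitted
    to the pooled memory functions of all runs.

    Returns ``(results, mc_mean, decay_s)``.
    """
    params = culture_params if culture_params is not None else CultureParams()
    culture = generate_culture(params)  # one fixed culture, repeatedly probed
    run_seeds = _spawn(seed, n_runs)
    results: list = []
    for rs in run_seeds:
        _, s_inp, s_x0, s_trial = _spawn(rs, 4)
        inp = make_binary_input(int(duration_s / 0.5), 0.5, seed=s_inp)
        pattern = culture.stimulus_for_region("left_perception", drive_amplitude)
        x0 = np.random.default_rng(s_x0).normal(0.0, 0.3, params.n_neurons)
        rec = simulate(culture, [(pattern, inp)], duration_s, seed=s_trial,
                       x0=x0, record_rates=False)
        traces = spikes_to_fluorescence(rec, calcium, seed=s_trial)
        cohort = select_responsive(traces, inp, MEMORY_COHORT_SIZE)
        state = denoise(traces, MEMORY_DENOISE_S).select(cohort)
        results.append(memory_profile(state, inp, lam=lam))
    mc_mean = float(np.mean([r.mc for r in results]))
    decay = fit_memory_decay(results)
    return results, mc_mean, decay


def avoidance_experiment(
    seed: int = 1,
    n_seeds: int = 5,
    n_readout: int = 15,
    train_s: float = 150.0,
    before_s: float = 20.0,
    min_encounters: int = 40,
    culture_params: Optional[CultureParams] = None,
    calcium: CalciumParams = CalciumParams(),
    drive_amplitude: float = 4.5,
):
    """Closed-loop obstacle avoidance at the reference conditions.

    For each seed: fresh culture, fresh readouts over ``n_readout`` random
    execution-area neurons per side, 3-phase protocol (before / FORCE
    learning / fixed weights) with at least ``min_encounters`` fixed-weight
    encounters.  Returns ``(reports, mean_accuracy)``.
    """
    reports = []
    for run_seed in _spawn(seed, n_seeds):
        s_cult, s_sub, s_ctrl, s_course, s_loop = _spawn(run_seed, 5)
        params = culture_params if culture_params is not None else CultureParams(seed=s_cult)
        culture = generate_culture(params)
        rng = np.random.default_rng(s_sub)
        left = rng.choice(culture.region_masks["left_execution"], n_readout, replace=False)
        right = rng.choice(culture.region_masks["right_execution"], n_readout, replace=False)
        controller = ForceController(left, right, seed=s_ctrl)
        fixed_s = min_encounters * 10.0 + 10.0
        total_s = before_s + train_s + fixed_s
        course = build_course(int(np.ceil(total_s / 10.0)) + 1, seed=s_course)
        log = run_closed_loop(
            culture, controller, course,
            {"before_s": before_s, "learn_s": train_s, "fixed_s": fixed_s},
            seed=s_loop, calcium=calcium, drive_amplitude=drive_amplitude,
        )
        reports.append(score(log, "fixed"))
    mean_acc = float(np.mean([r.total for r in reports]))
    return reports, mean_acc
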