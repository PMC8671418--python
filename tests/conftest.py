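"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from circamark.actigraphy import fit_hmm
from circamark.synthetic import (
    ActigraphyParams,
    UrineSimParams,
    generate_actigraphy,
    generate_urine_series,
)


@pytest.fixture(scope="session")
def regular_recording():
    """5-day recording with fixed 00:00-08:00 bedtimes and no interruptions."""
    params = ActigraphyParams(
        bed_start=0,
        bed_end=8 * 60,
        bedtime_jitter_sd=0.0,
        night_interruption_rate=0.0,
        start_clock=15 * 60,
    )
    series, states = generate_actigraphy(params, seed=11)
    return params, series, states


@pytest.fixture(scope="session")
def fitted_regular(regular_recording):
    _, series, states = regular_recording
    model = fit_hmm(series, n_restarts=3, seed=0)
    return series, states, model


@pytest.fixture(scope="session")
def default_recording():
    params = ActigraphyParams()
    series, states = generate_actigraphy(params, seed=11)
    return params, series, states


@pytest.fixture()
def study_times():
    return np.array([7, 11, 15, 19, 23, 31, 35, 39, 43, 47], dtype=float)


@pytest.fixture()
def noisy_urine():
    params = UrineSimParams(
        mesor_log=np.log(6.0), amp12_log=0.15, amp24_log=0.3, noise_sd_log=0.1
    )
    return params, generate_urine_series(params, seed=21)
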