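"""Shared fixtures: a small synthetic study (6 vessels, 6 days) reused
across modules, plus its preprocessed matrix."""

import numpy as np
import pytest

from ramcal import (build_design, build_schedule, assign_spike_scheme,
                    generate_dataset, preprocess_pipeline)
from ramcal.synthetic_data import NoiseModel

SMALL_SPIKE_DAYS = frozenset({4, 5, 6})


@pytest.fixture(scope="session")
def small_design():
    return build_design(n_doe=4, n_control=2, seed=7)


@pytest.fixture(scope="session")
def small_records(small_design):
    schedule = build_schedule(n_vessels=6, n_days=6, spike_days=SMALL_SPIKE_DAYS)
    spikes = assign_spike_scheme(small_design, SMALL_SPIKE_DAYS, seed=7)
    return generate_dataset(small_design, schedule=schedule,
                            spike_events=spikes, seed=7)


@pytest.fixture(scope="session")
def noiseless_records(small_design):
    """Same study, all noise sources off: references equal simulated truth."""
    schedule = build_schedule(n_vessels=6, n_days=6, spike_days=SMALL_SPIKE_DAYS)
    spikes = assign_spike_scheme(small_design, SMALL_SPIKE_DAYS, seed=7)
    noise = NoiseModel(detector_sd=0.0, gain_jitter_sd=0.0,
                       reference_cv={}, seed=7)
    return generate_dataset(small_design, noise=noise, schedule=schedule,
                            spike_events=spikes, seed=7)


@pytest.fixture(scope="session")
def small_pre(small_records):
    X, meta, log = preprocess_pipeline(small_records)
    return {"X": X, "meta": meta, "log": log, "axis": small_records[0].axis}
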