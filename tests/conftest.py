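import dataclasses

import numpy as np
import pytest

from proxyshift.chronology import sample_age_models
from proxyshift.ensemble import default_time_grid, simulate_ensemble
from proxyshift.proxies import MeasurementUncertainty
from proxyshift.synthetic import generate_record, lake_preset, marine_preset


@pytest.fixture(scope="session")
def marine_record():
    return generate_record(marine_preset(seed=11))


@pytest.fixture(scope="session")
def lake_record():
    return generate_record(lake_preset(seed=13))


@pytest.fixture(scope="session")
def marine_summaries(marine_record):
    """Age ensemble + per-proxy Monte Carlo summaries at a modest draw count."""
    horizons, series, spec = marine_record
    ages = sample_age_models(horizons, 500, series[0].depth, seed=2)
    grid = default_time_grid(series, ages)
    summaries = [
        simulate_ensemble(s, ages, 500, grid, seed=100 + i)
        for i, s in enumerate(series)
    ]
    return ages, summaries, spec


def exact_truth_spec(spec):
    """A copy of a truth spec with all measurement noise and dating error removed."""
    return dataclasses.replace(
        spec,
        noise_spec={
            k: MeasurementUncertainty(u.mode, 0.0) for k, u in spec.noise_spec.items()
        },
        age_sigma_fn=lambda d: np.zeros_like(np.asarray(d, dtype=float)),
    )
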