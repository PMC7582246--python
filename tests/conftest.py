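"""Shared fixtures: simulated cohorts, trials and segment datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gaitstgp.imu import build_dataset
from gaitstgp.params import make_cohort
from gaitstgp.simulate import simulate_trial


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(3, 3, seed=11)


@pytest.fixture(scope="session")
def zero_noise_trial(small_cohort):
    return simulate_trial(small_cohort[0], "normal", 6, seed=42, noise_scale=0.0)


@pytest.fixture(scope="session")
def noisy_trial(small_cohort):
    return simulate_trial(small_cohort[1], "normal", 6, seed=43, noise_scale=0.05)


@pytest.fixture(scope="session")
def desk_cohort():
    """20 subjects for the desk-scale learning experiments."""
    return make_cohort(10, 10, seed=7)


@pytest.fixture(scope="session")
def desk_dataset(desk_cohort):
    """~600 labeled segments: 20 subjects x 3 paces x 5 strides per side."""
    trials = [
        simulate_trial(p, pace, 5, seed=1000 + 10 * i + j, noise_scale=0.05)
        for i, p in enumerate(desk_cohort)
        for j, pace in enumerate(("slow", "normal", "fast"))
    ]
    dataset, report = build_dataset(trials)
    return dataset, report, trials


@pytest.fixture(scope="session")
def desk_subjects(desk_cohort):
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in desk_cohort],
            "cohort": [p.cohort for p in desk_cohort],
            "laterality": [p.laterality for p in desk_cohort],
        }
    )
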