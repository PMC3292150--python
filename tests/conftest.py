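"""Shared fixtures: session-scoped synthetic trials and derived metrics.

The heavier simulation batteries are computed once per session and reused by
the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from emgfatigue import (
    PAIR_NF_TF,
    dbi_window_sweep,
    extract_all,
    generate_cohort,
    generate_trial,
    imdf,
    rolling_std,
)
from emgfatigue.features import spectro_1d
from emgfatigue.labeling import label_trial
from emgfatigue.preprocess import bandpass_filter, segment_windows
from emgfatigue.simulate import SyntheticConfig


@pytest.fixture(scope="session")
def default_trial():
    """Default-config trial, seed 1, with its ground truth."""
    return generate_trial(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_trial():
    """Noise-free goniometer variant of the default trial, seed 1."""
    return generate_trial(SyntheticConfig(seed=1, noise_sd=0.0))


def battery_metrics(seed: int) -> dict:
    """Per-seed fatigue-direction metrics used by the property batteries."""
    cfg = SyntheticConfig(seed=seed)
    trial, truth = generate_trial(cfg)
    filtered = bandpass_filter(trial.emg[0], trial.fs_emg)
    windows = segment_windows(filtered, trial.fs_emg)
    mdf = np.array([imdf(w, trial.fs_emg) for w in windows])
    phase = np.array([int(lab) for lab in truth.labels])
    unified = spectro_1d(trial)
    uphase = np.array([int(truth.labels[int(t)]) for t in unified.times])
    ss = rolling_std(unified, 3)
    sphase = np.array([int(truth.labels[int(t)]) for t in ss.times])
    sweep = dbi_window_sweep(unified, truth, PAIR_NF_TF, spans=(1, 2, 3, 4, 5))
    return {
        "imdf_nf": mdf[phase == 0].mean(),
        "imdf_f": mdf[phase == 2].mean(),
        "unified_nf": unified.values[uphase == 0].mean(),
        "unified_f": unified.values[uphase == 2].mean(),
        "ss_nf": ss.values[sphase == 0].mean(),
        "ss_tf": ss.values[sphase == 1].mean(),
        "ss_late_f": ss.values[-15:].mean(),
        "dbi": sweep,
    }


@pytest.fixture(scope="session")
def battery20():
    """Fatigue-direction metrics for the 20-seed default battery."""
    return {seed: battery_metrics(seed) for seed in range(1, 21)}


@pytest.fixture(scope="session")
def cohort7():
    """Default 10-subject x 3-trial cohort (seed 7): fuzzy labels + features."""
    cohort = generate_cohort(10, 3, seed=7)
    labeled = [(trial, label_trial(trial)) for trial, _truth in cohort]
    features = [extract_all(trial) for trial, _truth in cohort]
    return labeled, features
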