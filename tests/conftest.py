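"""Shared fixtures: small simulated cohorts and handy signal builders."""

from __future__ import annotations

import numpy as np
import pytest

from hdwear.pipeline import extract_cohort_features
from hdwear.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 6 HD + 6 control cohort, simulated once per session."""
    config = CohortConfig(master_seed=7, n_hd=6, n_control=6)
    manifests, recordings, records = simulate_cohort(config)
    return config, manifests, recordings, records


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Feature table and labels for the small cohort."""
    _, manifests, recordings, records = small_cohort
    X = extract_cohort_features(manifests, recordings)
    groups = np.array([r.group for r in records])
    return X, groups, records


def make_sine(freq_hz: float, fs: float, duration_s: float, amp: float = 1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return t, amp * np.sin(2 * np.pi * freq_hz * t)
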