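"""Shared fixtures: small synthetic cohorts and fitted models.

Everything is generated programmatically at collection time; heavier
fixtures are session-scoped so several tests can share one simulation/fit.
"""

import numpy as np
import pytest

from tdehmm import (EmbeddingConfig, HmmConfig, TimeDelayEmbeddedHMM,
                    default_cohort_spec, simulate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """2-state cohort (5/20 Hz), 6 channels, 100 Hz, 30 s, 2+2 subjects."""
    spec = default_cohort_spec(n_per_group=2, n_channels=6, fs=100.0,
                               duration=30.0, frequencies=(5.0, 20.0),
                               persistence=0.97, seed=3)
    subjects, gt = simulate_cohort(spec)
    return spec, subjects, gt


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """HMM fitted to the small cohort (2 restarts)."""
    spec, subjects, gt = small_cohort
    model = TimeDelayEmbeddedHMM(
        subjects, embedding=EmbeddingConfig(n_lags=15),
        config=HmmConfig(K=2, n_runs=2, max_iterations=40, seed=0))
    return model, model.fit()
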