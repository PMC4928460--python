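"""Shared fixtures: small phantoms and cohorts, generated once per session."""

import numpy as np
import pytest

import slfomap as sm


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast phantom: 16x16x8 grid, 300 timepoints."""
    return sm.PhantomSpec(grid_shape=(16, 16, 8), n_timepoints=300, rng_seed=101)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return sm.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, cardiac-free phantom for exact-recovery checks."""
    return sm.PhantomSpec(
        grid_shape=(16, 16, 8),
        n_timepoints=300,
        noise_sd=0.0,
        cardiac_amplitude_arterial=0.0,
        rng_seed=77,
    )


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    return sm.generate_phantom(clean_spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Four small subjects, preprocessed, with masks and ground truth."""
    from slfomap.pipeline import preprocess_subject

    cfg = sm.AnalysisConfig()
    cohort = sm.generate_cohort(
        4, sm.PhantomSpec(grid_shape=(16, 16, 8), n_timepoints=300), rng_seed=303
    )
    return [(preprocess_subject(s, cfg), m, t) for s, m, t in cohort]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
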