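import numpy as np
import pytest

from ppmspect import CohortConfig, preprocess_pipeline, simulate_cohort

#: coarse grid for tests that do not need the full 36k-point resolution
SMALL_GRID = (0.5, 9.5, 3601)


@pytest.fixture(scope="session")
def default_cohort():
    """The frozen default synthetic cohort (49 preterm / 18 term, seed 1)."""
    config = CohortConfig(seed=1)
    spectra, labels = simulate_cohort(config)
    return config, spectra, labels


@pytest.fixture(scope="session")
def default_binned(default_cohort):
    """Preprocessed (aligned, binned, normalized) default cohort."""
    _, spectra, labels = default_cohort
    binned, shifts = preprocess_pipeline(spectra)
    return binned, labels, shifts


@pytest.fixture()
def small_config():
    """A light cohort configuration for fast unit tests."""
    return CohortConfig(n_preterm=8, n_term=6, grid=SMALL_GRID, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
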