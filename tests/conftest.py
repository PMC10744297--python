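import numpy as np
import pytest

import ramanpipe as rp


@pytest.fixture(scope="session")
def default_grid():
    return rp.build_default_grid()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 500-3200 cm^-1 axis (step 2) for fast end-to-end tests."""
    return rp.SpectralGrid(np.arange(500.0, 3200.0, 2.0))


@pytest.fixture(scope="session")
def default_cohort():
    """The canonical simulated cohort: 22 patients, 442 spectra."""
    return rp.generate_cohort(rp.SimulatorConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort(small_grid):
    """Compact contaminated cohort (8 patients, 80 spectra) on the coarse axis."""
    cfg = rp.SimulatorConfig(n_patients=8, spectra_per_patient_per_class=5,
                             extra_pairs_first_patient=0, seed=11)
    return rp.generate_cohort(cfg, grid=small_grid)


@pytest.fixture
def tiny_cohort():
    """Three handwritten spectra on a 10-point grid, for I/O and plumbing."""
    grid = rp.SpectralGrid(np.arange(500.0, 510.0))
    recs = [
        rp.SpectrumRecord("s1", "pA", 0, np.linspace(1, 2, 10)),
        rp.SpectrumRecord("s2", "pA", 1, np.linspace(2, 1, 10)),
        rp.SpectrumRecord("s3", "pB", 0, np.full(10, 3.25)),
    ]
    return rp.Cohort(grid=grid, records=recs, provenance={"note": "handwritten"})
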