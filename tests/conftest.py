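import numpy as np
import pytest

from ramanclock import CohortSpec, default_band_library, simulate_cohort


@pytest.fixture(scope="session")
def library():
    return default_band_library()


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort at the study's marginals but few replicates."""
    spec = CohortSpec(n_donors=40, replicates_per_donor=3, seed=11)
    donors, spectra = simulate_cohort(spec)
    return spec, donors, spectra


@pytest.fixture(scope="session")
def calibration_donors():
    """Donor records only (no spectra needed) at the full study size."""
    spec = CohortSpec(n_donors=132, replicates_per_donor=1, seed=5)
    donors, _ = simulate_cohort(spec)
    return donors


def make_donors(n=132, seed=0, **kwargs):
    spec = CohortSpec(n_donors=n, replicates_per_donor=1, seed=seed, **kwargs)
    donors, _ = simulate_cohort(spec)
    return donors
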