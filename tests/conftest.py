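import numpy as np
import pandas as pd
import pytest

from rai2ctbp import synthetic


@pytest.fixture(scope="session")
def qpcr_noise_free():
    """Cohorts with zero noise and zero donor spread: exact recovery regime."""
    healthy = synthetic.HealthyDonorSpec(
        gene_mean={"AR": 8.0, "KRT19": 9.0, "RAI2": 10.0},
        gene_sd={"AR": 0.0, "KRT19": 0.0, "RAI2": 0.0},
        n_donors=10,
    )
    specs = [
        synthetic.CohortSpec(
            name="CRPC",
            n_samples=27,
            gene_positive_fraction={"AR": 0.6, "KRT19": 0.4, "RAI2": 0.5},
            positive_shift={"AR": 6.0, "KRT19": 6.0, "RAI2": 6.0},
            missing_rate=0.0,
            noise_sd=0.0,
        ),
        synthetic.CohortSpec(
            name="AVPC",
            n_samples=57,
            gene_positive_fraction={"AR": 0.9, "KRT19": 0.5, "RAI2": 0.3},
            positive_shift={"AR": 6.0, "KRT19": 6.0, "RAI2": 6.0},
            missing_rate=0.0,
            noise_sd=0.0,
        ),
    ]
    return synthetic.gen_qpcr_cohorts(specs, healthy, seed=11), healthy


@pytest.fixture(scope="session")
def profile_set_high_snr():
    spec = synthetic.ProfileSpec(
        coincidence_fraction=0.9, peak_amplitude=100.0, noise_sd=2.0
    )
    return synthetic.gen_line_profiles(spec, seed=7), spec


@pytest.fixture(scope="session")
def small_foci_image():
    spec = synthetic.ImageSpec(
        shape=(16, 64, 64),
        voxel_size=(0.2, 0.1, 0.1),
        n_cells=2,
        foci_per_cell=3,
        focus_radius=0.4,
        amplitude=100.0,
        background=10.0,
        noise_sd=2.0,
    )
    img, truth, mask = synthetic.gen_foci_image(spec, seed=5)
    return img, truth, mask, spec
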