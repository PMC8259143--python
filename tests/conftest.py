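import numpy as np
import pytest

from renalct import phantom, roi


@pytest.fixture(scope="session")
def published_cohort():
    """A tabular cohort drawn at the published calibration (74/31)."""
    return phantom.simulate_cohort(phantom.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def structured_volume():
    """Deterministic phantom with 3 compact patches and 1 vessel arc."""
    spec = phantom.LesionSpec(
        label="ccRCC", diameter_mm=30.0, n_patches=3, patch_contrast_hu=90.0,
        n_vessels=1, cyst_fraction=0.0, pseudocapsule=False,
        tumor_noise_sd=5.0)
    return spec, phantom.simulate_lesion_volume(spec, seed=9)


@pytest.fixture(scope="session")
def homogeneous_volume():
    """Noise-free homogeneous tumor sphere (radius 15 mm)."""
    spec = phantom.LesionSpec(
        label="AML.wovf", diameter_mm=30.0, n_patches=0, n_vessels=0,
        cyst_fraction=0.0, pseudocapsule=False, noise_sd=0.0,
        tumor_noise_sd=0.0)
    return spec, phantom.simulate_lesion_volume(spec, seed=0)


@pytest.fixture
def noise_free_protocol():
    return roi.ProtocolConfig(observer_noise_sd=0.0, seed=0)
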