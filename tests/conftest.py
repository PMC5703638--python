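import numpy as np
import pytest

from cstetquant.calibration import ThresholdSet
from cstetquant.composition import reference_profiles
from cstetquant.scattering import load_cross_sections


@pytest.fixture(scope="session")
def xsec():
    return load_cross_sections()


@pytest.fixture(scope="session")
def table_profiles():
    """Packaged reference number-density profiles (published table values)."""
    return reference_profiles(computed=False)


@pytest.fixture(scope="session")
def computed_profiles():
    """Reference profiles recomputed from counts/psv/formula."""
    return reference_profiles(computed=True)


@pytest.fixture
def measured_thresholds():
    """The five intensity levels of the reference tomogram evaluation."""
    return ThresholdSet(
        granule_peak=0.3,
        granule_inclusive=3.0,
        ribosome_peak=5.3,
        ribosome_inclusive=7.5,
        water=16.0,
    )


@pytest.fixture(scope="session")
def small_phantom():
    """A quick 128^3 phantom at 4 nm voxels with the default study conditions."""
    from cstetquant.phantom import PhantomSpec, generate_phantom

    spec = PhantomSpec(
        shape=(128, 128, 128),
        voxel_size=4.0,
        mito_semi_axes=(180.0, 200.0, 220.0),
        n_ribosomes=150,
        seed=3,
    )
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
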