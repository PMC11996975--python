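import numpy as np
import pytest

from ctiq import (FlatNPS, GaussianMTF, GaussianSSP, PhantomSpec,
                  SyntheticTruth, generate_axial_stack)

PIXEL = 300.0 / 512.0          # in-plane spacing of the emulated grid, mm
NYQUIST = 1.0 / (2.0 * PIXEL)  # in-plane Nyquist frequency, mm^-1


@pytest.fixture(scope="session")
def two_rod_spec() -> PhantomSpec:
    """30-mm rods at +-50 mm offset, 300/50 HU contrasts, in a 300-mm bath."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def tilted_spec() -> PhantomSpec:
    """70-mm centered rod tilted 5 degrees for SSP measurement."""
    return PhantomSpec(rod_diameter_mm=70.0, rod_offsets_mm=((0.0, 0.0),),
                       rod_contrasts_hu=(300.0,), tilt_deg=5.0)


@pytest.fixture(scope="session")
def noiseless_rod_stack(two_rod_spec):
    """One noiseless two-rod slice blurred by a Gaussian MTF (f50 = 0.41)."""
    truth = SyntheticTruth(mtf_model=GaussianMTF(0.41),
                           nps_model=FlatNPS(0.0), seed=0)
    return generate_axial_stack(two_rod_spec, truth, n_slices=1)


@pytest.fixture(scope="session")
def sharp_rod_stack(two_rod_spec):
    """One noiseless two-rod slice with no blur (area-coverage edges)."""
    return generate_axial_stack(two_rod_spec, SyntheticTruth(seed=0), n_slices=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
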