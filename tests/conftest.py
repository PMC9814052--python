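import numpy as np
import pytest

from jfreduce import calibration as cal
from jfreduce import detector_model as dm
from jfreduce.geometry import DetectorGeometry


@pytest.fixture(scope="session")
def module_geometry():
    """Full 512 x 1024 single-module detector at 12.4 keV."""
    return DetectorGeometry.single_module(wavelength_A=1.0)


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced 32 x 64 module for statistics-heavy tests."""
    return DetectorGeometry.single_module(module_rows=32, module_cols=64)


@pytest.fixture(scope="session")
def truth(module_geometry):
    return dm.make_calibration_truth(module_geometry, seed=1)


@pytest.fixture(scope="session")
def small_truth(small_geometry):
    return dm.make_calibration_truth(small_geometry, seed=1)


@pytest.fixture(scope="session")
def constants(truth):
    return cal.build_fixed_point_constants(
        truth.pedestal_true[:, 0], truth.gain_true[:, 0], energy_kev=12.4)


@pytest.fixture(scope="session")
def diffraction_frame(truth, module_geometry):
    """One synthetic diffraction frame plus its injected-spot ground truth."""
    spots = dm.random_spot_table(module_geometry, 50, seed=2,
                                 intensity_range=(100.0, 1000.0))
    return dm.simulate_diffraction_frame(truth, module_geometry, spots,
                                         background_mean=1.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
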