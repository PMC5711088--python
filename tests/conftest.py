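import numpy as np
import pytest

from beamcheck import (PRESETS, ScanCurve, make_commissioning_dataset,
                       make_profile, normalize_profile, resample)


@pytest.fixture(scope="session")
def params6():
    return PRESETS["6x"]


@pytest.fixture()
def trapezoid():
    """Ideal trapezoid profile: flat 100 to |x|=40 mm, linear edges to 0 at 50 mm.

    On the integer grid the 20%/80%/50% levels are hit exactly at
    +/-48, +/-42 and +/-45 mm.
    """
    x = np.arange(-70.0, 71.0)
    v = np.clip((50.0 - np.abs(x)) * 10.0, 0.0, 100.0)
    return ScanCurve(axis="crossline", positions=x, values=v, energy_label="6x",
                     field_x=80.0, field_y=80.0, ssd=1000.0, scan_depth=0.0,
                     collimation="jaw", source="synthetic")


@pytest.fixture(scope="session")
def profile6():
    """Normalized 10x10 cm analytic profile at 100 mm depth on a 1 mm grid."""
    prof = make_profile(PRESETS["6x"], field_x=100.0, depth=100.0)
    return normalize_profile(resample(prof, 1.0))


@pytest.fixture(scope="session")
def identity_dataset(tmp_path_factory):
    """Small single-energy dataset where measured = TPS = VS exactly."""
    root = tmp_path_factory.mktemp("identity") / "ds"
    make_commissioning_dataset(root, seed=7, energies=("6x",), identity=True,
                               n_patients=8, n_planar_cases=2)
    return root


@pytest.fixture(scope="session")
def perturbed_dataset(tmp_path_factory):
    """Small single-energy dataset with the default known discrepancies."""
    root = tmp_path_factory.mktemp("perturbed") / "ds"
    make_commissioning_dataset(root, seed=11, energies=("6x",), n_patients=10,
                               n_planar_cases=2)
    return root
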