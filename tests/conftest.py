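import numpy as np
import pytest
import scipy.ndimage as ndi

import phantomforge as pf

SMALL = dict(shape=(96, 96, 60), spacing=(4.0, 4.0, 4.0))


def lesion_seeds(truth, names=("lesion_v",)):
    """Operator-style seed clicks: the centroid voxel of each lesion mask."""
    out = {}
    for n in names:
        c = np.round(ndi.center_of_mass(truth.masks[n])).astype(int)
        out[n] = [tuple(int(v) for v in c)]
    return out


@pytest.fixture(scope="session")
def patient_scheme():
    return pf.builtin_scheme("patient")


@pytest.fixture(scope="session")
def chest_noiseless():
    """Digital chest with exact per-compartment means (no noise)."""
    spec = pf.DigitalChestSpec(noise_sd=0.0, seed=1, **SMALL)
    return pf.make_digital_chest(spec)


@pytest.fixture(scope="session")
def chest_sd30():
    """Digital chest with uniform 30 HU voxel noise."""
    spec = pf.DigitalChestSpec(noise_sd=30.0, seed=2, **SMALL)
    return pf.make_digital_chest(spec)


@pytest.fixture(scope="session")
def ref_curve():
    return pf.reference_calibration_curve()


@pytest.fixture(scope="session")
def patient_transfer(ref_curve):
    """Phantom transfer HU implied by the printed plan for every compartment."""
    plan = pf.plan_infill({n: pf.PATIENT_HU[n][0] for n in pf.PATIENT_HU}, ref_curve)
    return pf.transfer_from_plan(ref_curve, plan)


@pytest.fixture(scope="session")
def ramp_volume():
    """One voxel per integer HU over the full scheme domain."""
    hu = np.arange(-1024, 2401, dtype=float).reshape(-1, 1, 1)
    return pf.CTVolume(hu, (1.0, 1.0, 1.0))
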