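from datetime import datetime, timedelta

import numpy as np
import pytest

from gaitpet.imaging_io import AcquisitionMeta, LabelMask, VolumeGrid


@pytest.fixture
def spacing_pet():
    """The PET grid geometry: 1.6 x 1.6 mm in-plane, 2.0 mm slices."""
    return (1.6, 1.6, 2.0)


@pytest.fixture
def meta():
    """60-minute uptake, 50 MBq injection, 70 kg subject."""
    t0 = datetime(2019, 1, 1, 9, 0, 0)
    return AcquisitionMeta(
        injected_activity_bq=5.0e7,
        injection_time=t0,
        scan_start_time=t0 + timedelta(minutes=60),
        body_mass_g=70_000.0,
    )


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VolumeGrid(np.asarray(values, dtype=float), spacing, origin)


def make_mask(labels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return LabelMask(np.asarray(labels), spacing, origin)
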