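import numpy as np
import pytest

import cdslm as c


@pytest.fixture(scope="session")
def foam_scope():
    """Small foam specimen in index-mismatched medium (n=1.45 vs air
    detection optics): the standard under-cleared-tissue condition."""
    vol, air = c.make_foam_volume(25.0, 4.0, (64, 96, 96), (1, 1, 3),
                                  seed=2, intensity=400.0)
    scope = c.VirtualScope(
        vol,
        c.LightSheetModel(waist_fwhm_um=10.0, modulation_period_um=16.0),
        c.DetectionModel(depth_of_field_um=10.0, base_blur_sigma_um=1.0,
                         pixel_size_um=1.0, image_shape=(96, 96)),
        c.RefractiveIndexProfile.homogeneous(1.45, 1.0, z_max_um=300.0),
    )
    return scope


@pytest.fixture(scope="session")
def matched_scope():
    """Same foam specimen in an index-matched medium: zero defocus."""
    vol, _ = c.make_foam_volume(25.0, 4.0, (64, 96, 96), (1, 1, 3),
                                seed=2, intensity=400.0)
    return c.VirtualScope(vol, profile=c.RefractiveIndexProfile.matched())


@pytest.fixture
def disk_image():
    """25 well-separated bright disks (radius 5 px) on a dark background."""
    img = np.zeros((200, 200))
    yy, xx = np.mgrid[:200, :200]
    for cy in range(20, 200, 40):
        for cx in range(20, 200, 40):
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 25] = 100.0
    return img
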