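import numpy as np
import pytest

import retperf as rp


@pytest.fixture(scope="session")
def small_network():
    """Deterministic 4+4 vessel network used across tests."""
    return rp.generate_vessel_network(4, 4, seed=1)


@pytest.fixture(scope="session")
def noiseless_scene():
    """One calibrated noiseless scene at the case-arm group means."""
    return rp.build_scene(2.82, 1.0930, 0.47, seed=7)


def gaussian_dip_profile(diameter_um, scale_um_per_px, contrast=0.5,
                         background=1.0, offset_frac=0.31, reach=3.5):
    """Analytic noiseless dark-vessel profile: the independent oracle
    for the FWHM caliper. Sample grid deliberately misaligned with the
    vessel center by ``offset_frac`` of a pixel."""
    sigma = diameter_um / rp.FWHM_PER_SIGMA
    n = int(np.ceil(reach * diameter_um / scale_um_per_px)) + 6
    pos = (np.arange(-n, n + 1) + offset_frac) * scale_um_per_px
    prof = background - background * contrast * np.exp(
        -pos ** 2 / (2 * sigma ** 2)
    )
    return pos, prof
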