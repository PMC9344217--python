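"""Shared fixtures: small rendered scenes and one noiseless volume run."""

import dataclasses

import numpy as np
import pytest

from foveapit import segmentation as seg
from foveapit import synthetic as syn


@pytest.fixture(scope="session")
def default_params() -> syn.VolumeParams:
    return syn.VolumeParams()


@pytest.fixture(scope="session")
def noisy_bscan(default_params):
    """One default-noise pit-slice B-scan with its truth rows."""
    frame, ilm, rpe = syn.generate_bscan(default_params, seed=11)
    return frame, ilm, rpe


@pytest.fixture(scope="session")
def noiseless_params(default_params) -> syn.VolumeParams:
    return dataclasses.replace(default_params, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_volume(noiseless_params):
    return syn.generate_volume(noiseless_params, seed=3)


@pytest.fixture(scope="session")
def noiseless_record(noiseless_volume):
    """Full pipeline run on the noiseless volume (segmentation is slow)."""
    from foveapit.morphometry import quantify_volume

    vol, truth = noiseless_volume
    return quantify_volume(vol), truth


@pytest.fixture(scope="session")
def small_volume_params():
    """A short-frame volume that keeps whole-volume tests cheap."""
    return syn.VolumeParams(height=80, rpe_center_row=60.0, cprt_px=25.0,
                            a_fovea=0.03, a_macula=0.0, noise_sigma=0.1)


def two_band_image(h=64, w=64, r1=20, r2=40, bright=200.0, dark=10.0):
    """Piecewise-constant scan: dark, bright band rows r1..r2, dark."""
    img = np.full((h, w), dark)
    img[r1:r2 + 1] = bright
    return img


@pytest.fixture()
def sharp_scan():
    return two_band_image()
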