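import dataclasses

import numpy as np
import pytest

from utecine import UTE_REFERENCE, acquire, navigator_sigma_for_snr, mouse_heart_phantom
from utecine.phantom import DynamicEllipse, DynamicPhantom


def make_static(phantom: DynamicPhantom) -> DynamicPhantom:
    """Freeze a phantom at its end-diastolic geometry (no motion at all)."""
    ells = [dataclasses.replace(e, semi_axes_es=e.semi_axes_ed,
                                resp_amplitude=(0.0, 0.0), resp_intensity_amp=0.0)
            for e in phantom.ellipses]
    return dataclasses.replace(phantom, ellipses=ells)


@pytest.fixture(scope="session")
def phantom1():
    return mouse_heart_phantom(n_slices=1)


@pytest.fixture(scope="session")
def static_phantom1(phantom1):
    return make_static(phantom1)


@pytest.fixture(scope="session")
def unit_disk():
    """A single centered unit-intensity disk of radius 1.5 mm."""
    return DynamicPhantom(
        ellipses=[DynamicEllipse(center=(0.0, 0.0), semi_axes_ed=(1.5, 1.5),
                                 semi_axes_es=(1.5, 1.5), intensity=1.0)],
        n_slices=1)


@pytest.fixture(scope="session")
def ute_1slice():
    return dataclasses.replace(UTE_REFERENCE, n_slices=1)


@pytest.fixture(scope="session")
def ute_short(ute_1slice):
    """Paper protocol shortened to 40 movie cycles (61 s) for gating tests."""
    return dataclasses.replace(ute_1slice, n_movie_cycles=40)


@pytest.fixture(scope="session")
def acq_short_snr10(phantom1, ute_short):
    """One-slice acquisition at navigator SNR 10, 9840 spokes."""
    sigma = navigator_sigma_for_snr(phantom1, 10.0, slice_index=0)
    return acquire(phantom1, ute_short, noise_sigma=sigma, seed=7)


@pytest.fixture(scope="session")
def acq_static_fullsweep(static_phantom1, ute_1slice):
    """Noiseless fully-sampled (492-spoke) static single sweep."""
    params = dataclasses.replace(ute_1slice, n_projections=492, n_movie_cycles=1)
    return acquire(static_phantom1, params, noise_sigma=0.0, seed=0)
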