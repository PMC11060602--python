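import dataclasses

import pytest

import sarcoscan as sc

#: Optics overrides that make add_noise a no-op in the photon limit.
NOISELESS = dict(photons_per_unit=1e12, background_level=0.0, read_noise_sd=0.0)


def noiseless(optics: sc.OpticalModel, **extra) -> sc.OpticalModel:
    return dataclasses.replace(optics, **NOISELESS, **extra)


@pytest.fixture(scope="session")
def default_image() -> sc.MultiChannelImage:
    """One realistic SIM+nanobody image with ground truth attached."""
    return sc.simulate(sc.DEFAULT_LATTICE, sc.DEFAULT_OPTICS, seed=101)


@pytest.fixture(scope="session")
def clean_image() -> sc.MultiChannelImage:
    """Zero jitter, zero noise, zero blur: the exactly-recoverable case."""
    lat = dataclasses.replace(sc.DEFAULT_LATTICE, length_jitter_sd_nm=0.0)
    opt = noiseless(sc.DEFAULT_OPTICS, psf_fwhm_nm=0.0, linkage_error_nm=0.0)
    return sc.simulate(lat, opt, seed=5)
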