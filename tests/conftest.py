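import numpy as np
import pytest

from bilispec.preprocess import NormalizedSpectrum
from bilispec.spectra import Spectrum


@pytest.fixture
def simple_spectrum():
    """A small strictly-increasing spectrum for I/O and normalization tests."""
    wl = np.arange(340.0, 1061.0, 5.0)
    rng = np.random.default_rng(99)
    return Spectrum("s1", 0.0, wl, rng.uniform(10.0, 5000.0, wl.size))


def make_banded_nspec(assignments, base=1.0, stage="ref_renormalized",
                      ref_wavelength_nm=605.0):
    """A reference-renormalized spectrum with chosen band values.

    ``assignments`` maps (lo_nm, hi_nm) -> value painted onto a 1 nm grid of
    constant ``base``; later assignments win on overlap.
    """
    wl = np.arange(340.0, 1061.0, 1.0)
    vals = np.full(wl.size, base)
    for (lo, hi), v in assignments.items():
        vals[(wl >= lo) & (wl <= hi)] = v
    return NormalizedSpectrum("banded", 0.0, wl, vals, stage,
                              ref_wavelength_nm if stage == "ref_renormalized" else None)


@pytest.fixture
def banded_nspec_factory():
    return make_banded_nspec
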