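"""Spectral preprocessing: min-max normalization, band averages, self-referencing.

The pipeline rescales each spectrum to [0, 1] over its full recorded range
(``I'(l) = (I(l) - Imin) / (Imax - Imin)``), then re-normalizes against the
band-averaged value at a photostable reference wavelength (605 nm by default,
the region where 0- and 15-minute spectra of whole blood coincide).  All
band quantities are arithmetic means over a closed +/-5 nm window, the FWHM of
a typical LED, so the features transfer to LED-based instruments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import Spectrum

__all__ = [
    "BandSpec",
    "NormalizedSpectrum",
    "DegenerateSpectrumError",
    "EmptyBandError",
    "GridMismatchError",
    "ReferenceBandError",
    "minmax_normalize",
    "band_average",
    "renormalize_to_reference",
    "select_reference_band",
    "DEFAULT_REF_CENTER_NM",
    "DEFAULT_BAND_HALF_WIDTH_NM",
    "DEFAULT_CANDIDATE_CENTERS",
]

DEFAULT_REF_CENTER_NM = 605.0
DEFAULT_BAND_HALF_WIDTH_NM = 5.0
#: Candidate reference centers span the chromophore-informative 450-700 nm
#: region; outside it a tungsten-halogen source leaves too few counts for a
#: stability comparison to be meaningful.
DEFAULT_CANDIDATE_CENTERS = tuple(float(c) for c in range(450, 701, 5))


class DegenerateSpectrumError(ValueError):
    """Constant spectrum: Imax == Imin, min-max normalization undefined."""


class EmptyBandError(ValueError):
    """No grid point falls inside the requested wavelength band."""


class GridMismatchError(ValueError):
    """Two spectra that must share a wavelength grid do not."""


class ReferenceBandError(ValueError):
    """Reference band average is zero or negative; cannot self-reference."""


@dataclass(frozen=True)
class BandSpec:
    """A closed wavelength band ``[center - half_width, center + half_width]``."""

    center_nm: float
    half_width_nm: float = DEFAULT_BAND_HALF_WIDTH_NM

    def __post_init__(self) -> None:
        if self.half_width_nm <= 0:
            raise ValueError("half_width_nm must be positive")


@dataclass(frozen=True)
class NormalizedSpectrum:
    """A normalized spectrum; ``stage`` records how far preprocessing went.

    ``stage='minmax'`` values lie in [0, 1] with the extremes attained
    exactly; ``stage='ref_renormalized'`` values are additionally divided by
    the band average at ``ref_wavelength_nm`` so that band averages 1 there.
    """

    sample_id: str
    timepoint_min: float
    wavelengths_nm: np.ndarray
    norm_intensities: np.ndarray
    stage: str
    ref_wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("minmax", "ref_renormalized"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if (self.ref_wavelength_nm is not None) != (self.stage == "ref_renormalized"):
            raise ValueError("ref_wavelength_nm present iff stage='ref_renormalized'")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)


def minmax_normalize(spec: Spectrum) -> NormalizedSpectrum:
    """Rescale intensities to [0, 1] over the full recorded range.

    Raises
    ------
    DegenerateSpectrumError
        If the spectrum is constant (Imax == Imin).
    """
    it = spec.intensities
    imin, imax = float(it.min()), float(it.max())
    if imax == imin:
        raise DegenerateSpectrumError(
            f"{spec.sample_id}: constant spectrum (Imax == Imin == {imax})"
        )
    return NormalizedSpectrum(
        sample_id=spec.sample_id,
        timepoint_min=spec.timepoint_min,
        wavelengths_nm=spec.wavelengths_nm,
        norm_intensities=(it - imin) / (imax - imin),
        stage="minmax",
    )


def _band_mask(wavelengths: np.ndarray, band: BandSpec) -> np.ndarray:
    lo = band.center_nm - band.half_width_nm
    hi = band.center_nm + band.half_width_nm
    return (wavelengths >= lo) & (wavelengths <= hi)


def band_average(nspec: NormalizedSpectrum, band: BandSpec) -> float:
    """Unweighted arithmetic mean of normalized intensity over a closed band."""
    mask = _band_mask(nspec.wavelengths_nm, band)
    if not mask.any():
        raise EmptyBandError(
            f"no grid point in band {band.center_nm}+/-{band.half_width_nm} nm "
            f"(grid covers {nspec.wavelengths_nm[0]:.1f}-{nspec.wavelengths_nm[-1]:.1f} nm)"
        )
    return float(nspec.norm_intensities[mask].mean())


def renormalize_to_reference(nspec: NormalizedSpectrum, ref: BandSpec) -> NormalizedSpectrum:
    """Divide a min-max spectrum by its band average at the reference band.

    The result is self-referenced: its band average at ``ref.center_nm`` is 1,
    making samples comparable independently of overall throughput.
    """
    if nspec.stage != "minmax":
        raise ValueError("renormalize_to_reference expects a stage='minmax' spectrum")
    ref_val = band_average(nspec, ref)
    if ref_val <= 0:
        raise ReferenceBandError(
            f"reference band average at {ref.center_nm} nm is {ref_val}; must be > 0"
        )
    return NormalizedSpectrum(
        sample_id=nspec.sample_id,
        timepoint_min=nspec.timepoint_min,
        wavelengths_nm=nspec.wavelengths_nm,
        norm_intensities=nspec.norm_intensities / ref_val,
        stage="ref_renormalized",
        ref_wavelength_nm=ref.center_nm,
    )


def select_reference_band(
    spec_t0: NormalizedSpectrum,
    spec_t15: NormalizedSpectrum,
    candidate_centers: Sequence[float] = DEFAULT_CANDIDATE_CENTERS,
    half_width: float = DEFAULT_BAND_HALF_WIDTH_NM,
) -> tuple[float, dict[float, float]]:
    """Pick the most photostable candidate band between two timepoints.

    The stability score of a candidate is the mean absolute difference of the
    two min-max-normalized spectra over the grid points in its band; the
    candidate with the minimal score wins, ties going to the lower center.

    Returns
    -------
    (chosen_center, scores)
        The winning center and the score of every candidate.
    """
    if spec_t0.stage != "minmax" or spec_t15.stage != "minmax":
        raise ValueError("select_reference_band expects stage='minmax' spectra")
    if (len(spec_t0) != len(spec_t15)
            or not np.array_equal(spec_t0.wavelengths_nm, spec_t15.wavelengths_nm)):
        raise GridMismatchError("the two spectra are on different wavelength grids")
    if len(candidate_centers) == 0:
        raise ValueError("candidate_centers must be non-empty")

    absdiff = np.abs(spec_t0.norm_intensities - spec_t15.norm_intensities)
    scores: dict[float, float] = {}
    for c in candidate_centers:
        mask = _band_mask(spec_t0.wavelengths_nm, BandSpec(float(c), half_width))
        if not mask.any():
            continue
        scores[float(c)] = float(absdiff[mask].mean())
    if not scores:
        raise EmptyBandError("no candidate band overlaps the wavelength grid")
    best = min(scores, key=lambda c: (scores[c], c))
    return best, scores
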