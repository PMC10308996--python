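"""Synthetic whole-blood transmission spectra with a controllable bilirubin level.

The generator emulates a tungsten-halogen-illuminated microcapillary of
neonatal whole blood via the Beer-Lambert law: a smooth Planck-like source
envelope at ~3000 K multiplied by ``exp(-A(lambda))``, where the absorbance
``A`` is a sum of Gaussian chromophore bands — bilirubin (centered 460 nm,
broad), the heme Soret band (~416.6 nm), oxyhemoglobin (~542.7 and
~578.6 nm), methemoglobin (500-550 nm) and an asymmetric deoxyhemoglobin
pair (645/675 nm).  Detector noise is multiplicative Gaussian.

The bilirubin concentration drives the spectrum three ways, mirroring the
biochemistry the hierarchy exploits: the blue-region bilirubin band scales
with concentration; the 645/675 nm deoxyhemoglobin imbalance grows with
concentration (so the alpha statistic crosses its 0.0125 threshold at
10 mg/dl); and the methemoglobin band switches on above 10 mg/dl (so beta
crosses 0.0014 at 15 mg/dl).  The coupling constants were fixed once by a
numerical sweep at zero noise and are shipped as defaults.

The 15-minute spectrum models photoisomerization (a fractional loss of the
bilirubin band), small per-band strength jitter, and a smooth stray-light
baseline drift.  All temporal perturbations vanish inside a protected
600-610 nm window (and at the spectral extremes the min-max normalization
pins), so the photostable-reference search recovers ~605 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .spectra import SampleRecord, Spectrum, write_manifest, write_spectrum

__all__ = [
    "ChromophoreBand",
    "Coupling",
    "SynthConfig",
    "generate_pair",
    "generate_labeled_cohorts",
    "DEFAULT_FIXED_BANDS",
]

#: Absorbance contribution of bilirubin per mg/dl at its 460 nm band peak.
BILIRUBIN_STRENGTH_PER_MGDL = 0.045
#: Methemoglobin band strength per mg/dl of bilirubin above 10 mg/dl.
MET_COUPLING = 0.15
#: Deoxyhemoglobin 645 nm band strength per mg/dl (asymmetry driver); the
#: value makes the pipeline alpha statistic cross 0.0125 at 10 mg/dl.
DEOXY_COUPLING = 0.0298197  # calibrated; see docs/methods.md
#: Concentration-independent part of the 645 nm deoxyhemoglobin band.
DEOXY_BASE_645 = 0.15
#: Oxyhemoglobin band strengths; scaled so the pipeline beta statistic
#: crosses 0.0014 at 15 mg/dl.
OXY_542_STRENGTH = 1.7958345  # calibrated; see docs/methods.md
OXY_578_STRENGTH = 1.4366676  # calibrated; see docs/methods.md


@dataclass(frozen=True)
class ChromophoreBand:
    """One Gaussian absorbance band: ``strength * exp(-(l-c)^2 / 2 w^2)``."""

    name: str
    center_nm: float
    width_nm: float
    strength: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")

    def profile(self, lam: np.ndarray) -> np.ndarray:
        return np.exp(-((lam - self.center_nm) ** 2) / (2.0 * self.width_nm**2))


DEFAULT_FIXED_BANDS: tuple[ChromophoreBand, ...] = (
    ChromophoreBand("soret", 416.57, 12.0, 2.2),
    ChromophoreBand("oxy_hb_542", 542.71, 10.0, OXY_542_STRENGTH),
    ChromophoreBand("oxy_hb_578", 578.57, 10.0, OXY_578_STRENGTH),
    ChromophoreBand("deoxy_hb_675", 675.0, 13.0, 0.55),
)


@dataclass(frozen=True)
class Coupling:
    """Coefficients tying hemoglobin-state bands to the bilirubin level."""

    met: float = MET_COUPLING
    deoxy: float = DEOXY_COUPLING


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic sample.

    ``noise_sd`` is the multiplicative detector noise; ``drift_amplitude`` is
    the 15-minute stray-light baseline drift as a fraction of the source
    peak; ``band_jitter_sd`` is the relative 15-minute jitter of non-bilirubin
    band strengths.
    """

    bilirubin_mgdl: float = 10.0
    grid_start_nm: float = 340.0
    grid_stop_nm: float = 1060.0
    grid_step_nm: float = 0.2
    source_temperature_K: float = 3000.0
    noise_sd: float = 0.01
    photoisomerization_fraction: float = 0.15
    coupling: Coupling = field(default_factory=Coupling)
    drift_amplitude: float = 0.018
    band_jitter_sd: float = 0.005
    fixed_bands: tuple[ChromophoreBand, ...] = DEFAULT_FIXED_BANDS
    bilirubin_band: ChromophoreBand = ChromophoreBand("bilirubin", 460.0, 35.0, 1.0)
    met_band: ChromophoreBand = ChromophoreBand("met_hb", 525.0, 18.0, 1.0)
    deoxy_band: ChromophoreBand = ChromophoreBand("deoxy_hb_645", 645.0, 13.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step_nm <= 0 or self.grid_stop_nm <= self.grid_start_nm:
            raise ValueError("invalid wavelength grid")
        if self.bilirubin_mgdl <= 0:
            raise ValueError("bilirubin_mgdl must be positive")
        if not 0 <= self.photoisomerization_fraction < 1:
            raise ValueError("photoisomerization_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop_nm - self.grid_start_nm) / self.grid_step_nm)) + 1
        return self.grid_start_nm + self.grid_step_nm * np.arange(n)


def _planck_envelope(lam_nm: np.ndarray, temperature_K: float) -> np.ndarray:
    """Spectral radiance of a blackbody, normalized to peak 1 on the grid."""
    lam_m = lam_nm * 1e-9
    hc_over_k = 1.43877688e-2  # m K
    rad = lam_m**-5 / np.expm1(hc_over_k / (lam_m * temperature_K))
    return rad / rad.max()


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _drift_shape(lam: np.ndarray) -> np.ndarray:
    """Stray-light drift profile: zero in the protected 600-610 nm window,
    zero in the Soret-dip and >= 900 nm regions (where the min-max extremes
    live), smoothly ~1 elsewhere."""
    notch_605 = _smoothstep((np.abs(lam - 605.0) - 7.0) / 5.0)   # 0 on [598, 612]
    notch_soret = _smoothstep((np.abs(lam - 416.57) - 12.0) / 13.0)
    nir_cut = 1.0 - _smoothstep((lam - 860.0) / 40.0)            # 0 beyond 900
    return notch_605 * notch_soret * nir_cut


def _band_strengths(cfg: SynthConfig, *, at_15min: bool,
                    jitter: dict[str, float] | None) -> list[ChromophoreBand]:
    c = cfg.bilirubin_mgdl
    bands = [replace(cfg.bilirubin_band,
                     strength=BILIRUBIN_STRENGTH_PER_MGDL * c
                     * (1.0 - (cfg.photoisomerization_fraction if at_15min else 0.0)))]
    dynamic = [
        replace(cfg.met_band, strength=cfg.coupling.met * max(0.0, c - 10.0)),
        replace(cfg.deoxy_band, strength=DEOXY_BASE_645 + cfg.coupling.deoxy * c),
    ]
    for band in list(cfg.fixed_bands) + dynamic:
        s = band.strength
        if at_15min and jitter is not None:
            s *= 1.0 + jitter.get(band.name, 0.0)
        bands.append(replace(band, strength=max(0.0, s)))
    return bands


def _absorbance(lam: np.ndarray, bands: list[ChromophoreBand]) -> np.ndarray:
    A = np.zeros_like(lam)
    for band in bands:
        if band.strength > 0:
            A += band.strength * band.profile(lam)
    return A


def generate_pair(cfg: SynthConfig) -> tuple[Spectrum, Spectrum]:
    """Generate the 0- and 15-minute spectra of one synthetic sample.

    Both share the source envelope and chromophore model; the 15-minute
    spectrum reduces the bilirubin band by ``photoisomerization_fraction``,
    jitters the other band strengths, and adds the stray-light drift.  All
    randomness derives from ``cfg.seed``.
    """
    lam = cfg.grid()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    envelope = _planck_envelope(lam, cfg.source_temperature_K)

    jitter_names = [b.name for b in cfg.fixed_bands] + [cfg.met_band.name, cfg.deoxy_band.name]
    jitter = {name: float(rng.normal(0.0, cfg.band_jitter_sd)) if cfg.band_jitter_sd > 0 else 0.0
              for name in jitter_names}

    out = []
    for at_15min in (False, True):
        bands = _band_strengths(cfg, at_15min=at_15min, jitter=jitter)
        intensity = envelope * np.exp(-_absorbance(lam, bands))
        if cfg.noise_sd > 0:
            intensity = intensity * (1.0 + rng.normal(0.0, cfg.noise_sd, lam.size))
        if at_15min and cfg.drift_amplitude > 0:
            intensity = intensity + cfg.drift_amplitude * _drift_shape(lam)
        out.append(np.clip(intensity, 0.0, None))
    sid = f"synth-{cfg.seed}"
    return (
        Spectrum(sid, 0.0, lam, out[0]),
        Spectrum(sid, 15.0, lam, out[1]),
    )


def generate_labeled_cohorts(
    n_per_cohort: int,
    seed: int,
    outdir: str | Path | None = None,
    **overrides,
) -> list[SampleRecord]:
    """Generate a labelled synthetic study: n samples per clinical cohort.

    Concentrations are drawn uniformly in (4, 10), (10, 15) and (15, 22)
    mg/dl for the low, medium and high cohorts.  If ``outdir`` is given,
    spectra are written as two-column text files plus a ``manifest.tsv``.
    Keyword overrides are applied to every sample's :class:`SynthConfig`.
    """
    if n_per_cohort < 1:
        raise ValueError("n_per_cohort must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1ab]))
    records: list[SampleRecord] = []
    paths: dict[str, dict[float, str]] = {}
    cohort_ranges = (("low", 4.0, 10.0), ("medium", 10.0, 15.0), ("high", 15.0, 22.0))
    for cohort, lo, hi in cohort_ranges:
        for k in range(n_per_cohort):
            conc = float(rng.uniform(lo, hi))
            sample_seed = int(rng.integers(0, 2**31 - 1))
            cfg = SynthConfig(bilirubin_mgdl=conc, seed=sample_seed, **overrides)
            s0, s15 = generate_pair(cfg)
            sid = f"{cohort}-{k:03d}"
            s0 = Spectrum(sid, 0.0, s0.wavelengths_nm, s0.intensities)
            s15 = Spectrum(sid, 15.0, s15.wavelengths_nm, s15.intensities)
            rec = SampleRecord(sid, conc, {0.0: s0, 15.0: s15})
            records.append(rec)
            if outdir is not None:
                outdir_p = Path(outdir)
                outdir_p.mkdir(parents=True, exist_ok=True)
                p0, p15 = f"{sid}_t0.tsv", f"{sid}_t15.tsv"
                write_spectrum(s0, outdir_p / p0)
                write_spectrum(s15, outdir_p / p15)
                paths[sid] = {0.0: p0, 15.0: p15}
    if outdir is not None:
        write_manifest(records, Path(outdir) / "manifest.tsv", paths)
    return records
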