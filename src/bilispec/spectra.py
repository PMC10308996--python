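"""Spectrum containers and delimited-text I/O.

Spectra arrive as two-column text exports (wavelength in nm, intensity in
detector counts) from visible-range fibre spectrometers, typically covering
340-1060 nm at ~0.2 nm steps.  The dialect is sniffed: tab, comma, semicolon
or whitespace delimiters, an optional single header line, and ``#`` comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "Spectrum",
    "SampleRecord",
    "SpectrumParseError",
    "SpectrumValidationError",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
]


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed into >= 2 valid rows."""


class SpectrumValidationError(ValueError):
    """Raised when parsed or constructed spectral data violate invariants."""


@dataclass(frozen=True)
class Spectrum:
    """A raw transmission spectrum for one sample at one timepoint.

    Parameters
    ----------
    sample_id : str
        Identifier of the blood sample.
    timepoint_min : float
        Minutes since first illumination (typically 0 or 15).
    wavelengths_nm : ndarray
        Strictly increasing wavelength grid in nm.
    intensities : ndarray
        Non-negative detector counts, same length as the grid.
    """

    sample_id: str
    timepoint_min: float
    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise SpectrumValidationError(
                "wavelengths and intensities must be 1-D and of equal length"
            )
        if wl.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumValidationError("wavelengths must be strictly increasing")
        if self.timepoint_min < 0:
            raise SpectrumValidationError("timepoint_min must be non-negative")
        if np.any(it < 0):
            bad = int(np.argmax(it < 0))
            raise SpectrumValidationError(
                f"negative intensity {it[bad]} at {wl[bad]:.1f} nm"
            )

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)


@dataclass
class SampleRecord:
    """One labelled sample: laboratory reference value plus its spectra."""

    sample_id: str
    lab_total_bilirubin_mgdl: float | None = None
    spectra: dict[float, Spectrum] = field(default_factory=dict)
    features: object | None = None
    prediction: object | None = None

    def __post_init__(self) -> None:
        c = self.lab_total_bilirubin_mgdl
        if c is not None and not (0 < c < 50):
            raise SpectrumValidationError(
                f"laboratory total bilirubin {c} mg/dl outside the plausible (0, 50) range"
            )


_DELIMS = ["\t", ",", ";"]
_NUM = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split(line: str) -> list[str]:
    for d in _DELIMS:
        if d in line:
            return [f.strip() for f in line.split(d)]
    return line.split()


def read_spectrum(path: str | Path, sample_id: str, timepoint_min: float) -> Spectrum:
    """Read a two-column delimited spectrum file.

    Lines starting with ``#`` and non-numeric header lines are skipped.
    Duplicate wavelengths are collapsed by averaging their intensities and the
    result is sorted by wavelength.  The timepoint is caller-supplied metadata;
    it is not inferred from the file name.
    """
    path = Path(path)
    wl: list[float] = []
    it: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split(line)
            if len(fields) < 2 or not (_NUM.match(fields[0]) and _NUM.match(fields[1])):
                continue  # header or junk line
            w, i = float(fields[0]), float(fields[1])
            if i < 0:
                raise SpectrumValidationError(
                    f"{path}:{lineno}: negative intensity {i}"
                )
            wl.append(w)
            it.append(i)
    if len(wl) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 valid data rows")
    wla = np.array(wl)
    ita = np.array(it)
    uniq, inv = np.unique(wla, return_inverse=True)
    if uniq.size != wla.size:
        summed = np.zeros_like(uniq)
        counts = np.zeros_like(uniq)
        np.add.at(summed, inv, ita)
        np.add.at(counts, inv, 1.0)
        ita = summed / counts
        wla = uniq
    else:
        order = np.argsort(wla)
        wla, ita = wla[order], ita[order]
    return Spectrum(sample_id, timepoint_min, wla, ita)


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as tab-delimited text with one header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("wavelength_nm\tintensity\n")
        for w, i in zip(spec.wavelengths_nm, spec.intensities):
            fh.write(f"{w:.6f}\t{i:.6f}\n")


_MANIFEST_COLS = ("sample_id", "lab_total_bilirubin_mgdl", "path_t0", "path_t15")


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read a labelled-sample manifest (TSV/CSV) and load its spectra.

    Expected columns: sample_id, lab_total_bilirubin_mgdl, path_t0, path_t15.
    Spectrum paths are resolved relative to the manifest's directory.
    """
    import pandas as pd

    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else None
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    missing = set(_MANIFEST_COLS[:2]) - set(df.columns)
    if missing:
        raise SpectrumParseError(f"{path}: manifest missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        conc = row["lab_total_bilirubin_mgdl"]
        conc = None if (conc is None or (isinstance(conc, float) and np.isnan(conc))) else float(conc)
        spectra: dict[float, Spectrum] = {}
        for col, t in (("path_t0", 0.0), ("path_t15", 15.0)):
            if col in df.columns and isinstance(row[col], str) and row[col]:
                spectra[t] = read_spectrum(path.parent / row[col], sid, t)
        records.append(SampleRecord(sid, conc, spectra))
    return records


def write_manifest(records: list[SampleRecord], path: str | Path,
                   spectrum_paths: Mapping[str, Mapping[float, str]]) -> None:
    """Write a manifest referencing already-written spectrum files."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_MANIFEST_COLS) + "\n")
        for rec in records:
            paths = spectrum_paths.get(rec.sample_id, {})
            conc = "" if rec.lab_total_bilirubin_mgdl is None else repr(rec.lab_total_bilirubin_mgdl)
            fh.write(
                f"{rec.sample_id}\t{conc}\t{paths.get(0.0, '')}\t{paths.get(15.0, '')}\n"
            )
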