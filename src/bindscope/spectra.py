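"""Emission-spectrum data model, titration I/O and signal extraction.

A fluorescence titration follows one protein solution across increasing
ligand concentrations at fixed temperature and excitation wavelength.
The zero-ligand spectrum is the reference ``F0``; the intensity change
``dF = F - F0`` at a fixed analysis wavelength (340 nm by default, the
tryptophan emission region) is the binding observable.  Rayleigh light
scattering (RLS) records use excitation equal to emission (350 nm) and
report relative protein size.

File dialect: UTF-8 delimited text (comma or tab, auto-detected), ``#``
comment lines ignored; first column is wavelength in nm and each further
column one spectrum whose header cell is the ligand concentration in
mol/L.  One file per temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "TitrationSeries",
    "SynchronousRecord",
    "DeltaFSeries",
    "RLSResult",
    "read_titration",
    "write_titration",
    "intensity_at",
    "delta_f_series",
    "rls_intensity",
    "celsius_to_kelvin",
]

DEFAULT_ANALYSIS_WAVELENGTH = 340.0  # nm, tryptophan emission
DEFAULT_RLS_WAVELENGTH = 350.0  # nm, synchronous-scan convention


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15


@dataclass
class EmissionSpectrum:
    """One emission scan at fixed ligand concentration.

    wavelengths are nm (strictly increasing), intensities arbitrary
    fluorescence units, concentration mol/L, temperature K.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_wavelength: float
    temperature: float
    ligand_concentration: float

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("need at least 2 wavelength points")
        if self.wavelengths.size != self.intensities.size:
            raise ValueError("wavelengths and intensities differ in length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("negative fluorescence intensity")
        if self.ligand_concentration < 0:
            raise ValueError("negative ligand concentration")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")


@dataclass
class TitrationSeries:
    """Ordered emission spectra sharing grid, excitation and temperature.

    Exactly one spectrum has ligand concentration zero (the reference);
    concentrations are strictly increasing.
    """

    spectra: list[EmissionSpectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("empty titration series")
        self.spectra = sorted(self.spectra, key=lambda s: s.ligand_concentration)
        first = self.spectra[0]
        for s in self.spectra[1:]:
            if s.excitation_wavelength != first.excitation_wavelength:
                raise ValueError("spectra differ in excitation wavelength")
            if s.temperature != first.temperature:
                raise ValueError("spectra differ in temperature")
            if not np.array_equal(s.wavelengths, first.wavelengths):
                raise ValueError("spectra differ in wavelength grid")
        concs = self.concentrations
        if np.any(np.diff(concs) <= 0):
            raise ValueError(f"duplicate ligand concentrations: {concs.tolist()}")
        if np.count_nonzero(concs == 0.0) != 1:
            raise ValueError("no reference spectrum (exactly one c=0 required)")

    @property
    def excitation_wavelength(self) -> float:
        return self.spectra[0].excitation_wavelength

    @property
    def temperature(self) -> float:
        return self.spectra[0].temperature

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s.ligand_concentration for s in self.spectra])

    @property
    def reference(self) -> EmissionSpectrum:
        return self.spectra[0]


def intensity_at(spectrum: EmissionSpectrum, wavelength: float) -> float:
    """Intensity at ``wavelength``: exact on grid points, else linear
    interpolation between bracketing points.  Raises outside the grid."""
    wl = spectrum.wavelengths
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}] nm"
        )
    return float(np.interp(wavelength, wl, spectrum.intensities))


@dataclass
class DeltaFSeries:
    """Positive dF = F - F0 pairs usable in the double-reciprocal fit,
    with non-positive pairs reported separately."""

    points: list[tuple[float, float]]
    excluded: list[tuple[float, float]]
    wavelength: float
    temperature: float


def delta_f_series(
    series: TitrationSeries,
    wavelength: float = DEFAULT_ANALYSIS_WAVELENGTH,
) -> DeltaFSeries:
    """Extract (concentration, dF) pairs at the analysis wavelength.

    dF = F(c) - F(0).  Pairs with dF <= 0 cannot enter a reciprocal fit
    and are returned in ``excluded``.
    """
    f0 = intensity_at(series.reference, wavelength)
    points: list[tuple[float, float]] = []
    excluded: list[tuple[float, float]] = []
    for s in series.spectra[1:]:
        df = intensity_at(s, wavelength) - f0
        (points if df > 0 else excluded).append((s.ligand_concentration, df))
    return DeltaFSeries(
        points=points,
        excluded=excluded,
        wavelength=wavelength,
        temperature=series.temperature,
    )


@dataclass(frozen=True)
class SynchronousRecord:
    """One synchronous-scan (RLS) intensity reading."""

    ligand_concentration: float
    excitation_wavelength: float
    emission_wavelength: float
    intensity: float


@dataclass
class RLSResult:
    points: list[tuple[float, float]]
    normalized: bool
    wavelength: float


def rls_intensity(
    records: Sequence[SynchronousRecord],
    wavelength: float = DEFAULT_RLS_WAVELENGTH,
) -> RLSResult:
    """Per-concentration scattering intensity at the synchronous wavelength.

    Normalized to the zero-ligand reading when one exists, otherwise the
    raw intensities are returned with ``normalized=False``.
    """
    if not records:
        raise ValueError("no synchronous records")
    for r in records:
        if r.excitation_wavelength != r.emission_wavelength:
            raise ValueError(
                "not a synchronous record: excitation "
                f"{r.excitation_wavelength} nm != emission {r.emission_wavelength} nm"
            )
    recs = sorted(records, key=lambda r: r.ligand_concentration)
    ref = next((r for r in recs if r.ligand_concentration == 0.0), None)
    if ref is not None and ref.intensity > 0:
        pts = [(r.ligand_concentration, r.intensity / ref.intensity) for r in recs]
        return RLSResult(points=pts, normalized=True, wavelength=wavelength)
    pts = [(r.ligand_concentration, r.intensity) for r in recs]
    return RLSResult(points=pts, normalized=False, wavelength=wavelength)


# ---------------------------------------------------------------------------
# titration file I/O


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_titration(
    path: str | Path,
    excitation_wavelength: float,
    temperature: float,
) -> TitrationSeries:
    """Read a titration file (dialect in the module docstring).

    Metadata not stored in the file — excitation wavelength (nm) and
    temperature (K) — is supplied by the caller.  Columns are re-sorted
    by ascending concentration.
    """
    path = Path(path)
    numbered = [
        (i, ln.rstrip("\n"))
        for i, ln in enumerate(path.read_text().splitlines(), start=1)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if len(numbered) < 3:
        raise ValueError(f"{path}: too few rows for a titration file")
    delim = _sniff_delimiter(numbered[0][1])

    hdr_no, hdr = numbered[0]
    hdr_fields = [f.strip() for f in hdr.split(delim)]
    ncol = len(hdr_fields)
    if ncol < 2:
        raise ValueError(f"{path}, line {hdr_no}: need wavelength + >=1 spectrum column")
    try:
        concs = [float(f) for f in hdr_fields[1:]]
    except ValueError as exc:
        raise ValueError(f"{path}, line {hdr_no}: non-numeric concentration header") from exc
    if len(set(concs)) != len(concs):
        raise ValueError(f"{path}, line {hdr_no}: duplicate ligand concentrations")
    if 0.0 not in concs:
        raise ValueError(f"{path}: no reference spectrum (missing c=0 column)")

    rows = np.empty((len(numbered) - 1, ncol))
    for r, (lineno, line) in enumerate(numbered[1:]):
        fields = line.split(delim)
        if len(fields) != ncol:
            raise ValueError(
                f"{path}, line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        try:
            rows[r] = [float(f) for f in fields]
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: non-numeric cell") from exc

    spectra = [
        EmissionSpectrum(
            wavelengths=rows[:, 0],
            intensities=rows[:, j + 1],
            excitation_wavelength=excitation_wavelength,
            temperature=temperature,
            ligand_concentration=c,
        )
        for j, c in enumerate(concs)
    ]
    return TitrationSeries(spectra=spectra)


def write_titration(series: TitrationSeries, path: str | Path, delimiter: str = ",") -> None:
    """Write a titration series in the dialect ``read_titration`` consumes."""
    path = Path(path)
    header = delimiter.join(
        ["wavelength_nm"] + [repr(s.ligand_concentration) for s in series.spectra]
    )
    grid = series.reference.wavelengths
    mat = np.column_stack([grid] + [s.intensities for s in series.spectra])
    lines = [
        f"# excitation_nm={series.excitation_wavelength} temperature_K={series.temperature}",
        header,
    ]
    for row in mat:
        lines.append(delimiter.join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")
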