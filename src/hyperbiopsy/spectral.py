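"""Wavelength grids, chromophore spectra, and spectral design matrices.

The acquisition system scans a discrete, evenly spaced wavelength grid
(510-900 nm in 5 nm steps, 79 bands at most).  Every downstream
operation -- attenuation fitting, Monte Carlo absorption models --
consumes tabulated chromophore spectra resampled onto that grid.

Unit conventions
----------------
Molar species (hemoglobins, cytochrome-c-oxidase redox states,
cytochromes b and c) carry *base-10 molar extinction coefficients* in
mM^-1 cm^-1; water and lipid carry *absorption coefficients* in cm^-1
(their fitted coefficient is a dimensionless volume-fraction
difference).  All attenuation fitting is done in base-10 attenuation
A = -log10 R, so extinction columns enter the design matrix as-is; the
natural-log factor of the Beer-Lambert absorption model is applied only
inside the Monte Carlo absorption composition (see :mod:`hyperbiopsy.mc`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MOLAR_CHROMOPHORES",
    "FRACTION_CHROMOPHORES",
    "WavelengthGrid",
    "ChromophoreSpectrum",
    "SpectralBasis",
    "make_wavelength_grid",
    "resample_spectrum",
    "build_basis",
    "load_spectrum_csv",
    "load_library_manifest",
    "load_literature_library",
]

#: species whose fitted coefficient is a concentration (mM) times pathlength (cm)
MOLAR_CHROMOPHORES = frozenset(
    {"HbO2", "HHb", "oxCCO", "redCCO", "oxCytB", "redCytB", "oxCytC", "redCytC"}
)
#: species whose fitted coefficient is a dimensionless volume-fraction difference
FRACTION_CHROMOPHORES = frozenset({"water", "lipid"})


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced grid of band-center wavelengths in nm."""

    start_nm: float
    stop_nm: float
    step_nm: float
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_bands(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.start_nm == other.start_nm
            and self.stop_nm == other.stop_nm
            and self.step_nm == other.step_nm
        )

    def __hash__(self) -> int:
        return hash((self.start_nm, self.stop_nm, self.step_nm))

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band centered at ``wavelength_nm`` (must be on grid)."""
        offset = (wavelength_nm - self.start_nm) / self.step_nm
        k = int(round(offset))
        if not (0 <= k < self.n_bands) or abs(offset - k) > 1e-9:
            raise ValueError(f"{wavelength_nm} nm is not a band of {self}")
        return k

    def subgrid(self, lo_nm: float, hi_nm: float) -> "WavelengthGrid":
        """Contiguous sub-grid from ``lo_nm`` to ``hi_nm`` inclusive."""
        i0, i1 = self.index_of(lo_nm), self.index_of(hi_nm)
        if i1 < i0:
            raise ValueError("hi_nm must be >= lo_nm")
        return WavelengthGrid(lo_nm, hi_nm, self.step_nm, self.values[i0 : i1 + 1])

    def band_slice(self, lo_nm: float, hi_nm: float) -> slice:
        return slice(self.index_of(lo_nm), self.index_of(hi_nm) + 1)


def make_wavelength_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build an evenly spaced wavelength grid.

    The span must divide evenly by the step; (510, 900, 5) yields the
    full 79-band acquisition grid.
    """
    if step_nm <= 0:
        raise ValueError(f"step_nm must be > 0, got {step_nm}")
    if stop_nm < start_nm:
        raise ValueError(f"stop_nm ({stop_nm}) < start_nm ({start_nm})")
    span = stop_nm - start_nm
    n_steps = round(span / step_nm)
    remainder = span - n_steps * step_nm
    if abs(remainder) > 1e-9:
        raise ValueError(
            f"range {start_nm}-{stop_nm} nm is not divisible by step {step_nm} nm "
            f"(remainder {span % step_nm:g} nm)"
        )
    values = start_nm + step_nm * np.arange(n_steps + 1, dtype=float)
    return WavelengthGrid(float(start_nm), float(stop_nm), float(step_nm), values)


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """A tabulated absorber spectrum.

    ``unit_kind`` is ``"molar_extinction"`` (mM^-1 cm^-1, base 10) for
    molar species and ``"absorption_coefficient"`` (cm^-1) for water and
    lipid.
    """

    name: str
    unit_kind: str
    wavelengths: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("spectrum needs at least two tabulated points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError(f"{self.name}: wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"{self.name}: values must be finite and >= 0")
        if self.unit_kind not in ("molar_extinction", "absorption_coefficient"):
            raise ValueError(f"unknown unit_kind {self.unit_kind!r}")

    def __call__(self, wavelength_nm) -> np.ndarray:
        """Linear interpolation; never extrapolates."""
        lam = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        bad = (lam < lo) | (lam > hi)
        if np.any(bad):
            offending = np.atleast_1d(lam)[np.atleast_1d(bad)]
            raise ValueError(
                f"{self.name}: wavelengths {offending.tolist()} nm outside "
                f"tabulated range [{lo:g}, {hi:g}] nm"
            )
        return np.interp(lam, self.wavelengths, self.values)


def resample_spectrum(spectrum: ChromophoreSpectrum, grid: WavelengthGrid) -> np.ndarray:
    """Piecewise-linear resample of a tabulated spectrum onto ``grid``."""
    return spectrum(grid.values)


@dataclass(frozen=True)
class SpectralBasis:
    """Design matrix for attenuation fitting: bands x chromophores.

    Column order matches ``chromophores``; when ``include_offset`` an
    all-ones column (broadband scattering offset) is appended last.
    """

    chromophores: tuple
    grid: WavelengthGrid
    matrix: np.ndarray = field(repr=False)
    include_offset: bool = False

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.chromophores.index(name)]

    def restricted(self, grid: WavelengthGrid, names: Sequence[str]) -> "SpectralBasis":
        """Basis restricted to a sub-grid and a subset of chromophores."""
        rows = self.grid.band_slice(grid.start_nm, grid.stop_nm)
        cols = [self.chromophores.index(n) for n in names]
        sub = self.matrix[rows][:, cols]
        if self.include_offset:
            sub = np.hstack([sub, np.ones((sub.shape[0], 1))])
        return SpectralBasis(tuple(names), grid, sub, self.include_offset)


def build_basis(
    spectra: Iterable[ChromophoreSpectrum],
    grid: WavelengthGrid,
    include_offset: bool = False,
) -> SpectralBasis:
    """Resample chromophore spectra into a bands x chromophores matrix.

    Extinction tables are assumed base-10, so columns are used as-is and
    the fitted coefficients come out directly in mM*cm (molar species)
    or as dimensionless content differences (water/lipid).
    """
    spectra = list(spectra)
    names = [s.name for s in spectra]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate chromophore names: {dupes}")
    cols = [resample_spectrum(s, grid) for s in spectra]
    if include_offset:
        cols.append(np.ones(grid.n_bands))
    matrix = np.column_stack(cols)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("basis contains non-finite entries")
    return SpectralBasis(tuple(names), grid, matrix, include_offset)


# ---------------------------------------------------------------------------
# CSV library I/O
# ---------------------------------------------------------------------------

def load_spectrum_csv(path, name: str, unit_kind: str) -> ChromophoreSpectrum:
    """Read one ``wavelength_nm,value`` CSV table."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["wavelength_nm", "value"]:
        raise ValueError(f"{path}: expected columns wavelength_nm,value")
    return ChromophoreSpectrum(
        name, unit_kind, df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float)
    )


def load_library_manifest(manifest_path) -> dict:
    """Load a chromophore library from a ``name,unit_kind,path`` manifest CSV.

    Paths are resolved relative to the manifest location.  Returns a dict
    name -> :class:`ChromophoreSpectrum`.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"name", "unit_kind", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"{manifest_path}: manifest needs columns {sorted(required)}")
    library = {}
    for row in df.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        library[row.name] = load_spectrum_csv(p, row.name, row.unit_kind)
    return library


def save_library(library: dict, directory) -> Path:
    """Write a chromophore library as per-spectrum CSVs plus a manifest.

    Returns the manifest path; the layout round-trips through
    :func:`load_library_manifest`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, spec in library.items():
        fname = f"{name.lower()}.csv"
        pd.DataFrame({"wavelength_nm": spec.wavelengths, "value": spec.values}).to_csv(
            directory / fname, index=False
        )
        rows.append({"name": name, "unit_kind": spec.unit_kind, "path": fname})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_literature_library() -> dict:
    """Bundled literature chromophore library (re-tabulated approximations).

    The tables under ``data/literature`` are coarse re-tabulations of the
    standard published compilations for hemoglobin and cytochrome
    extinction and water/lipid absorption, at 2-10 nm spacing over
    500-910 nm; linear interpolation puts them on any acquisition grid
    inside that range.  They capture the landmark band positions and the
    NIR magnitudes to within a few percent, which is adequate for the
    forward optical model; they are not a metrological reference.
    """
    root = importlib.resources.files("hyperbiopsy") / "data" / "literature"
    with importlib.resources.as_file(root / "manifest.csv") as p:
        return load_library_manifest(p)
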