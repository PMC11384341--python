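"""Per-pixel spectral unmixing via the modified Beer-Lambert law (MBLL).

The model: the attenuation difference of a pixel relative to a baseline
spectrum is a linear combination of chromophore extinction/absorption
spectra times concentration (or content) differences and a fixed optical
pathlength,

    dA(lambda) = sum_j E_j(lambda) * dc_j * L   (+ optional constant offset)

solved per pixel by unconstrained ordinary least squares over the bands
of a fitting window.  Coefficients are *differences* against the
baseline and may be negative.  Two standard windows are provided: the
full acquisition range (510-900 nm, ten chromophores including the b and
c cytochromes) and the NIR range (740-900 nm, six chromophores).

Derived biomarkers: total hemoglobin HbT = HbO2 + HHb and differential
cytochrome-c-oxidase diffCCO = oxCCO - redCCO.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import h5py
import numpy as np

from .analysis import Spectrum, attenuation, roi_mean_spectrum
from .hypercube import Hypercube
from .spectral import SpectralBasis, WavelengthGrid

__all__ = [
    "FitWindow",
    "FULL_WINDOW",
    "NIR_WINDOW",
    "ConcentrationMaps",
    "baseline_spectrum",
    "unmix_pixel",
    "unmix_cube",
    "derived_maps",
    "write_maps",
    "read_maps",
]


@dataclass(frozen=True)
class FitWindow:
    """A named wavelength window and its chromophore set."""

    name: str
    lo_nm: float
    hi_nm: float
    chromophores: tuple

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError("window bounds must satisfy lo < hi")


FULL_WINDOW = FitWindow(
    "full", 510.0, 900.0,
    ("HbO2", "HHb", "oxCCO", "redCCO", "oxCytB", "redCytB", "oxCytC", "redCytC", "water", "lipid"),
)
NIR_WINDOW = FitWindow(
    "nir", 740.0, 900.0,
    ("HbO2", "HHb", "oxCCO", "redCCO", "water", "lipid"),
)


@dataclass
class ConcentrationMaps:
    """Fitted per-pixel coefficient maps for one window.

    Molar species are in mM*cm (concentration difference times the unit
    pathlength); water/lipid are dimensionless content differences.  The
    offset map (when fitted) absorbs broadband scattering changes.
    """

    coefficients: Dict[str, np.ndarray]
    rmse: np.ndarray
    window: FitWindow
    baseline: Spectrum
    pathlength_cm: float = 1.0
    offset: Optional[np.ndarray] = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coefficients[name]

    @property
    def spatial_shape(self):
        return self.rmse.shape


def baseline_spectrum(ref_cube: Hypercube, central_fraction: float = 0.10) -> Spectrum:
    """Attenuation of the mean reflectance over a centered square ROI.

    ``central_fraction`` is the fraction of the field-of-view *area*
    covered by the square; 1.0 uses the whole FOV.
    """
    if not 0 < central_fraction <= 1:
        raise ValueError("central_fraction must be in (0, 1]")
    if ref_cube.kind != "reflectance":
        raise ValueError(f"baseline needs a reflectance cube, got {ref_cube.kind!r}")
    rows, cols = ref_cube.spatial_shape
    side_frac = np.sqrt(central_fraction)
    h = max(1, int(round(rows * side_frac)))
    w = max(1, int(round(cols * side_frac)))
    r0 = (rows - h) // 2
    c0 = (cols - w) // 2
    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0 : r0 + h, c0 : c0 + w] = True
    mean_refl = roi_mean_spectrum(ref_cube, mask)
    return attenuation(mean_refl)


def _check_rank(matrix: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(matrix)
    if rank < matrix.shape[1]:
        # name columns involved in the collinearity via tiny singular values
        _, s, vt = np.linalg.svd(matrix, full_matrices=False)
        null = vt[s < s[0] * 1e-10]
        involved = sorted(
            {names[j] if j < len(names) else "offset"
             for row in null for j in np.flatnonzero(np.abs(row) > 1e-6)}
        )
        raise ValueError(f"basis is rank deficient (rank {rank} < {matrix.shape[1]}); "
                         f"collinear columns involve {involved}")


def unmix_pixel(delta_A: np.ndarray, basis: SpectralBasis, pathlength_cm: float = 1.0):
    """Least-squares fit of one attenuation-difference spectrum.

    Returns ``(coefficients, rmse)`` where coefficients follow the basis
    column order (offset last when present) and are already divided by
    the pathlength.
    """
    delta_A = np.asarray(delta_A, dtype=float)
    if delta_A.shape != (basis.matrix.shape[0],):
        raise ValueError(
            f"delta_A length {delta_A.size} != basis band count {basis.matrix.shape[0]}"
        )
    _check_rank(basis.matrix, basis.chromophores)
    scaled, *_ = np.linalg.lstsq(basis.matrix, delta_A, rcond=None)
    resid = delta_A - basis.matrix @ scaled
    rmse = float(np.sqrt(np.mean(resid**2)))
    coeffs = scaled / pathlength_cm
    if basis.include_offset:  # the offset column is not a concentration
        coeffs[-1] = scaled[-1]
    return coeffs, rmse


def unmix_cube(
    att_cube: Hypercube,
    baseline: Spectrum,
    window: FitWindow,
    basis: SpectralBasis,
    pathlength_cm: float = 1.0,
) -> ConcentrationMaps:
    """Unmix every pixel of an attenuation cube against a baseline.

    The cube and baseline share the acquisition grid; both are restricted
    to the window bands, the basis must already be restricted (see
    :meth:`SpectralBasis.restricted`) or built on the window grid with the
    window's chromophore set.  The whole cube is solved in one batched
    least-squares call; missing pixels propagate as NaN maps.
    """
    if att_cube.kind != "attenuation":
        raise ValueError(f"expected an attenuation cube, got {att_cube.kind!r}")
    if att_cube.grid != baseline.grid:
        raise ValueError("cube and baseline are on different grids")
    band_sel = att_cube.grid.band_slice(window.lo_nm, window.hi_nm)
    window_grid = att_cube.grid.subgrid(window.lo_nm, window.hi_nm)
    if basis.grid != window_grid:
        raise ValueError("basis grid does not match the fitting window")
    expected_cols = len(window.chromophores) + (1 if basis.include_offset else 0)
    if tuple(basis.chromophores) != tuple(window.chromophores) or basis.n_columns != expected_cols:
        raise ValueError("basis chromophores do not match the window's set")
    _check_rank(basis.matrix, basis.chromophores)

    rows, cols = att_cube.spatial_shape
    n_bands = window_grid.n_bands
    delta = att_cube.data[:, :, band_sel] - baseline.values[band_sel]
    flat = delta.reshape(-1, n_bands)
    valid = ~np.any(np.isnan(flat), axis=1)

    # one pseudoinverse for the whole cube: coeffs = pinv(B) @ dA
    pinv = np.linalg.pinv(basis.matrix)
    scaled = np.full((flat.shape[0], basis.n_columns), np.nan)
    scaled[valid] = flat[valid] @ pinv.T
    resid = np.full(flat.shape[0], np.nan)
    if valid.any():
        r = flat[valid] - scaled[valid] @ basis.matrix.T
        resid[valid] = np.sqrt(np.mean(r**2, axis=1))

    coeffs = scaled.copy()
    n_chrom = len(window.chromophores)
    coeffs[:, :n_chrom] /= pathlength_cm
    maps = {
        name: coeffs[:, j].reshape(rows, cols)
        for j, name in enumerate(window.chromophores)
    }
    offset_map = coeffs[:, -1].reshape(rows, cols) if basis.include_offset else None
    return ConcentrationMaps(
        coefficients=maps,
        rmse=resid.reshape(rows, cols),
        window=window,
        baseline=baseline,
        pathlength_cm=pathlength_cm,
        offset=offset_map,
    )


def derived_maps(maps: ConcentrationMaps) -> Dict[str, np.ndarray]:
    """Total hemoglobin and differential cytochrome-c-oxidase maps."""
    needed = ("HbO2", "HHb", "oxCCO", "redCCO")
    missing = [n for n in needed if n not in maps.coefficients]
    if missing:
        raise ValueError(f"maps lack required species: {missing}")
    return {
        "HbT": maps["HbO2"] + maps["HHb"],
        "diffCCO": maps["oxCCO"] - maps["redCCO"],
    }


def write_maps(maps: ConcentrationMaps, path) -> None:
    """Write concentration maps to HDF5 (one dataset per species + /rmse)."""
    with h5py.File(path, "w") as f:
        for name, img in maps.coefficients.items():
            f.create_dataset(name, data=img)
        f.create_dataset("rmse", data=maps.rmse)
        if maps.offset is not None:
            f.create_dataset("offset", data=maps.offset)
        f.create_dataset("baseline", data=maps.baseline.values)
        f.create_dataset("baseline_wavelengths_nm", data=maps.baseline.grid.values)
        f.attrs["window"] = maps.window.name
        f.attrs["window_lo_nm"] = maps.window.lo_nm
        f.attrs["window_hi_nm"] = maps.window.hi_nm
        f.attrs["chromophores"] = list(maps.window.chromophores)
        f.attrs["pathlength_cm"] = maps.pathlength_cm
        f.attrs["offset_fitted"] = maps.offset is not None


def read_maps(path) -> ConcentrationMaps:
    from .hypercube import _grid_from_wavelengths

    with h5py.File(path, "r") as f:
        chroms = tuple(str(c) for c in f.attrs["chromophores"])
        window = FitWindow(str(f.attrs["window"]), float(f.attrs["window_lo_nm"]),
                           float(f.attrs["window_hi_nm"]), chroms)
        coeffs = {name: f[name][()] for name in chroms}
        baseline = Spectrum(
            _grid_from_wavelengths(f["baseline_wavelengths_nm"][()]),
            f["baseline"][()], kind="attenuation",
        )
        return ConcentrationMaps(
            coefficients=coeffs,
            rmse=f["rmse"][()],
            window=window,
            baseline=baseline,
            pathlength_cm=float(f.attrs["pathlength_cm"]),
            offset=f["offset"][()] if "offset" in f else None,
        )
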