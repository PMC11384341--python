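"""Hypercube container, reflectance reconstruction, and file I/O.

A hypercube is a ``rows x cols x bands`` stack where each pixel carries a
full spectrum.  Raw acquisitions come as three stacks -- sample intensity
I, white-standard reference W, and dark counts D -- each with its own
camera integration time.  Reflectance is reconstructed per voxel as

    R = (I - (t_I/t_D) D) / ((t_I/t_W) W - (t_I/t_D) D)

which cancels the illumination profile and the camera offset.  Invalid
voxels (non-positive denominator) become NaN and are ignored by all
downstream ROI statistics; values outside the clip range are clipped and
counted, never dropped.

Axis order is fixed as (row, col, band), row 0 at the image top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import tifffile

from .spectral import WavelengthGrid, make_wavelength_grid

__all__ = [
    "Hypercube",
    "CalibrationSet",
    "ClipReport",
    "reconstruct_reflectance",
    "read_hypercube",
    "write_hypercube",
]

KINDS = ("intensity", "white", "dark", "reflectance", "attenuation")
_TIMED_KINDS = ("intensity", "white", "dark")


@dataclass
class Hypercube:
    """A (rows, cols, bands) data cube with its wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid
    kind: str
    integration_time_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (rows, cols, bands), got {self.data.ndim}-D")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.data.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"band dimension {self.data.shape[2]} != grid band count {self.grid.n_bands}"
            )
        if self.kind in _TIMED_KINDS:
            if self.integration_time_ms is None or self.integration_time_ms <= 0:
                raise ValueError(f"{self.kind} cube requires integration_time_ms > 0")

    @property
    def shape(self):
        return self.data.shape

    @property
    def spatial_shape(self):
        return self.data.shape[:2]

    def with_data(self, data: np.ndarray, kind: Optional[str] = None) -> "Hypercube":
        return replace(self, data=data, kind=kind or self.kind)


@dataclass
class CalibrationSet:
    """Intensity/white/dark stacks sharing grid and spatial shape."""

    intensity: Hypercube
    white: Hypercube
    dark: Hypercube

    def __post_init__(self) -> None:
        cubes = (self.intensity, self.white, self.dark)
        for cube, kind in zip(cubes, _TIMED_KINDS):
            if cube.kind != kind:
                raise ValueError(f"expected kind {kind!r}, got {cube.kind!r}")
        shapes = {c.shape for c in cubes}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch between stacks: {sorted(shapes)}")
        grids = {c.grid for c in cubes}
        if len(grids) != 1:
            raise ValueError("intensity/white/dark must share the wavelength grid")

    @property
    def t_I(self) -> float:
        return self.intensity.integration_time_ms

    @property
    def t_W(self) -> float:
        return self.white.integration_time_ms

    @property
    def t_D(self) -> float:
        return self.dark.integration_time_ms


@dataclass(frozen=True)
class ClipReport:
    """Bookkeeping from reflectance reconstruction."""

    n_below: int
    n_above: int
    n_invalid: int
    clip_range: tuple

    @property
    def n_clipped(self) -> int:
        return self.n_below + self.n_above


def reconstruct_reflectance(
    cal: CalibrationSet, clip_range: tuple = (0.0, 1.5)
) -> tuple:
    """Reconstruct the calibrated reflectance cube from raw stacks.

    Dark counts are rescaled by the intensity/dark integration-time ratio
    in both numerator and denominator; the white term by the
    intensity/white ratio.  Returns ``(reflectance_cube, ClipReport)``.
    """
    lo, hi = clip_range
    if not lo < hi:
        raise ValueError(f"clip_range must be increasing, got {clip_range}")
    dark = (cal.t_I / cal.t_D) * cal.dark.data
    denom = (cal.t_I / cal.t_W) * cal.white.data - dark
    numer = cal.intensity.data - dark
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = numer / denom
    invalid = ~(denom > 0) | ~np.isfinite(refl)
    refl[invalid] = np.nan
    n_below = int(np.sum(refl < lo))
    n_above = int(np.sum(refl > hi))
    refl = np.clip(refl, lo, hi)
    cube = Hypercube(refl, cal.intensity.grid, "reflectance")
    return cube, ClipReport(n_below, n_above, int(invalid.sum()), (lo, hi))


# ---------------------------------------------------------------------------
# File formats: multi-page TIFF + JSON sidecar, or HDF5
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _grid_from_wavelengths(wl: np.ndarray) -> WavelengthGrid:
    wl = np.asarray(wl, dtype=float)
    if wl.size == 1:
        return WavelengthGrid(float(wl[0]), float(wl[0]), 1.0, wl)
    steps = np.diff(wl)
    if not np.allclose(steps, steps[0]):
        raise ValueError("stored wavelengths are not evenly spaced")
    return make_wavelength_grid(wl[0], wl[-1], steps[0])


def write_hypercube(cube: Hypercube, path, format: Optional[str] = None) -> None:
    """Write a cube as multi-page TIFF (+ JSON sidecar) or HDF5.

    Format is inferred from the suffix when not given (.tif/.tiff vs
    .h5/.hdf5).  TIFF pages are one per band, in grid order.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    meta = {
        "wavelengths_nm": cube.grid.values.tolist(),
        "kind": cube.kind,
        "integration_time_ms": cube.integration_time_ms,
    }
    if fmt == "tiff":
        # band-major pages: (bands, rows, cols)
        tifffile.imwrite(path, np.moveaxis(cube.data, 2, 0))
        _sidecar_path(path).write_text(json.dumps(meta))
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=cube.data)
            f.create_dataset("wavelengths_nm", data=cube.grid.values)
            f.attrs["kind"] = cube.kind
            if cube.integration_time_ms is not None:
                f.attrs["integration_time_ms"] = cube.integration_time_ms
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_hypercube(path, format: Optional[str] = None) -> Hypercube:
    """Read a cube written by :func:`write_hypercube` (lossless round-trip)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        data = np.moveaxis(tifffile.imread(path), 0, 2)
        if data.ndim == 2:  # single page
            data = data[:, :, None]
        meta = json.loads(_sidecar_path(path).read_text())
        wl = np.asarray(meta["wavelengths_nm"], dtype=float)
        if data.shape[2] != wl.size:
            raise ValueError(
                f"{path}: {data.shape[2]} pages but sidecar lists {wl.size} wavelengths"
            )
        return Hypercube(data, _grid_from_wavelengths(wl), meta["kind"], meta.get("integration_time_ms"))
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            wl = f["wavelengths_nm"][()]
            kind = f.attrs["kind"]
            t = f.attrs.get("integration_time_ms")
        if data.shape[2] != wl.size:
            raise ValueError(
                f"{path}: band dim {data.shape[2]} but {wl.size} stored wavelengths"
            )
        return Hypercube(data, _grid_from_wavelengths(wl), str(kind), None if t is None else float(t))
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")
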