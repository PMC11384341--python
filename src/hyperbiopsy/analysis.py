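"""Attenuation transform, ROI spectra, RMSD, and second spectral derivatives.

Attenuation A = -log10 R is the quantity the linear unmixing model fits;
its second derivative with respect to wavelength sharpens overlapping
absorption peaks (hemoglobin at ~540/560/575 nm and 757 nm, the
cytochrome-c-oxidase bands at 605 and ~840 nm) and suppresses the slowly
varying scattering background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .hypercube import Hypercube
from .spectral import WavelengthGrid

__all__ = ["ROI", "Spectrum", "attenuation", "roi_mean_spectrum", "rmsd", "second_derivative"]


@dataclass
class ROI:
    """A region of interest: boolean mask or (row0, col0, height, width) rect."""

    mask: Optional[np.ndarray] = None
    rect: Optional[tuple] = None
    label: str = ""

    def __post_init__(self) -> None:
        if (self.mask is None) == (self.rect is None):
            raise ValueError("give exactly one of mask or rect")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim != 2:
                raise ValueError("mask must be 2-D")

    def resolve(self, spatial_shape: tuple) -> np.ndarray:
        """Boolean mask for a cube of the given (rows, cols) shape."""
        if self.mask is not None:
            if self.mask.shape != tuple(spatial_shape):
                raise ValueError(
                    f"mask shape {self.mask.shape} != cube spatial shape {tuple(spatial_shape)}"
                )
            mask = self.mask
        else:
            r0, c0, h, w = self.rect
            if h <= 0 or w <= 0 or r0 < 0 or c0 < 0:
                raise ValueError(f"bad rect {self.rect}")
            if r0 + h > spatial_shape[0] or c0 + w > spatial_shape[1]:
                raise ValueError(f"rect {self.rect} exceeds image {tuple(spatial_shape)}")
            mask = np.zeros(spatial_shape, dtype=bool)
            mask[r0 : r0 + h, c0 : c0 + w] = True
        if not mask.any():
            raise ValueError("ROI selects no pixels")
        return mask

    @classmethod
    def from_json(cls, path) -> "ROI":
        spec = json.loads(Path(path).read_text())
        if "rect" in spec:
            return cls(rect=tuple(spec["rect"]), label=spec.get("label", ""))
        if "rle_mask" in spec:
            shape = tuple(spec["rle_mask"]["shape"])
            runs = spec["rle_mask"]["runs"]  # alternating off/on run lengths
            flat = np.zeros(int(np.prod(shape)), dtype=bool)
            pos, on = 0, False
            for run in runs:
                if on:
                    flat[pos : pos + run] = True
                pos += run
                on = not on
            return cls(mask=flat.reshape(shape), label=spec.get("label", ""))
        raise ValueError(f"{path}: need 'rect' or 'rle_mask'")


@dataclass
class Spectrum:
    """A single spectrum on a wavelength grid; NaN marks missing bands."""

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bands,):
            raise ValueError(
                f"values length {self.values.size} != grid band count {self.grid.n_bands}"
            )


def attenuation(cube_or_spectrum, floor: float = 1e-4):
    """Base-10 attenuation A = -log10(max(R, floor)).

    Accepts a reflectance :class:`~hyperbiopsy.hypercube.Hypercube` or a
    reflectance :class:`Spectrum`; NaN (missing) stays NaN.  The floor
    caps attenuation of near-zero reflectance instead of producing
    infinities.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if isinstance(cube_or_spectrum, Hypercube):
        if cube_or_spectrum.kind != "reflectance":
            raise ValueError(f"expected a reflectance cube, got kind {cube_or_spectrum.kind!r}")
        data = cube_or_spectrum.data
        att = -np.log10(np.fmax(data, floor))
        att[np.isnan(data)] = np.nan
        return cube_or_spectrum.with_data(att, kind="attenuation")
    if isinstance(cube_or_spectrum, Spectrum):
        if cube_or_spectrum.kind != "reflectance":
            raise ValueError(f"expected a reflectance spectrum, got kind {cube_or_spectrum.kind!r}")
        vals = cube_or_spectrum.values
        att = -np.log10(np.fmax(vals, floor))
        att[np.isnan(vals)] = np.nan
        return Spectrum(cube_or_spectrum.grid, att, kind="attenuation")
    raise TypeError(f"unsupported input {type(cube_or_spectrum)}")


def roi_mean_spectrum(cube: Hypercube, roi: Union[ROI, np.ndarray, None] = None) -> Spectrum:
    """Per-band mean over the ROI's non-missing pixels.

    ``roi=None`` averages the whole field of view.  A band where every
    selected pixel is missing comes back NaN with a warning.
    """
    if roi is None:
        mask = np.ones(cube.spatial_shape, dtype=bool)
    elif isinstance(roi, ROI):
        mask = roi.resolve(cube.spatial_shape)
    else:
        mask = ROI(mask=np.asarray(roi)).resolve(cube.spatial_shape)
    selected = cube.data[mask]  # (n_pixels, bands)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(selected, axis=0)
    if np.any(np.isnan(means)):
        warnings.warn("some bands had no valid pixels in the ROI; reported as NaN")
    return Spectrum(cube.grid, means, kind=cube.kind)


def rmsd(spec1: Spectrum, spec2: Spectrum) -> float:
    """Root-mean-square deviation between two spectra on the same grid."""
    if spec1.grid != spec2.grid:
        raise ValueError("spectra are on different wavelength grids")
    diff = spec1.values - spec2.values
    return float(np.sqrt(np.mean(diff**2)))


def second_derivative(spec: Spectrum, smooth_window: int = 0) -> Spectrum:
    """Central second finite difference with respect to wavelength.

    Interior band k gets (v[k-1] - 2 v[k] + v[k+1]) / step^2; the two
    endpoints are reported missing (NaN) rather than one-sided.  An
    optional odd moving-average window (in bands) smooths first;
    default is no smoothing.
    """
    if spec.grid.n_bands < 3:
        raise ValueError("second derivative needs at least 3 bands")
    v = spec.values.astype(float)
    if smooth_window:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd number of bands")
        kernel = np.ones(smooth_window) / smooth_window
        core = np.convolve(v, kernel, mode="valid")
        pad = smooth_window // 2
        v = np.concatenate([v[:pad], core, v[-pad:]]) if pad else core
    step = spec.grid.step_nm
    out = np.full_like(v, np.nan)
    out[1:-1] = (v[:-2] - 2 * v[1:-1] + v[2:]) / step**2
    return Spectrum(spec.grid, out, kind="second_derivative")
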