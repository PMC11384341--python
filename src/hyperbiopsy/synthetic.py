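"""Synthetic phantoms, a Gaussian-peak chromophore library, and cohorts.

Everything the pipeline needs can be generated here with no downloads:

* a ten-chromophore spectral library built from sums of Gaussians whose
  peak centers sit at the landmark wavelengths of the real absorbers
  (hemoglobin at 540/575 and 555/757 nm, the cytochrome-c-oxidase bands
  at 605 and ~840 nm, rising water/lipid NIR tails);
* tissue phantoms: spatially varying chromophore-difference maps
  (smooth background plus circular "blood cluster" blobs) rendered
  through the Beer-Lambert forward model into raw intensity/white/dark
  stacks, the exact inverse of the reflectance reconstruction;
* cohorts of phantom fields of view with programmed group effects in
  lipid content (higher in HGG) and diffCCO (lower in HGG), default
  3 LGG + 7 HGG.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .analysis import Spectrum
from .hypercube import CalibrationSet, Hypercube
from .spectral import ChromophoreSpectrum, SpectralBasis, WavelengthGrid, build_basis

__all__ = [
    "make_synthetic_library",
    "PhantomScene",
    "Blob",
    "render_phantom",
    "make_cohort",
    "default_baseline",
]

_TAB_LO, _TAB_HI, _TAB_STEP = 480.0, 940.0, 2.0


def _gauss(lam: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)


# (unit_kind, [(center_nm, sigma_nm, amplitude)], constant floor, exp-decay term)
_LIBRARY_RECIPE = {
    "HbO2": ("molar_extinction", [(540, 8, 50.0), (575, 7, 54.0), (830, 60, 1.0)], 0.2, None),
    "HHb": ("molar_extinction", [(555, 10, 53.0), (757, 15, 1.5)], 0.5, (500, 80, 20.0)),
    "oxCCO": ("molar_extinction", [(840, 50, 1.0)], 0.25, (500, 120, 0.9)),
    "redCCO": ("molar_extinction", [(605, 8, 1.2)], 0.30, (500, 150, 1.0)),
    "oxCytB": ("molar_extinction", [(560, 25, 3.0)], 0.8, (500, 60, 8.0)),
    "redCytB": ("molar_extinction", [(562, 6, 25.0), (532, 6, 12.0)], 0.4, (500, 100, 6.0)),
    "oxCytC": ("molar_extinction", [(530, 30, 11.0)], 0.6, None),
    "redCytC": ("molar_extinction", [(550, 5, 29.0), (521, 5, 15.0)], 0.4, (500, 110, 7.0)),
    "water": ("absorption_coefficient", [(745, 20, 0.02), (970, 45, 0.45)], 0.0004, None),
    "lipid": ("absorption_coefficient", [(930, 25, 0.10), (760, 18, 0.004)], 0.004, None),
}


def make_synthetic_library(
    grid: Optional[WavelengthGrid] = None, seed: int = 0
) -> Dict[str, ChromophoreSpectrum]:
    """Gaussian-peak stand-ins for the ten chromophore spectra.

    Peak centers are fixed by construction; the seed perturbs only the
    peak amplitudes (+-10%), so different seeds give spectrally similar
    but not identical libraries.  The tabulation spans 480-940 nm, so
    any acquisition grid inside 510-900 nm can be resampled.  ``grid``
    is accepted for signature symmetry and only checked for coverage.
    """
    rng = np.random.default_rng(seed)
    lam = np.arange(_TAB_LO, _TAB_HI + _TAB_STEP / 2, _TAB_STEP)
    library: Dict[str, ChromophoreSpectrum] = {}
    for name, (unit, peaks, floor, decay) in _LIBRARY_RECIPE.items():
        vals = np.full_like(lam, floor)
        for center, sigma, amp in peaks:
            vals += _gauss(lam, center, sigma, amp * (1 + 0.1 * rng.uniform(-1, 1)))
        if decay is not None:
            edge, scale, amp = decay
            vals += amp * (1 + 0.1 * rng.uniform(-1, 1)) * np.exp(-(lam - edge) / scale)
        library[name] = ChromophoreSpectrum(name, unit, lam, vals)
    if grid is not None:
        for spec in library.values():
            spec(grid.values)  # raises if the grid is not covered
    return library


@dataclass(frozen=True)
class Blob:
    """A circular feature adding chromophore differences inside its radius."""

    center: tuple  # (row, col)
    radius: float  # pixels
    deltas: Mapping[str, float]

    def footprint(self, shape: tuple) -> np.ndarray:
        if self.radius <= 0:
            raise ValueError("blob radius must be > 0")
        r0, c0 = self.center
        if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
            raise ValueError(f"blob center {self.center} outside image {shape}")
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius**2


@dataclass
class PhantomScene:
    """Recipe for one synthetic field of view."""

    shape: tuple = (128, 128)
    background: Mapping[str, float] = field(default_factory=dict)
    blobs: Sequence[Blob] = ()
    scatter_offset: float = 0.0
    multiplicative_sd: float = 0.01
    dark_sd_counts: float = 0.5
    dark_floor_counts: float = 50.0
    white_level_counts: float = 4000.0
    vignette_strength: float = 0.15
    t_I_ms: float = 10.0
    t_W_ms: float = 5.0
    t_D_ms: float = 10.0
    seed: int = 0

    def truth_maps(self, chromophores: Sequence[str]) -> Dict[str, np.ndarray]:
        """Ground-truth difference map per chromophore."""
        maps = {}
        for name in chromophores:
            img = np.full(self.shape, float(self.background.get(name, 0.0)))
            for blob in self.blobs:
                if name in blob.deltas:
                    img[blob.footprint(self.shape)] += blob.deltas[name]
            maps[name] = img
        return maps


def default_baseline(grid: WavelengthGrid, level: float = 0.30) -> Spectrum:
    """A smooth, scattering-like baseline attenuation (decreasing with lambda)."""
    lam = grid.values
    vals = level + 0.25 * (500.0 / lam) ** 1.5
    return Spectrum(grid, vals, kind="attenuation")


def render_phantom(
    scene: PhantomScene,
    library: Mapping[str, ChromophoreSpectrum],
    grid: WavelengthGrid,
    baseline_A: Optional[Spectrum] = None,
    chromophores: Optional[Sequence[str]] = None,
) -> dict:
    """Render a scene into raw intensity/white/dark stacks plus the truth.

    Forward model per pixel: A(lambda) = baseline_A + sum_i E_i dc_i +
    scatter_offset, R = 10^-A; the white stack is a flat spectral
    illumination times a smooth 2-D vignette gain; the intensity stack is
    the exact algebraic inverse of the reflectance reconstruction plus
    multiplicative (shot-like) and additive dark noise.  Negative
    rendered counts are clipped at zero and counted.

    Returns a dict with ``truth``, ``calibration`` (a
    :class:`~hyperbiopsy.hypercube.CalibrationSet`), ``reflectance_true``
    and ``n_clipped_negative``.
    """
    rng = np.random.default_rng(scene.seed)
    if baseline_A is None:
        baseline_A = default_baseline(grid)
    if chromophores is None:
        chromophores = [n for n in library if n in set(scene.background) | {
            k for b in scene.blobs for k in b.deltas}]
        chromophores = chromophores or list(library)
    basis = build_basis([library[n] for n in chromophores], grid)
    truth = scene.truth_maps(chromophores)
    rows, cols = scene.shape
    stack = np.stack([truth[n] for n in chromophores], axis=-1)  # (r, c, k)
    att = baseline_A.values + stack @ basis.matrix.T + scene.scatter_offset
    refl = 10.0 ** (-att)

    # white cube: flat spectrum x smooth radial vignette
    rr = (np.arange(rows) - (rows - 1) / 2) / max(rows, 1)
    cc = (np.arange(cols) - (cols - 1) / 2) / max(cols, 1)
    gain = 1.0 - scene.vignette_strength * (rr[:, None] ** 2 + cc[None, :] ** 2)
    white_clean = scene.white_level_counts * gain[:, :, None] * np.ones(grid.n_bands)
    dark_clean = np.full((rows, cols, grid.n_bands), scene.dark_floor_counts)

    # exact inverse of the reconstruction formula
    tI, tW, tD = scene.t_I_ms, scene.t_W_ms, scene.t_D_ms
    dark_scaled = (tI / tD) * dark_clean
    intensity_clean = refl * ((tI / tW) * white_clean - dark_scaled) + dark_scaled

    intensity = intensity_clean * (1 + scene.multiplicative_sd * rng.standard_normal(intensity_clean.shape))
    dark = dark_clean + scene.dark_sd_counts * rng.standard_normal(dark_clean.shape)
    white = white_clean * (1 + scene.multiplicative_sd * rng.standard_normal(white_clean.shape))
    n_neg = int(np.sum(intensity < 0) + np.sum(dark < 0) + np.sum(white < 0))
    intensity = np.clip(intensity, 0, None)
    dark = np.clip(dark, 0, None)
    white = np.clip(white, 0, None)

    cal = CalibrationSet(
        intensity=Hypercube(intensity, grid, "intensity", tI),
        white=Hypercube(white, grid, "white", tW),
        dark=Hypercube(dark, grid, "dark", tD),
    )
    return {
        "truth": truth,
        "chromophores": tuple(chromophores),
        "calibration": cal,
        "reflectance_true": Hypercube(refl, grid, "reflectance"),
        "baseline_A": baseline_A,
        "n_clipped_negative": n_neg,
    }


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: programmed group means of the truth maps, in fitted-coefficient units
LGG_LIPID_MEAN = -2.53
LGG_DIFFCCO_MEAN = 0.50
DEFAULT_LIPID_EFFECT = 2.064  # HGG minus LGG lipid content difference
DEFAULT_DIFFCCO_EFFECT = -0.30  # HGG minus LGG diffCCO (mM cm)
_LIPID_SD = (0.15, 0.30)  # between-sample sd (LGG, HGG)
_DIFFCCO_SD = (0.04, 0.05)


def make_cohort(
    n_lgg: int = 3,
    n_hgg: int = 7,
    lipid_effect: float = DEFAULT_LIPID_EFFECT,
    diffcco_effect: float = DEFAULT_DIFFCCO_EFFECT,
    seed: int = 0,
    shape: tuple = (128, 128),
) -> tuple:
    """Phantom scenes for a two-group cohort with programmed effects.

    Fields of view are ordered HGG first; the very first FOV is the
    unmixing reference (all its background differences are zero, since
    downstream analysis quantifies every map *relative to* the first
    sample, which in the emulated study is a grade-4 biopsy).  Every
    other FOV gets a background lipid content and a diffCCO (split
    evenly between +oxCCO and -redCCO) drawn around its group mean, plus
    two blood-cluster blobs elevating HbT.  Returns ``(scenes,
    cohort_table)`` where ``scenes`` maps fov_id ->
    :class:`PhantomScene`.
    """
    from .stats import CohortTable
    import pandas as pd

    if n_lgg < 1 or n_hgg < 1:
        raise ValueError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    scenes: Dict[str, PhantomScene] = {}
    rows_meta: List[tuple] = []
    groups = [("HGG", 4, 1)] * n_hgg + [("LGG", 2, 0)] * n_lgg
    for i, (group, grade, gi) in enumerate(groups):
        fov = f"P{i + 1:02d}"
        if i == 0:  # the reference FOV defines the zero of every map
            background = {}
        else:
            lipid_mu = LGG_LIPID_MEAN + (lipid_effect if group == "HGG" else 0.0)
            cco_mu = LGG_DIFFCCO_MEAN + (diffcco_effect if group == "HGG" else 0.0)
            lipid = rng.normal(lipid_mu, _LIPID_SD[gi])
            diffcco = rng.normal(cco_mu, _DIFFCCO_SD[gi])
            background = {
                "lipid": lipid,
                "oxCCO": diffcco / 2.0,
                "redCCO": -diffcco / 2.0,
                "water": rng.normal(0.0, 0.02),
                "HbO2": rng.normal(0.005, 0.002),
                "HHb": rng.normal(0.005, 0.002),
            }
        blobs = []
        for _ in range(2):  # blood clusters
            r0 = int(rng.integers(shape[0] // 4, 3 * shape[0] // 4))
            c0 = int(rng.integers(shape[1] // 4, 3 * shape[1] // 4))
            radius = float(rng.uniform(0.04, 0.10) * min(shape))
            blobs.append(Blob((r0, c0), radius, {
                "HbO2": float(rng.uniform(0.01, 0.03)),
                "HHb": float(rng.uniform(0.005, 0.02)),
            }))
        scenes[fov] = PhantomScene(
            shape=shape,
            background=background,
            blobs=tuple(blobs),
            scatter_offset=float(rng.normal(0.0, 0.01)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rows_meta.append((fov, fov, grade, False, ""))
    table = CohortTable(pd.DataFrame(rows_meta, columns=list(CohortTable.REQUIRED)))
    return scenes, table
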