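"""Tissue optical model and slab Monte Carlo photon transport.

The tissue is a homogeneous gray-matter slab (default 0.5 cm thick)
resting on a thin, strongly absorbing backing layer, with Fresnel
boundaries to the surrounding medium at top and bottom.  Optical
properties per wavelength come from:

* a reduced-scattering power law  mu_s'(lambda) = a (lambda/500 nm)^-b
  with gray-matter parameters a = 40.8 cm^-1, b = 3.089;
* the conversion  mu_s = mu_s' / (1 - g)  with anisotropy g = 0.85;
* a composite absorption coefficient summing water and lipid volume
  fractions times their absorption spectra plus ln(10) times the molar
  concentrations of HHb, HbO2, oxCCO and redCCO times their base-10
  molar extinction spectra.

Default composition (human gray matter): 70% water, 10% lipid,
56.7 uM each of HHb and HbO2, 1 uM oxCCO, 4 uM redCCO.

The simulation tallies fluence (path-length estimator), the mean photon
pathlength inside gray matter, a per-photon pathlength histogram, and
the weight budget (absorbed / escaped top / through backing / lost
laterally).  Runs are exactly reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from ._mc_kernel import run_kernel
from .analysis import Spectrum
from .spectral import ChromophoreSpectrum, WavelengthGrid

__all__ = [
    "TissueComposition",
    "TissueModel",
    "MCResult",
    "reduced_scattering",
    "scattering_coefficient",
    "total_absorption",
    "run_slab_mc",
    "pathlength_spectrum",
]

LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class TissueComposition:
    """Chromophore make-up of the slab; concentrations in micromolar."""

    water_fraction: float = 0.70
    lipid_fraction: float = 0.10
    c_HHb_uM: float = 56.7
    c_HbO2_uM: float = 56.7
    c_oxCCO_uM: float = 1.0
    c_redCCO_uM: float = 4.0

    def __post_init__(self) -> None:
        for name in ("water_fraction", "lipid_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("c_HHb_uM", "c_HbO2_uM", "c_oxCCO_uM", "c_redCCO_uM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TissueModel:
    """Slab geometry, scattering law, and composition for the simulation."""

    slab_thickness_cm: float = 0.5
    backing_thickness_cm: float = 0.005
    backing_mua_cm: float = 1e6
    voxel_mm: float = 0.05
    lateral_extent_cm: float = 2.0
    composition: TissueComposition = field(default_factory=TissueComposition)
    scatter_a_cm: float = 40.8
    scatter_b: float = 3.089
    g: float = 0.85
    n_tissue: float = 1.36
    n_outside: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.g < 1:
            raise ValueError(f"anisotropy g must be in [0, 1), got {self.g}")
        for name in ("slab_thickness_cm", "backing_thickness_cm", "backing_mua_cm",
                     "voxel_mm", "lateral_extent_cm", "scatter_a_cm", "n_tissue", "n_outside"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MCResult:
    """Tallies of one simulation at one wavelength."""

    fluence: Optional[np.ndarray]
    mean_pathlength_cm: float
    mean_pathlength_unweighted_cm: float
    mean_pathlength_detected_cm: float
    pathlength_histogram: np.ndarray
    pathlength_bin_edges_cm: np.ndarray
    fractions: dict
    n_photons: int
    seed: int
    wavelength_nm: float
    mua_cm: float
    mus_cm: float


def reduced_scattering(lambda_nm, a_cm: float = 40.8, b: float = 3.089):
    """Reduced scattering coefficient mu_s' = a (lambda/500 nm)^-b, cm^-1.

    Equals ``a_cm`` at the 500-nm reference wavelength and decreases with
    wavelength for b > 0, as measured for brain tissue.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = a_cm * (lam / 500.0) ** (-b)
    return float(out) if np.isscalar(lambda_nm) else out


def scattering_coefficient(musp_cm, g: float):
    """mu_s = mu_s' / (1 - g); g is the scattering anisotropy factor."""
    if g >= 1:
        raise ValueError(f"anisotropy g must be < 1, got {g}")
    return musp_cm / (1.0 - g)


def total_absorption(
    comp: TissueComposition, lambda_nm: float, library: Mapping[str, ChromophoreSpectrum]
) -> float:
    """Composite absorption coefficient of the slab at one wavelength, cm^-1.

    mu_a = W mu_a,H2O + F mu_a,fat
         + ln10 (C_HHb eps_HHb + C_HbO2 eps_HbO2 + C_oxCCO eps_oxCCO
                 + C_redCCO eps_redCCO)

    with concentrations in mM against base-10 extinction in mM^-1 cm^-1.
    """
    mua = comp.water_fraction * float(library["water"](lambda_nm))
    mua += comp.lipid_fraction * float(library["lipid"](lambda_nm))
    molar = (
        ("HHb", comp.c_HHb_uM),
        ("HbO2", comp.c_HbO2_uM),
        ("oxCCO", comp.c_oxCCO_uM),
        ("redCCO", comp.c_redCCO_uM),
    )
    for name, c_uM in molar:
        mua += LN10 * (c_uM * 1e-3) * float(library[name](lambda_nm))
    return float(mua)


def run_slab_mc(
    model: TissueModel,
    lambda_nm: float,
    n_photons: int,
    seed: int,
    library: Mapping[str, ChromophoreSpectrum],
    tally_fluence: bool = True,
    hist_bins: int = 100,
    hist_max_cm: float = 5.0,
    mua_override: Optional[float] = None,
    mus_override: Optional[float] = None,
    source_half_width_cm: Optional[float] = None,
) -> MCResult:
    """Run the slab simulation at one wavelength.

    ``mua_override``/``mus_override`` bypass the optical model (useful
    for analytic checks such as ballistic transmission with mu_s = 0).
    The source is a normally incident planar beam, by default covering
    the full top face.  Mean pathlength is the launch-weight-normalized
    integral of photon weight over path inside gray matter (the backing
    is excluded); the unweighted per-photon average is also reported.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mua = total_absorption(model.composition, lambda_nm, library) if mua_override is None else float(mua_override)
    mus = (
        scattering_coefficient(reduced_scattering(lambda_nm, model.scatter_a_cm, model.scatter_b), model.g)
        if mus_override is None
        else float(mus_override)
    )
    voxel = model.voxel_mm / 10.0  # cm
    half_extent = model.lateral_extent_cm / 2.0
    if source_half_width_cm is None:
        source_half_width_cm = half_extent
    depth = model.slab_thickness_cm + model.backing_thickness_cm
    if tally_fluence:
        n_lat = max(1, int(round(model.lateral_extent_cm / voxel)))
        n_z = max(1, int(round(depth / voxel)))
        fluence = np.zeros((n_lat, n_lat, n_z))
    else:
        fluence = np.zeros((1, 1, 1))
    hist = np.zeros(hist_bins)

    (absorbed, reflected, transmitted, lost_side, sum_wpath, sum_path,
     sum_det_wpath, sum_det_w) = run_kernel(
        int(n_photons),
        int(seed) % (2**31),
        mua,
        mus,
        model.g,
        model.n_tissue,
        model.n_outside,
        model.slab_thickness_cm,
        model.backing_thickness_cm,
        model.backing_mua_cm,
        half_extent,
        float(source_half_width_cm),
        1e-4,
        0.1,
        tally_fluence,
        fluence,
        voxel,
        hist,
        float(hist_max_cm),
    )
    n = float(n_photons)
    fractions = {
        "absorbed": absorbed / n,
        "reflected_top": reflected / n,
        "transmitted_backing": transmitted / n,
        "lost_side": lost_side / n,
    }
    edges = np.linspace(0.0, hist_max_cm, hist_bins + 1)
    return MCResult(
        fluence=fluence / n if tally_fluence else None,
        mean_pathlength_cm=sum_wpath / n,
        mean_pathlength_unweighted_cm=sum_path / n,
        mean_pathlength_detected_cm=(sum_det_wpath / sum_det_w) if sum_det_w > 0 else float("nan"),
        pathlength_histogram=hist,
        pathlength_bin_edges_cm=edges,
        fractions=fractions,
        n_photons=int(n_photons),
        seed=int(seed),
        wavelength_nm=float(lambda_nm),
        mua_cm=mua,
        mus_cm=mus,
    )


def pathlength_spectrum(
    model: TissueModel,
    grid: WavelengthGrid,
    n_photons: int,
    seed: int,
    library: Mapping[str, ChromophoreSpectrum],
    weighted: bool = True,
) -> Spectrum:
    """Mean photon pathlength versus wavelength (one run per band).

    Each band uses an independent, deterministic sub-seed derived from
    ``seed``; fluence tallies are skipped for speed.
    """
    values = np.empty(grid.n_bands)
    for k, lam in enumerate(grid.values):
        res = run_slab_mc(
            model, lam, n_photons, seed=(seed * 1000003 + k) % (2**31),
            library=library, tally_fluence=False,
        )
        values[k] = res.mean_pathlength_cm if weighted else res.mean_pathlength_unweighted_cm
    return Spectrum(grid, values, kind="pathlength")
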