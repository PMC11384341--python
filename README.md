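# hyperbiopsy

Analysis toolkit for broadband hyperspectral reflectance imaging of fresh
tissue biopsies (510–900 nm, 5-nm steps, up to 79 bands). It covers the
whole chain from raw camera stacks to tumor-grading statistics:

1. **Reflectance reconstruction.** Raw intensity `I`, white-standard `W`
   and dark-count `D` hypercubes with camera integration times
   `t_I, t_W, t_D` are combined per voxel as

   ```
   R = (I − (t_I/t_D)·D) / ((t_I/t_W)·W − (t_I/t_D)·D)
   ```

   with clipping to [0, 1.5] and missing-value propagation for dead
   pixels.

2. **Spectral analysis.** Attenuation `A = −log10 R`, ROI mean spectra,
   RMSD between ROI spectra, and second spectral derivatives that sharpen
   the hemoglobin (540/560/575, 757 nm) and cytochrome-c-oxidase
   (605, ~840 nm) bands.

3. **MBLL unmixing.** Per-pixel attenuation differences against a
   reference-sample baseline are fitted by unconstrained least squares
   against chromophore spectra (modified Beer–Lambert law with unit
   pathlength):

   ```
   ΔA(λ) = Σ_j ε_j(λ) · Δc_j · L  (+ constant scattering offset)
   ```

   in a full window (510–900 nm; HbO₂, HHb, oxCCO, redCCO, cytochromes
   b/c in both redox states, water, lipid) and a NIR window (740–900 nm;
   six chromophores). Derived biomarkers: HbT = HbO₂ + HHb and
   diffCCO = oxCCO − redCCO, plus a per-pixel fit RMSE map.

4. **Photon Monte Carlo.** A gray-matter slab (0.5 cm, absorbing
   backing, Fresnel boundaries, n = 1.36) with the scattering power law
   `μs′ = 40.8·(λ/500 nm)^−3.089` cm⁻¹, `μs = μs′/(1−g)`, g = 0.85, and a
   composite absorption from water/lipid fractions and hemoglobin/CCO
   concentrations. Tallies: fluence, mean photon pathlength,
   per-photon pathlength histograms, and the weight budget.

5. **Grading statistics.** Per-FOV biomarker means for a cohort of
   lower-grade (WHO 2–3) vs higher-grade (WHO 4) glioma samples, exact
   two-sided Mann–Whitney U tests (full null enumeration, midranks),
   normal-density overlap coefficients, and threshold rules (lipid
   content at −2, diffCCO at 0.35 mM/cm).

6. **Synthetic data.** Gaussian-peak chromophore libraries, tissue
   phantoms with blood-cluster blobs rendered through the exact forward
   model into raw `I/W/D` stacks, and 3 + 7 cohorts with programmed
   lipid/diffCCO group effects — so the entire pipeline runs and is
   tested without any downloads.

## Worked example

```python
import numpy as np
from hyperbiopsy import (
    make_wavelength_grid, make_synthetic_library, render_phantom,
    reconstruct_reflectance, attenuation, build_basis, unmix_cube,
    derived_maps, FULL_WINDOW,
)
from hyperbiopsy.synthetic import PhantomScene, Blob

grid = make_wavelength_grid(510, 900, 5)          # 79 bands
library = make_synthetic_library(grid, seed=0)

scene = PhantomScene(
    shape=(128, 128),
    background={"lipid": -0.5, "oxCCO": 0.1, "redCCO": -0.05},
    blobs=(Blob((40, 40), 12, {"HbO2": 0.02, "HHb": 0.01}),),
    multiplicative_sd=0.01, seed=11,
)
rendered = render_phantom(scene, library, grid)
cube, clip = reconstruct_reflectance(rendered["calibration"])
basis = build_basis([library[n] for n in FULL_WINDOW.chromophores],
                    grid, include_offset=True)
maps = unmix_cube(attenuation(cube), rendered["baseline_A"], FULL_WINDOW, basis)
hbt = derived_maps(maps)["HbT"]
truth = rendered["truth"]["HbO2"] + rendered["truth"]["HHb"]
print("HbT correlation:", np.corrcoef(hbt.ravel(), truth.ravel())[0, 1])
print("mean fit RMSE:", np.nanmean(maps.rmse))
```

prints

```
HbT correlation: 0.9987461262705588
mean fit RMSE: 0.005753258472088215
```

i.e. with 1% multiplicative camera noise the recovered total-hemoglobin
map is essentially the ground truth, and the per-pixel MBLL fit residual
is below half a percent of an attenuation unit.

The same chain is available from the shell:

```sh
hyperbiopsy simulate --out sim/ --seed 1           # synthetic cohort
hyperbiopsy run --input-dir sim/ --out results/    # reconstruct→unmix→stats
hyperbiopsy mc --wavelength 900 --photons 1e5 --seed 1
```

`hyperbiopsy run` prints the group comparisons: on the default synthetic
cohort both the lipid rule (full window, threshold −2) and the diffCCO
rule (NIR window, threshold 0.35 mM/cm) separate the 3 LGG from the 7
HGG fields of view completely, with the exact Mann–Whitney
p = 2/C(10,3) ≈ 0.0167 — the smallest two-sided p attainable at these
group sizes.

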