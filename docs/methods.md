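# Methods

This note records the models implemented by `hyperbiopsy`, the
conventions and defaults chosen where several readings were defensible,
and what the synthetic-data tests do and do not demonstrate.

## Reflectance reconstruction

Raw acquisitions are three hypercubes (rows × cols × bands): sample
intensity `I`, white-standard reference `W` and dark counts `D`, each
with its camera integration time. Reflectance is

    R = (I − (t_I/t_D)·D) / ((t_I/t_W)·W − (t_I/t_D)·D)

applied voxel-wise with the dark term rescaled identically in numerator
and denominator. Properties used as tests: the formula is invariant
under common rescaling of `I, W, D`, and reduces to `(I−D)/(W−D)` for
equal times. Voxels with non-positive denominator become NaN (missing)
and are ignored, never interpolated, by all downstream statistics — a
single dead pixel must not poison a sample mean. Values outside the
clip range (default [0, 1.5]) are clipped and counted; reflectance
slightly above 1 against a white standard is ordinary noise, but
unbounded values would blow up the log-domain attenuation. Axis order
is fixed (row, col, band), row 0 at the image top, 0-based everywhere.

## Attenuation and derivative analysis

Attenuation is `A = −log10(max(R, floor))` with `floor = 1e−4`
(capping A at 4 for near-zero reflectance). The second spectral
derivative uses the unsmoothed central difference
`(v[k−1] − 2v[k] + v[k+1])/Δλ²`; endpoints are reported missing rather
than one-sided-differenced, so no boundary formula has to be invented.
An optional odd moving-average window is available but off by default,
because derivative pre-smoothing is an analysis choice, not a given.
RMSD between two ROI spectra is the plain root-mean-square over bands;
for multi-ROI summaries all unordered ROI pairs within a sample are
averaged (the pairing convention is recorded in output metadata).

## MBLL unmixing

The modified Beer–Lambert model treats the attenuation difference of
each pixel relative to a baseline spectrum as linear in chromophore
concentration differences:

    ΔA(λ) = Σ_j ε_j(λ) · Δc_j · L  (+ β·1, optional offset)

* **Base-10 convention.** All fitting is in decadic attenuation, and
  the bundled extinction tables are decadic, so no ln 10 appears in the
  design matrix; the ln 10 factors of the composite absorption
  coefficient live in the Monte Carlo model where absorption is
  natural-log by definition.
* **Units.** Molar species (hemoglobins, CCO redox states, cytochromes
  b/c) come out in mM·cm — numerically mM at the fixed unit pathlength
  L = 1 cm. Water and lipid multiply absorption-coefficient spectra
  (cm⁻¹), so their coefficients are dimensionless content differences.
* **Unconstrained least squares.** Coefficients are differences against
  a baseline and are legitimately negative; no non-negativity is
  imposed. The solver is a single pseudoinverse applied to all pixels
  (a 79-band 2048² cube solves in well under a minute on one core).
* **Offset column.** A wavelength-constant column is fitted by default
  to absorb broadband scattering differences; it is toggleable and the
  choice is stored in the output metadata.
* **Baseline.** The attenuation of the mean reflectance over a centered
  square covering 10% of the FOV area of a designated reference sample
  (the cohort's first FOV by default). All maps are therefore
  *differences relative to that reference*.
* **Windows.** `full` = 510–900 nm with ten chromophores; `nir` =
  740–900 nm with six (the cytochrome b/c signatures are visible-range
  features and are dropped there).
* **Fit quality.** A per-pixel RMSE map accompanies every fit; the
  fitted model can never do worse than the zero model on the same
  pixel, which is asserted as a property test.

## Tissue optical model and photon Monte Carlo

Geometry: a homogeneous gray-matter slab, default 0.5 cm thick, on a
0.005-cm backing layer with μa = 1e6 cm⁻¹ (the black absorbing material
under the sample), refractive index 1.36 against air, Fresnel
reflection at the outer top and bottom boundaries (the tissue–backing
interface is index-matched). The lateral extent is finite (default
2 cm); photons crossing the side walls are terminated and tallied as
`lost_side`, which is reported precisely so users can judge how good
the laterally-infinite approximation is at their settings.

Optical properties per wavelength:

* reduced scattering `μs′(λ) = a·(λ/500 nm)^−b`, a = 40.8 cm⁻¹,
  b = 3.089 — the monotonically decreasing power law measured for brain
  tissue (so μs′ equals `a` exactly at the 500-nm reference);
* `μs = μs′/(1−g)` with constant anisotropy g = 0.85;
* `μa = W·μa,H2O + F·μa,fat + ln10·Σ C_i·ε_i` over HHb, HbO₂, oxCCO,
  redCCO, with the default composition W = 0.70, F = 0.10,
  C_HHb = C_HbO2 = 56.7 μM, C_oxCCO = 1 μM, C_redCCO = 4 μM.

Transport: exponential free paths in the current layer's μt,
discrete-interaction weighting (deposit `w·μa/μt` per interaction),
Henyey–Greenstein deflection, Russian roulette below weight 1e−4 with
survival probability 0.1. Roulette adjustments are booked against the
absorbed tally with zero mean, so the four exit fractions sum to the
launched weight to 1e−9 *per run*, not merely in expectation. The
source is a normally incident planar beam over the full top face.
Fluence uses the path-length estimator with jittered sub-voxel segment
sampling (the jitter removes voxel-boundary aliasing without bias).

**Pathlength estimator conventions.** Three means are tallied:

* `mean_pathlength_cm` (default): launch-weight-normalized integral of
  packet weight over gray-matter path, `Σ∫w dℓ / N` — identical to the
  fluence volume integral;
* `mean_pathlength_detected_cm`: exit-weight-averaged path of packets
  escaping through the top surface (what a co-located detector sees);
* `mean_pathlength_unweighted_cm`: plain per-packet average.

At 900 nm with the defaults these give ≈ 0.85, 0.79 and 1.13 cm. An
independent diffusion-theory oracle (image-source slab solution,
⟨L⟩ = Σ L·w(L) with w(L) the pathlength-resolved reflectance times
exp(−μa L)) gives 0.85 cm for the laterally infinite slab and is
asserted against the MC in the test suite. The mean pathlength is
strongly sensitive to the lateral domain size (≈ 0.40 cm at a 0.5-cm-wide
domain vs ≈ 0.98 cm at 4 cm), because side-truncated random walks are
short; published figures for nominally "semi-infinite" voxel
simulations therefore depend on the simulated volume, which is usually
unstated. The package keeps the 2-cm default and reports the side-loss
fraction rather than silently matching any particular figure.

Desk-scale photon budgets (1e4–1e5 per band) give percent-level
standard errors on all tallies asserted in tests; the tallies are
unbiased, so larger budgets only narrow the error bars.

## Grading statistics

The observation unit is the field of view (a sample imaged twice
contributes two observations); lower-grade = WHO 2–3, higher-grade =
WHO 4. With 3 + 7 observations the exact two-sided Mann–Whitney p for
complete separation is 2/C(10,3) = 1/60 ≈ 0.0167 — the smallest
attainable at these sizes, which is why the observation unit matters.

* **Exact test.** The null distribution of the rank sum is enumerated
  by a subset-sum counting recursion over doubled midranks (equivalent
  to enumerating all C(n₁+n₂, n₁) labelings, exact under ties), used up
  to 25 pooled observations; beyond that a tie-corrected normal
  approximation with continuity correction takes over. Two-sided
  p = min(1, 2·min(P(≤), P(≥))).
* **Overlap coefficient.** OVL = ∫min(φ₁, φ₂) for two normals fitted by
  method of moments; the crossing points solve a quadratic and the
  integral is assembled from normal CDFs. Densities are compared in log
  space at the interval midpoint so far-tail crossings do not underflow.
  Verified against numerical integration.
* **Threshold rules.** A threshold separates the groups iff every
  observation of one group is strictly on one side; the side each group
  should occupy is inferred from group means, and offending observation
  ids are reported. No multiple-testing correction is applied to the
  per-wavelength test vector, matching the analysis convention the
  pipeline emulates.

## Synthetic data: what it does and does not show

The Gaussian-peak library places peaks at the real absorbers' landmark
wavelengths (HbO₂ 540/575 nm + broad NIR, HHb 555/757 nm, redCCO
605 nm, oxCCO ~840 nm broad, cytochrome b 532/562 nm, cytochrome c
521/550 nm, rising water/lipid NIR tails) with seed-perturbed
amplitudes. Amplitudes are scaled so that the programmed cohort effects
(lipid contents around −2.53 for LGG vs −0.466 for HGG relative to the
reference sample; diffCCO 0.5 vs 0.2 mM·cm; between-sample SDs
0.15/0.30 and 0.04/0.05) keep rendered reflectance inside (0, 1.5) —
with realistic-height 605-nm CCO extinction those coefficient scales
would drive reflectance out of range, which is a deliberate reminder
that the fitted "concentrations" of this model family are effective,
pathlength-confounded quantities. The first cohort FOV is the
reference with all-zero background, mirroring an analysis that
quantifies every sample against the first one; it is generated as a
higher-grade sample.

The phantom forward model is the exact algebraic inverse of the
reconstruction + MBLL chain plus multiplicative (shot-like) and
additive dark Gaussian noise and a smooth illumination vignette. A
zero-noise round trip is therefore the identity to ~1e−14 and is
asserted at 1e−6; with 1% multiplicative noise HbT recovery correlates
> 0.99 with truth. Passing these tests shows the chain is
self-consistent and noise-stable. It does **not** show that the MBLL
basis is spectroscopically complete for real tissue, that pathlength is
really constant across wavelength, or that the programmed group effects
have the real effect sizes — those require the original archived
patient data, which the pipeline can consume but which no test depends
on.

On conditioning: the raw condition number of the 79×10 design matrix is
~1.2e4, dominated by the three-orders-of-magnitude unit gap between
molar-extinction and absorption-coefficient columns; after column
normalization it is ~23, so the test suite asserts the normalized
condition (< 1e4) plus full rank, which is the meaningful collinearity
statement.

## Bundled spectra

`data/literature/*.csv` are coarse re-tabulations (2–10 nm spacing,
500–910 nm) of the standard published compilations for hemoglobin and
cytochrome extinction and water/lipid absorption, written for this
package: peak positions and NIR magnitudes are right to a few percent,
which suffices for the forward optical model; they are not a
metrological reference, and the manifest records each file's unit
convention so a user can swap in their preferred tabulation.

## Numerical choices and limitations

* Linear interpolation for all spectra; extrapolation always refused.
* Attenuation floor 1e−4; reflectance clip [0, 1.5].
* Baseline central fraction 0.10 of FOV area; pathlength 1 cm.
* MC voxel 0.05 mm; roulette threshold 1e−4, survival 0.1; seeds
  reduced mod 2³¹; per-band sub-seeds derived as `seed·1000003 + band`.
* Default phantom size 128×128 and photon budgets 1e4–1e5 keep the full
  suite in seconds-to-minutes on one core; these sizes are the
  package's test conditions, and all stochastic assertions state their
  tolerances at those sizes.
* No DPF/pathlength-spectrum coupling between the MC and the MBLL fit;
  no heterogeneous voxel labels beyond slab + backing; no polarization,
  time-resolved tallies, or GPU kernels.
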