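"""MBLL unmixing: baseline, per-pixel fits, cube fits, derived maps."""

import numpy as np
import pytest

from hyperbiopsy.analysis import Spectrum, attenuation
from hyperbiopsy.hypercube import Hypercube, reconstruct_reflectance
from hyperbiopsy.spectral import build_basis
from hyperbiopsy.synthetic import PhantomScene, Blob, render_phantom
from hyperbiopsy.unmix import (
    FULL_WINDOW,
    NIR_WINDOW,
    baseline_spectrum,
    derived_maps,
    read_maps,
    unmix_cube,
    unmix_pixel,
    write_maps,
)


@pytest.fixture(scope="module")
def full_basis(grid79, synth_library):
    return build_basis([synth_library[n] for n in FULL_WINDOW.chromophores], grid79)


@pytest.fixture(scope="module")
def nir_basis(grid_nir, synth_library):
    return build_basis([synth_library[n] for n in NIR_WINDOW.chromophores], grid_nir)


class TestBaseline:
    def test_constant_cube(self, grid79):
        cube = Hypercube(np.full((10, 10, 79), 0.5), grid79, "reflectance")
        base = baseline_spectrum(cube)
        assert np.allclose(base.values, -np.log10(0.5))
        assert base.kind == "attenuation"

    def test_full_fraction_equals_whole_fov(self, grid79, rng):
        cube = Hypercube(rng.uniform(0.2, 0.8, (9, 9, 79)), grid79, "reflectance")
        base = baseline_spectrum(cube, central_fraction=1.0)
        assert np.allclose(10.0 ** (-base.values), cube.data.mean(axis=(0, 1)))

    def test_checkerboard_central_square_oracle(self, grid79):
        data = np.zeros((8, 8, 79))
        checker = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)
        data[:] = (0.2 + 0.4 * checker)[:, :, None]
        cube = Hypercube(data, grid79, "reflectance")
        # central_fraction 0.25 -> centered 4x4 square, rows/cols 2..5
        base = baseline_spectrum(cube, central_fraction=0.25)
        expected = -np.log10(data[2:6, 2:6].mean(axis=(0, 1)))
        assert np.allclose(base.values, expected)

    def test_invalid_fraction_rejected(self, grid79):
        cube = Hypercube(np.full((4, 4, 79), 0.5), grid79, "reflectance")
        with pytest.raises(ValueError):
            baseline_spectrum(cube, central_fraction=0.0)


class TestUnmixPixel:
    def test_noiseless_inversion_over_random_draws(self, full_basis, rng):
        for _ in range(100):
            c0 = rng.normal(size=full_basis.n_columns)
            coeffs, rmse = unmix_pixel(full_basis.matrix @ c0, full_basis)
            assert np.allclose(coeffs, c0, atol=1e-8)
            assert rmse < 1e-10

    def test_zero_signal_gives_zero_coefficients(self, full_basis):
        coeffs, rmse = unmix_pixel(np.zeros(79), full_basis)
        assert np.allclose(coeffs, 0.0) and rmse == 0.0

    def test_matches_normal_equations_oracle(self, full_basis, rng):
        y = rng.normal(size=79)
        B = full_basis.matrix
        expected = np.linalg.solve(B.T @ B, B.T @ y)
        coeffs, rmse = unmix_pixel(y, full_basis)
        assert np.allclose(coeffs, expected, atol=1e-8)
        assert rmse == pytest.approx(np.sqrt(np.mean((y - B @ expected) ** 2)))

    def test_scaling_equivariance(self, full_basis, rng):
        y = rng.normal(size=79)
        c1, _ = unmix_pixel(y, full_basis)
        c2, _ = unmix_pixel(-3.2 * y, full_basis)
        assert np.allclose(c2, -3.2 * c1)

    def test_pathlength_scales_concentrations(self, full_basis, rng):
        y = rng.normal(size=79)
        c1, _ = unmix_pixel(y, full_basis, pathlength_cm=1.0)
        c2, _ = unmix_pixel(y, full_basis, pathlength_cm=2.0)
        assert np.allclose(c2, c1 / 2.0)

    def test_rank_deficient_basis_names_columns(self, grid79, synth_library):
        from hyperbiopsy.spectral import SpectralBasis

        col = synth_library["HbO2"](grid79.values)
        matrix = np.column_stack([col, 2.0 * col])
        bad = SpectralBasis(("HbO2", "HbO2x2"), grid79, matrix, False)
        with pytest.raises(ValueError, match="HbO2"):
            unmix_pixel(np.zeros(79), bad)


class TestUnmixCube:
    def test_cube_equal_to_baseline_gives_zero_maps(self, grid79, full_basis):
        base_vals = np.linspace(0.3, 0.6, 79)
        cube = Hypercube(np.broadcast_to(base_vals, (6, 6, 79)).copy(), grid79, "attenuation")
        maps = unmix_cube(cube, Spectrum(grid79, base_vals, "attenuation"), FULL_WINDOW, full_basis)
        for name in FULL_WINDOW.chromophores:
            assert np.allclose(maps[name], 0.0, atol=1e-10)
        assert np.allclose(maps.rmse, 0.0, atol=1e-12)

    def test_zero_noise_phantom_recovered_exactly(self, grid79, synth_library, full_basis):
        scene = PhantomScene(
            shape=(24, 24),
            background={"lipid": -0.8, "oxCCO": 0.15, "redCCO": -0.1, "water": 0.05},
            blobs=(Blob((12, 12), 4, {"HbO2": 0.02, "HHb": 0.015}),),
            scatter_offset=0.0,
            multiplicative_sd=0.0,
            dark_sd_counts=0.0,
            seed=7,
        )
        rendered = render_phantom(scene, synth_library, grid79)
        cube, _ = reconstruct_reflectance(rendered["calibration"])
        maps = unmix_cube(attenuation(cube), rendered["baseline_A"], FULL_WINDOW, full_basis)
        for name in rendered["chromophores"]:
            assert np.nanmax(np.abs(maps[name] - rendered["truth"][name])) < 1e-6

    def test_window_nesting_recovers_nir_coefficients(self, grid79, grid_nir, synth_library, nir_basis):
        # signal generated from the NIR chromophore set only, fitted in the NIR window
        rng = np.random.default_rng(3)
        full = build_basis([synth_library[n] for n in NIR_WINDOW.chromophores], grid79)
        c0 = rng.normal(scale=0.1, size=len(NIR_WINDOW.chromophores))
        signal = full.matrix @ c0
        base = np.linspace(0.4, 0.3, 79)
        cube = Hypercube((base + signal)[None, None, :], grid79, "attenuation")
        maps = unmix_cube(cube, Spectrum(grid79, base, "attenuation"), NIR_WINDOW, nir_basis)
        got = np.array([maps[n][0, 0] for n in NIR_WINDOW.chromophores])
        assert np.allclose(got, c0, atol=1e-8)

    def test_missing_pixels_propagate(self, grid79, full_basis):
        base = np.full(79, 0.4)
        data = np.broadcast_to(base, (2, 2, 79)).copy()
        data[0, 0, 10] = np.nan
        cube = Hypercube(data, grid79, "attenuation")
        maps = unmix_cube(cube, Spectrum(grid79, base, "attenuation"), FULL_WINDOW, full_basis)
        assert np.isnan(maps["HbO2"][0, 0]) and np.isnan(maps.rmse[0, 0])
        assert np.isfinite(maps.rmse[1, 1])

    def test_fit_never_worse_than_zero_model(self, grid79, full_basis, rng):
        base = np.full(79, 0.4)
        data = base + rng.normal(scale=0.05, size=(4, 4, 79))
        cube = Hypercube(data, grid79, "attenuation")
        maps = unmix_cube(cube, Spectrum(grid79, base, "attenuation"), FULL_WINDOW, full_basis)
        zero_rmse = np.sqrt(np.mean((data - base) ** 2, axis=2))
        assert np.all(maps.rmse <= zero_rmse + 1e-12)

    def test_noisy_phantom_hbt_correlation(self, grid79, synth_library):
        scene = PhantomScene(
            shape=(128, 128),
            background={"lipid": -0.5, "oxCCO": 0.1, "redCCO": -0.05},
            blobs=(
                Blob((40, 40), 12, {"HbO2": 0.02, "HHb": 0.01}),
                Blob((90, 70), 16, {"HbO2": 0.015, "HHb": 0.02}),
            ),
            multiplicative_sd=0.01,
            seed=11,
        )
        rendered = render_phantom(scene, synth_library, grid79)
        cube, _ = reconstruct_reflectance(rendered["calibration"])
        basis = build_basis(
            [synth_library[n] for n in FULL_WINDOW.chromophores], grid79, include_offset=True
        )
        maps = unmix_cube(attenuation(cube), rendered["baseline_A"], FULL_WINDOW, basis)
        hbt = derived_maps(maps)["HbT"]
        truth = rendered["truth"]["HbO2"] + rendered["truth"]["HHb"]
        r = np.corrcoef(hbt.ravel(), truth.ravel())[0, 1]
        assert r > 0.99


class TestDerivedMaps:
    def test_arithmetic(self):
        from hyperbiopsy.unmix import ConcentrationMaps

        shape = (2, 2)
        maps = ConcentrationMaps(
            coefficients={
                "HbO2": np.full(shape, 2.0),
                "HHb": np.full(shape, 3.0),
                "oxCCO": np.full(shape, 5.0),
                "redCCO": np.full(shape, 1.0),
            },
            rmse=np.zeros(shape),
            window=NIR_WINDOW,
            baseline=None,
        )
        out = derived_maps(maps)
        assert np.all(out["HbT"] == 5.0) and np.all(out["diffCCO"] == 4.0)

    def test_zero_inputs(self):
        from hyperbiopsy.unmix import ConcentrationMaps

        maps = ConcentrationMaps(
            coefficients={n: np.zeros((2, 2)) for n in ("HbO2", "HHb", "oxCCO", "redCCO")},
            rmse=np.zeros((2, 2)), window=NIR_WINDOW, baseline=None,
        )
        out = derived_maps(maps)
        assert np.all(out["HbT"] == 0.0) and np.all(out["diffCCO"] == 0.0)

    def test_missing_species_rejected(self):
        from hyperbiopsy.unmix import ConcentrationMaps

        maps = ConcentrationMaps(
            coefficients={"HbO2": np.zeros((2, 2))}, rmse=np.zeros((2, 2)),
            window=NIR_WINDOW, baseline=None,
        )
        with pytest.raises(ValueError, match="redCCO"):
            derived_maps(maps)


def test_maps_hdf5_round_trip(tmp_path, grid79, full_basis, rng):
    base = np.full(79, 0.4)
    data = base + rng.normal(scale=0.02, size=(3, 3, 79))
    cube = Hypercube(data, grid79, "attenuation")
    maps = unmix_cube(cube, Spectrum(grid79, base, "attenuation"), FULL_WINDOW, full_basis)
    path = tmp_path / "maps.h5"
    write_maps(maps, path)
    back = read_maps(path)
    assert set(back.coefficients) == set(maps.coefficients)
    for name in maps.coefficients:
        assert np.allclose(back[name], maps[name], equal_nan=True)
    assert np.allclose(back.rmse, maps.rmse)
    assert back.window.name == "full"
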