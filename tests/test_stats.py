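"""Cohort handling, exact Mann-Whitney, overlap coefficient, thresholds."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import mannwhitneyu, norm, rankdata

from hyperbiopsy.stats import (
    CohortTable,
    compare_groups,
    group_of,
    mann_whitney_exact,
    overlap_coefficient_normal,
    per_fov_mean,
    per_wavelength_group_test,
    reference_cohort,
    threshold_separation,
)


def brute_force_two_sided_p(x, y):
    """Oracle: enumerate all C(n1+n2, n1) group labelings of the pooled
    midranks and count rank sums as or more extreme than the observed."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    obs = ranks[:n1].sum()
    le = ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(idx)].sum()
        total += 1
        le += s <= obs + 1e-9
        ge += s >= obs - 1e-9
    return min(1.0, 2.0 * min(le / total, ge / total))


class TestCohort:
    def test_group_derivation(self):
        assert group_of(2) == group_of(3) == "LGG"
        assert group_of(4) == "HGG"
        with pytest.raises(ValueError):
            group_of(5)

    def test_reference_cohort_structure(self):
        cohort = reference_cohort()
        assert len(cohort.records) == 12  # 11 samples, one imaged twice
        assert len(cohort.analyzable) == 10
        assert len(cohort.fovs("LGG")) == 3
        assert len(cohort.fovs("HGG")) == 7
        excluded = cohort.records[cohort.records.excluded]
        assert set(excluded.sample_id) == {"S3", "S6"}
        assert (cohort.records.sample_id == "S4").sum() == 2

    def test_csv_round_trip(self, tmp_path):
        cohort = reference_cohort()
        cohort.to_csv(tmp_path / "c.csv")
        back = CohortTable.from_csv(tmp_path / "c.csv")
        assert back.records[["sample_id", "who_grade", "excluded"]].equals(
            cohort.records[["sample_id", "who_grade", "excluded"]]
        )


class TestPerFovMean:
    def _maps(self, img):
        from hyperbiopsy.unmix import ConcentrationMaps, NIR_WINDOW

        return ConcentrationMaps(coefficients={"lipid": img}, rmse=np.zeros(img.shape),
                                 window=NIR_WINDOW, baseline=None)

    def test_constant_and_half(self):
        assert per_fov_mean(self._maps(np.full((4, 4), 2.5)), "lipid") == 2.5
        img = np.zeros((2, 2))
        img[0] = 2.0
        assert per_fov_mean(self._maps(img), "lipid") == 1.0

    def test_matches_flat_loop_oracle_and_ignores_nan(self, rng):
        img = rng.normal(size=(5, 7))
        img[0, 0] = np.nan
        acc = [v for v in img.ravel() if np.isfinite(v)]
        assert per_fov_mean(self._maps(img), "lipid") == pytest.approx(sum(acc) / len(acc))

    def test_unknown_map_rejected(self):
        with pytest.raises(KeyError):
            per_fov_mean(self._maps(np.ones((2, 2))), "nope")


class TestMannWhitneyExact:
    def test_complete_separation_3v7(self):
        U, p = mann_whitney_exact([10.0, 11.0, 12.0], [1, 2, 3, 4, 5, 6, 7])
        assert p == pytest.approx(2 / comb(10, 3))
        assert round(p, 3) == 0.017

    def test_identical_multisets_give_maximal_p(self):
        _, p = mann_whitney_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_three_vs_three_separation(self):
        _, p = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / comb(6, 3))
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_enumeration_with_ties(self, trial):
        rng = np.random.default_rng(100 + trial)
        n1, n2 = rng.integers(2, 6, size=2)
        # integer draws force ties
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        _, p = mann_whitney_exact(x, y)
        assert p == pytest.approx(brute_force_two_sided_p(x, y), abs=1e-12)

    def test_agrees_with_scipy_exact_without_ties(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=8)
        _, p = mann_whitney_exact(x, y)
        expected = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(expected, abs=1e-12)

    def test_minimum_attainable_p_for_3v7(self, rng):
        floor = 2 / comb(10, 3)
        for _ in range(20):
            x, y = rng.normal(size=3), rng.normal(size=7)
            _, p = mann_whitney_exact(x, y)
            assert p >= floor - 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestOverlapCoefficient:
    def test_identical_normals(self):
        assert overlap_coefficient_normal(0, 1, 0, 1) == 100.0

    def test_equal_sd_closed_form(self):
        # |dmean| = 2 sigma -> OVL = 2 Phi(-1) = 31.73%
        assert overlap_coefficient_normal(0, 1, 2, 1) == pytest.approx(31.73, abs=0.01)

    def test_disjoint_limit(self):
        assert overlap_coefficient_normal(0, 1, 20, 1) < 0.01

    def test_symmetry_and_affine_invariance(self):
        a = overlap_coefficient_normal(1.0, 0.5, 2.5, 1.5)
        b = overlap_coefficient_normal(2.5, 1.5, 1.0, 0.5)
        assert a == pytest.approx(b, abs=1e-9)
        c = overlap_coefficient_normal(3 * 1.0 - 2, 3 * 0.5, 3 * 2.5 - 2, 3 * 1.5)
        assert a == pytest.approx(c, abs=1e-9)

    @pytest.mark.parametrize(
        "m1, s1, m2, s2",
        [(0, 1, 1, 2), (0.5, 0.3, -0.4, 1.1), (0, 2, 0, 0.5), (5, 1, 5.2, 1.01)],
    )
    def test_matches_numeric_integration(self, m1, s1, m2, s2):
        numeric, _ = quad(
            lambda x: min(norm.pdf(x, m1, s1), norm.pdf(x, m2, s2)), -50, 50, limit=400
        )
        assert overlap_coefficient_normal(m1, s1, m2, s2) == pytest.approx(
            100 * numeric, abs=0.01
        )

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            overlap_coefficient_normal(0, 0, 1, 1)


class TestThresholdSeparation:
    def test_constructed_lipid_separation(self):
        lgg = {"L1": -3.0, "L2": -2.6, "L3": -2.4}
        hgg = {f"H{i}": v for i, v in enumerate([-1, -0.5, -0.2, 0, 0.1, -0.9, -0.4])}
        res = threshold_separation({"LGG": lgg, "HGG": hgg}, -2.0)
        assert res["separates"] and res["misclassified"] == ()
        assert res["above_group"] == "HGG"

    def test_straddling_values_listed(self):
        res = threshold_separation(
            {"LGG": {"L1": -3.0, "L2": -1.5}, "HGG": {"H1": -0.5, "H2": -2.5}}, -2.0
        )
        assert not res["separates"]
        assert set(res["misclassified"]) == {"L2", "H2"}

    def test_monotone_transform_invariance(self, rng):
        lgg = {f"L{i}": v for i, v in enumerate(rng.normal(0, 1, 3))}
        hgg = {f"H{i}": v for i, v in enumerate(rng.normal(2, 1, 7))}
        thr = 1.0
        base = threshold_separation({"LGG": lgg, "HGG": hgg}, thr)
        f = lambda v: np.exp(v) + 3 * v  # strictly increasing
        trans = threshold_separation(
            {"LGG": {k: f(v) for k, v in lgg.items()},
             "HGG": {k: f(v) for k, v in hgg.items()}},
            f(thr),
        )
        assert base["separates"] == trans["separates"]
        assert set(base["misclassified"]) == set(trans["misclassified"])


class TestPerWavelengthTest:
    def _cohort(self):
        return reference_cohort()

    def test_identical_group_spectra_maximal_p(self):
        cohort = self._cohort()
        spectra = {f: np.ones(5) for f in cohort.fovs()}
        p = per_wavelength_group_test(spectra, cohort)
        assert np.all(p == 1.0)

    def test_injected_separating_band(self, rng):
        cohort = self._cohort()
        spectra = {f: rng.normal(size=6) for f in cohort.fovs()}
        for f in cohort.fovs("LGG"):
            spectra[f][3] = 100.0 + rng.uniform()
        for f in cohort.fovs("HGG"):
            spectra[f][3] = -100.0 - rng.uniform()
        p = per_wavelength_group_test(spectra, cohort)
        assert p[3] == pytest.approx(2 / comb(10, 3))
        assert np.all(p[np.arange(6) != 3] > p[3])

    def test_label_permutation_within_group_invariant(self, rng):
        cohort = self._cohort()
        spectra = {f: rng.normal(size=4) for f in cohort.fovs()}
        p1 = per_wavelength_group_test(spectra, cohort)
        lgg = cohort.fovs("LGG")
        permuted = dict(spectra)
        permuted[lgg[0]], permuted[lgg[1]] = spectra[lgg[1]], spectra[lgg[0]]
        p2 = per_wavelength_group_test(permuted, cohort)
        assert np.allclose(p1, p2)


def test_compare_groups_wires_everything(rng):
    cohort = reference_cohort()
    values = {}
    for f in cohort.fovs("LGG"):
        values[f] = rng.normal(-2.5, 0.1)
    for f in cohort.fovs("HGG"):
        values[f] = rng.normal(-0.5, 0.3)
    comp = compare_groups(values, cohort, "lipid", threshold=-2.0)
    assert comp.p_two_sided == pytest.approx(2 / comb(10, 3))
    assert comp.threshold_separates
    assert comp.overlap_pct is not None and 0 <= comp.overlap_pct <= 100
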