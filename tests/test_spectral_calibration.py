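"""Calibration algebra, isosbestic detection and dose-series deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crocin_radiolysis import synthetic_data as syn
from crocin_radiolysis.spectral_calibration import (
    Spectrum,
    calibrate_by_ratio,
    deconvolve_dose_series,
    differential_to_absolute,
    dimer_bleach_ratio,
    dimer_epsilon,
    find_isosbestic,
    g_exp_from_bleach,
)


class TestSpectrum:
    def test_validation(self):
        with pytest.raises(ValueError):
            Spectrum([400, 400, 402], [1, 2, 3])
        with pytest.raises(ValueError):
            Spectrum([400, 401], [1.0, -1.0], kind="molar_absorptivity")
        # differential spectra may be negative
        Spectrum([400, 401], [1.0, -1.0], kind="differential")

    def test_interpolation_and_resampling(self):
        s = Spectrum([400.0, 500.0], [0.0, 100.0], kind="absorbance")
        assert s.value_at(450.0) == pytest.approx(50.0)
        with pytest.raises(ValueError):
            s.value_at(600.0)
        with pytest.raises(ValueError):
            s.resample(np.array([350.0, 450.0]))


class TestRatioCalibration:
    def test_radical_band_from_crocin_reference(self):
        # the 678 nm radical band against the crocin 441 nm band, same path
        assert calibrate_by_ratio(1.35e5, 0.52, 0.024) == pytest.approx(6230, rel=0.001)

    def test_identity_and_half(self):
        assert calibrate_by_ratio(2e5, 0.5, 0.5) == pytest.approx(2e5)
        assert calibrate_by_ratio(2e5, 0.5, 0.25) == pytest.approx(1e5)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            calibrate_by_ratio(1e5, 0.0, 0.1)


class TestDifferentialToAbsolute:
    def test_bleach_at_441(self):
        grid = np.array([440.0, 441.0, 442.0])
        ref = Spectrum(grid, np.full(3, 1.35e5), kind="molar_absorptivity")
        diff = Spectrum(grid, np.full(3, -18_200.0), kind="differential")
        out = differential_to_absolute(diff, ref)
        assert out.value_at(441.0) == pytest.approx(1.17e5, rel=0.01)

    def test_gain_at_333(self):
        grid = np.array([332.0, 333.0, 334.0])
        ref = Spectrum(grid, np.full(3, 7000.0), kind="molar_absorptivity")
        diff = Spectrum(grid, np.full(3, 3000.0), kind="differential")
        assert differential_to_absolute(diff, ref).value_at(333.0) == pytest.approx(
            1.0e4, rel=0.01
        )

    def test_zero_differential_returns_reference(self, crocin_spectrum):
        zero = Spectrum(crocin_spectrum.wavelength_nm,
                        np.zeros_like(crocin_spectrum.values), kind="differential")
        out = differential_to_absolute(zero, crocin_spectrum)
        assert np.allclose(out.values, crocin_spectrum.values)

    def test_spectrum_minus_reference_round_trip(self, crocin_spectrum):
        target = syn.gen_radical_like_spectrum(crocin_spectrum.wavelength_nm)
        diff = Spectrum(crocin_spectrum.wavelength_nm,
                        target.values - crocin_spectrum.values, kind="differential")
        out = differential_to_absolute(diff, crocin_spectrum)
        assert np.allclose(out.values, target.values)

    def test_negative_result_clipped_with_warning(self):
        grid = np.array([400.0, 401.0])
        ref = Spectrum(grid, np.full(2, 100.0), kind="molar_absorptivity")
        diff = Spectrum(grid, np.full(2, -200.0), kind="differential")
        with pytest.warns(UserWarning):
            out = differential_to_absolute(diff, ref)
        assert np.all(out.values == 0.0)

    def test_disjoint_ranges_rejected(self):
        ref = Spectrum([400.0, 450.0], [1.0, 1.0], kind="molar_absorptivity")
        diff = Spectrum([600.0, 650.0], [0.0, 0.0], kind="differential")
        with pytest.raises(ValueError):
            differential_to_absolute(diff, ref)


class TestDimerEpsilon:
    def test_unit_ratio_gives_twice_the_radical(self):
        assert dimer_epsilon(1.35e5, 1.17e5, 1.0) == pytest.approx(2 * 1.17e5)

    def test_late_bleach_ratio_gives_dimer_band(self):
        ratio = dimer_bleach_ratio(1.35e5, 1.17e5, 1.84e5)
        assert ratio == pytest.approx(2.389, abs=0.001)
        assert dimer_epsilon(1.35e5, 1.17e5, ratio) == pytest.approx(1.84e5, rel=1e-6)

    def test_hand_algebra(self):
        assert dimer_epsilon(1e5, 0.5e5, 0.5) == pytest.approx(1.5e5)

    @pytest.mark.filterwarnings("ignore:negative dimer absorptivity")
    @settings(derandomize=True, max_examples=100)
    @given(
        eps_c=st.floats(1e3, 1e6),
        frac=st.floats(0.01, 0.99),
        ratio=st.floats(0.01, 3.0),
    )
    def test_inverse_of_bleach_ratio_equation(self, eps_c, frac, ratio):
        eps_r = frac * eps_c
        eps_d = dimer_epsilon(eps_c, eps_r, ratio)
        assert dimer_bleach_ratio(eps_c, eps_r, eps_d) == pytest.approx(ratio, rel=1e-9)

    def test_invalid_regime_rejected(self):
        with pytest.raises(ValueError):
            dimer_epsilon(1e5, 2e5, 1.0)
        with pytest.raises(ValueError):
            dimer_epsilon(1e5, 0.5e5, 0.0)


class TestFindIsosbestic:
    def test_constructed_crossing_located_within_one_grid_step(self):
        grid = np.arange(300.0, 501.0)
        base = np.linspace(1.0, 2.0, grid.size)
        family = []
        for a in [0.0, 0.3, 0.6, 1.0]:
            # all members cross at 375 nm exactly
            family.append(Spectrum(grid, base + a * (grid - 375.0) / 100.0))
        report = find_isosbestic(family)
        assert not report.degenerate
        assert any(abs(w - 375.0) <= 1.0 for w in report.wavelengths_nm)

    def test_dose_series_isosbestic(self, crocin_spectrum):
        series = syn.gen_dose_series(syn.SpectrumRecipe(noise_fraction=0.0))
        report = find_isosbestic(list(series.values()))
        assert any(abs(w - 375.0) <= 1.0 for w in report.wavelengths_nm)

    def test_identical_spectra_degenerate(self):
        grid = np.arange(300.0, 401.0)
        s = Spectrum(grid, np.linspace(1, 2, grid.size))
        report = find_isosbestic([s, Spectrum(grid, s.values.copy())])
        assert report.degenerate
        assert report.wavelengths_nm == []

    def test_non_crossing_spectra_empty(self):
        grid = np.arange(300.0, 401.0)
        v = np.linspace(1.0, 2.0, grid.size)
        report = find_isosbestic([Spectrum(grid, v), Spectrum(grid, v + 0.5)])
        assert report.wavelengths_nm == []


class TestDeconvolution:
    def test_zero_dose_is_pure_parent(self):
        recipe = syn.SpectrumRecipe(noise_fraction=0.0)
        series = syn.gen_dose_series(recipe)
        res = deconvolve_dose_series(series, recipe.eps_parent, recipe.c0, recipe.path_cm)
        row0 = res.concentrations.iloc[0]
        assert row0.dose_gy == 0.0
        assert row0.c_known == pytest.approx(recipe.c0)
        assert row0.c_product == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_round_trip_is_exact(self, product_spectrum):
        recipe = syn.SpectrumRecipe(noise_fraction=0.0)
        series = syn.gen_dose_series(recipe)
        res = deconvolve_dose_series(series, recipe.eps_parent, recipe.c0, recipe.path_cm)
        assert res.converged
        assert res.g_exp == pytest.approx(4.0e-7, rel=1e-6)
        true_c = np.clip(recipe.c0 - 4.0e-7 * res.concentrations.dose_gy.values, 0, None)
        assert np.max(np.abs(res.concentrations.c_known.values - true_c)) < 1e-6 * recipe.c0
        err = np.abs(res.product_eps.values - product_spectrum.values)
        assert err.max() < 1e-6 * product_spectrum.values.max()

    def test_fixture_band_ratio_recovered(self):
        recipe = syn.SpectrumRecipe(noise_fraction=0.0)
        series = syn.gen_dose_series(recipe)
        res = deconvolve_dose_series(series, recipe.eps_parent, recipe.c0, recipe.path_cm)
        ratio = res.product_eps.value_at(330.0) / res.product_eps.value_at(441.0)
        assert ratio == pytest.approx(0.25 / 0.11, rel=0.02)

    def test_noisy_round_trip_within_five_percent(self):
        # ±5% multiplicative noise, 100 seeds: concentrations recovered to
        # within 5% of the total-concentration scale, on average
        recipe0 = syn.SpectrumRecipe(noise_fraction=0.0)
        errs, g_errs = [], []
        for seed in range(100):
            recipe = syn.SpectrumRecipe(seed=seed)
            series = syn.gen_dose_series(recipe)
            res = deconvolve_dose_series(series, recipe0.eps_parent, recipe.c0,
                                         recipe.path_cm)
            true_c = np.clip(recipe.c0 - 4.0e-7 * res.concentrations.dose_gy.values,
                             0, None)
            errs.append(np.max(np.abs(res.concentrations.c_known.values - true_c))
                        / recipe.c0)
            g_errs.append(abs(res.g_exp / 4.0e-7 - 1.0))
        assert np.mean(errs) < 0.05
        assert np.mean(g_errs) < 0.05

    def test_rank_deficient_decomposition_flagged(self, crocin_spectrum):
        recipe = syn.SpectrumRecipe(
            eps_parent=crocin_spectrum,
            eps_product=crocin_spectrum,
            noise_fraction=0.0,
        )
        series = syn.gen_dose_series(recipe)
        res = deconvolve_dose_series(series, crocin_spectrum, recipe.c0, recipe.path_cm)
        assert any("rank_deficient" in f for f in res.flags)

    def test_wavelength_anchor_matches_max_dose_anchor(self, product_spectrum):
        recipe = syn.SpectrumRecipe(noise_fraction=0.0)
        series = syn.gen_dose_series(recipe)
        res = deconvolve_dose_series(
            series, recipe.eps_parent, recipe.c0, recipe.path_cm,
            product_anchor=(441.0, product_spectrum.value_at(441.0)),
        )
        assert res.g_exp == pytest.approx(4.0e-7, rel=0.01)

    def test_unanchored_fit_is_flagged(self):
        recipe = syn.SpectrumRecipe(noise_fraction=0.0)
        series = syn.gen_dose_series(recipe)
        res = deconvolve_dose_series(series, recipe.eps_parent, recipe.c0,
                                     recipe.path_cm, product_anchor=None)
        assert any("scale_indeterminate" in f for f in res.flags)

    def test_series_without_zero_dose_rejected(self, crocin_spectrum):
        grid = crocin_spectrum.wavelength_nm
        series = {10.0: Spectrum(grid, np.ones_like(grid), kind="absorbance")}
        with pytest.raises(ValueError):
            deconvolve_dose_series(series, crocin_spectrum, 1e-5, 0.1)


class TestGExpFromBleach:
    def test_consumption_yield_at_97_gy(self):
        # dA = 0.49 with d_eps = 1.24e5, 1 mm cell, 97 Gy
        g = g_exp_from_bleach(0.49, 1.24e5, 0.1, 97.0)
        assert g == pytest.approx(4.0e-7, rel=0.02)

    def test_zero_bleach(self):
        assert g_exp_from_bleach(0.0, 1.24e5, 0.1, 97.0) == 0.0

    def test_round_trip_with_dose_conversion(self):
        from crocin_radiolysis.radiolysis_yields import dose_to_concentration

        g_true, dose, d_eps, path = 4.0e-7, 97.0, 1.24e5, 0.1
        delta_a = dose_to_concentration(dose, g_true) * d_eps * path
        assert g_exp_from_bleach(delta_a, d_eps, path, dose) == pytest.approx(
            g_true, rel=1e-12
        )

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            g_exp_from_bleach(0.1, 0.0, 0.1, 97.0)
        with pytest.raises(ValueError):
            g_exp_from_bleach(0.1, 1e5, 0.1, 0.0)
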