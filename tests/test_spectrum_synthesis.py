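"""Line-list spectrum synthesis: subsampling, spin screening, Gaussian
convolution and probability-weighted mixing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crocin_radiolysis import synthetic_data as syn
from crocin_radiolysis.spectral_calibration import Spectrum
from crocin_radiolysis.spectrum_synthesis import (
    LineEnsemble,
    MixingWeights,
    convolve,
    mix,
    monomer_to_dimer_weights,
    spin_screen,
    subsample,
    sugar_driven_weights,
)
from crocin_radiolysis.units import HC_EV_NM


def make_ensemble(rows, ground_s2=0.75, total_steps=None):
    df = pd.DataFrame(rows, columns=["config_index", "energy_ev", "osc_strength", "s2"])
    total = total_steps if total_steps is not None else int(df.config_index.max()) + 1
    return LineEnsemble(df, ground_s2=ground_s2, total_steps=total)


class TestSubsample:
    def test_production_sampling_keeps_400_configurations(self):
        rows = [(i, 2.8, 1.0, 0.75) for i in range(60_000)]
        sub = subsample(make_ensemble(rows), burn_in=20_000, stride=100)
        assert sub.n_configurations == 400
        idx = sub.config_indices()
        assert idx.min() == 20_000
        assert np.all((idx - 20_000) % 100 == 0)

    def test_identity_subsampling(self):
        rows = [(i, 2.8, 1.0, 0.75) for i in range(10)]
        ens = make_ensemble(rows)
        sub = subsample(ens, burn_in=0, stride=1)
        assert sub.n_configurations == ens.n_configurations

    def test_empty_window_rejected(self):
        rows = [(i, 2.8, 1.0, 0.75) for i in range(20_000)]
        with pytest.raises(ValueError):
            subsample(make_ensemble(rows), burn_in=20_000, stride=100)


class TestSpinScreen:
    def test_relative_cutoff_discards_contaminated_lines(self):
        rows = [(0, 2.8, 1.0, s2) for s2 in (0.76, 0.88, 1.20)]
        kept = spin_screen(make_ensemble(rows, ground_s2=0.75), 0.20)
        assert sorted(kept.lines.s2) == [0.76, 0.88]

    def test_zero_parameter_keeps_ground_state_lines(self):
        rows = [(0, 2.8, 1.0, 0.75), (0, 3.0, 1.0, 0.75)]
        kept = spin_screen(make_ensemble(rows, ground_s2=0.75), 0.0)
        assert len(kept.lines) == 2

    def test_closed_shell_keeps_only_pure_singlets(self):
        rows = [(0, 2.8, 1.0, 0.0), (0, 3.0, 1.0, 0.4)]
        kept = spin_screen(make_ensemble(rows, ground_s2=0.0), 0.2)
        assert list(kept.lines.s2) == [0.0]

    def test_absolute_mode(self):
        rows = [(0, 2.8, 1.0, 0.9), (0, 3.0, 1.0, 1.0)]
        kept = spin_screen(make_ensemble(rows, ground_s2=0.75), 0.2, mode="absolute")
        assert list(kept.lines.s2) == [0.9]

    @settings(derandomize=True, max_examples=50)
    @given(
        s2_values=st.lists(st.floats(0.75, 2.0), min_size=1, max_size=20),
        p1=st.floats(0.0, 1.0),
        p2=st.floats(0.0, 1.0),
    )
    def test_idempotent_and_monotone(self, s2_values, p1, p2):
        rows = [(0, 2.8, 1.0, s2) for s2 in s2_values]
        ens = make_ensemble(rows, ground_s2=0.75)
        once = spin_screen(ens, p1)
        twice = spin_screen(once, p1)
        assert len(twice.lines) == len(once.lines)
        lo, hi = sorted((p1, p2))
        assert len(spin_screen(ens, lo).lines) <= len(spin_screen(ens, hi).lines)


class TestConvolve:
    def test_single_line_peaks_at_its_wavelength(self):
        ens = make_ensemble([(0, 2.8114, 3.22, 0.0)], ground_s2=0.0)
        spec = convolve(ens, 0.5)
        peak = spec.wavelength_nm[np.argmax(spec.values)]
        assert abs(peak - 441.0) <= 1.0

    @pytest.mark.parametrize("fwhm", [0.2, 0.5, 0.7])
    def test_peak_position_for_all_fwhm(self, fwhm):
        ens = make_ensemble([(0, HC_EV_NM / 500.0, 1.0, 0.0)], ground_s2=0.0)
        spec = convolve(ens, fwhm)
        peak = spec.wavelength_nm[np.argmax(spec.values)]
        assert abs(peak - 500.0) <= 1.0

    def test_energy_domain_area_equals_oscillator_strength_sum(self):
        recipe = syn.LineListRecipe(n_configurations=20, lines_per_config=5, seed=3)
        ens = syn.gen_linelist(recipe)
        for fwhm in (0.2, 0.5):
            spec = convolve(ens, fwhm, grid_nm=np.arange(120.0, 3000.0, 0.5))
            energies = HC_EV_NM / spec.wavelength_nm
            area = -np.trapezoid(spec.values, energies)
            mean_f = ens.lines.osc_strength.sum() / ens.n_configurations
            assert area == pytest.approx(mean_f, rel=0.01)

    def test_empty_ensemble_returns_zero_spectrum_with_warning(self):
        ens = make_ensemble([(0, 2.8, 1.0, 0.75)]).lines.iloc[:0]
        empty = LineEnsemble(ens, ground_s2=0.75, total_steps=1)
        with pytest.warns(UserWarning):
            spec = convolve(empty, 0.5)
        assert np.all(spec.values == 0.0)

    def test_linearity_duplicating_lines_doubles_spectrum(self):
        rows = [(0, 2.8, 1.0, 0.0), (0, 3.5, 0.5, 0.0)]
        single = convolve(make_ensemble(rows, ground_s2=0.0), 0.5)
        double = convolve(make_ensemble(rows + rows, ground_s2=0.0), 0.5)
        assert np.allclose(double.values, 2.0 * single.values)

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError):
            convolve(make_ensemble([(0, 2.8, 1.0, 0.0)]), 0.0)


class TestMix:
    def grid_specs(self):
        grid = np.arange(300.0, 601.0)
        a = Spectrum(grid, np.exp(-0.5 * ((grid - 460) / 30.0) ** 2), kind="intensity")
        b = Spectrum(grid, np.exp(-0.5 * ((grid - 415) / 30.0) ** 2), kind="intensity")
        return grid, a, b

    def test_half_sum(self):
        grid, a, b = self.grid_specs()
        out = mix({"a": a, "b": b}, {"a": 0.5, "b": 0.5})
        assert np.allclose(out.values, 0.5 * (a.values + b.values))

    def test_single_species_identity(self):
        _, a, _ = self.grid_specs()
        out = mix({"a": a}, {"a": 1.0})
        assert np.allclose(out.values, a.values)

    def test_disproportionation_combination_pattern(self):
        grid, a, b = self.grid_specs()
        specs = {"CaCa'": a, "CaCb'": b, "CaCa'cyc": a, "CbCb'cyc": b}
        weights = {"CaCa'": 0.0, "CaCb'": 0.5, "CaCa'cyc": 0.25, "CbCb'cyc": 0.25}
        out = mix(specs, weights)
        assert np.allclose(out.values, 0.75 * b.values + 0.25 * a.values)

    def test_identical_spectra_any_weights(self):
        _, a, _ = self.grid_specs()
        out = mix({"x": a, "y": a, "z": a}, {"x": 0.2, "y": 0.3, "z": 0.5})
        assert np.allclose(out.values, a.values)

    def test_missing_label_rejected(self):
        _, a, _ = self.grid_specs()
        with pytest.raises(KeyError):
            mix({"a": a}, {"a": 0.5, "b": 0.5})

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            MixingWeights({"a": 0.7, "b": 0.7})
        with pytest.raises(ValueError):
            MixingWeights({"a": -0.5, "b": 1.5})


class TestProbabilityArithmetic:
    def test_equal_monomers_give_quarter_half_quarter(self):
        w = monomer_to_dimer_weights(0.5, 0.5)
        assert dict(w.items()) == pytest.approx({"aa": 0.25, "ab": 0.5, "bb": 0.25})

    def test_sugar_driven_monomers_give_69_28_03(self):
        w = monomer_to_dimer_weights(5 / 6, 1 / 6)
        assert w["aa"] == pytest.approx(0.69, abs=0.005)
        assert w["ab"] == pytest.approx(0.28, abs=0.005)
        assert w["bb"] == pytest.approx(0.03, abs=0.005)

    def test_degenerate_pair(self):
        assert dict(monomer_to_dimer_weights(1.0, 0.0).items()) == pytest.approx(
            {"aa": 1.0, "ab": 0.0, "bb": 0.0}
        )

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.0, 1.0))
    def test_binomial_closure(self, p):
        w = monomer_to_dimer_weights(p, 1.0 - p)
        assert sum(v for _, v in w.items()) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            monomer_to_dimer_weights(0.6, 0.6)

    def test_sugar_driven_weights(self):
        w = sugar_driven_weights(1.0 / 3.0)
        assert w["a"] == pytest.approx(5.0 / 6.0)
        assert w["b"] == pytest.approx(1.0 / 6.0)
        assert dict(sugar_driven_weights(1.0).items()) == pytest.approx(
            {"a": 0.5, "b": 0.5}
        )
        assert dict(sugar_driven_weights(0.0).items()) == pytest.approx(
            {"a": 1.0, "b": 0.0}
        )
        with pytest.raises(ValueError):
            sugar_driven_weights(1.5)
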