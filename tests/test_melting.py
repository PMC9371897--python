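"""Gel quantification and Boltzmann melting-curve fits."""

import numpy as np
import pandas as pd
import pytest

from nicklattice import (
    FitError,
    GroundTruth,
    SurvivalDataset,
    TmUndefinedError,
    compare_fits,
    delta_tm,
    fit_boltzmann,
    fit_double_boltzmann,
    gen_band_table,
    gen_survival_dataset,
    survival_rates,
    yield_from_standard,
)


def band_row(lane, band, intensity, role="target", known_mass=np.nan):
    return {"lane": lane, "band": band, "intensity": intensity, "role": role, "known_mass": known_mass}


class TestYieldFromStandard:
    def test_equal_intensity_returns_known_mass(self):
        bands = pd.DataFrame([
            band_row("L1", "target", 500.0),
            band_row("ladder", "1500bp", 500.0, role="standard", known_mass=10.0),
        ])
        assert yield_from_standard(bands, "L1", "target")["mass"] == 10.0

    def test_linear_in_intensity(self):
        bands = pd.DataFrame([
            band_row("L1", "target", 1000.0),
            band_row("L2", "target", 0.0),
            band_row("ladder", "1500bp", 500.0, role="standard", known_mass=7.5),
        ])
        assert yield_from_standard(bands, "L1", "target")["mass"] == 15.0
        assert yield_from_standard(bands, "L2", "target")["mass"] == 0.0

    def test_yield_uses_input_mass(self):
        bands = pd.DataFrame([
            band_row("L1", "target", 250.0),
            band_row("ladder", "1500bp", 500.0, role="standard", known_mass=10.0),
        ])
        res = yield_from_standard(bands, "L1", "target", input_mass=20.0)
        assert res["yield"] == pytest.approx(0.25)

    def test_zero_standard_intensity_rejected(self):
        bands = pd.DataFrame([
            band_row("L1", "target", 1.0),
            band_row("ladder", "1500bp", 0.0, role="standard", known_mass=10.0),
        ])
        with pytest.raises(ZeroDivisionError):
            yield_from_standard(bands, "L1", "target")


class TestSurvivalRates:
    def test_definition(self):
        rows = [
            {**band_row("c", "t", 200.0, role="control"), "replicate": 0, "temperature_C": 4.0},
            {**band_row("a", "t", 200.0), "replicate": 0, "temperature_C": 35.0},
            {**band_row("b", "t", 80.0), "replicate": 0, "temperature_C": 55.0},
            {**band_row("d", "t", 0.0), "replicate": 0, "temperature_C": 75.0},
        ]
        data = survival_rates(pd.DataFrame(rows))
        s = data.table.set_index("temperature_C").survival
        assert s[35.0] == 1.0 and s[55.0] == pytest.approx(0.4) and s[75.0] == 0.0

    def test_zero_control_rejected(self):
        rows = [
            {**band_row("c", "t", 0.0, role="control"), "replicate": 0, "temperature_C": 4.0},
            {**band_row("a", "t", 1.0), "replicate": 0, "temperature_C": 35.0},
        ]
        with pytest.raises(ZeroDivisionError):
            survival_rates(pd.DataFrame(rows))

    def test_zero_noise_generator_round_trip(self):
        """survival_rates ∘ gen_band_table recovers the truth curve exactly."""
        truth = GroundTruth(noise_sd=0.0, intensity_sd=0.0, seed=5)
        bands = gen_band_table(truth=truth, noise_sd=0.0, seed=5)
        data = survival_rates(bands)
        temps = data.table.temperature_C.to_numpy()
        np.testing.assert_allclose(
            data.table.survival.to_numpy(), truth.curve(temps), atol=1e-12
        )


class TestFitBoltzmann:
    def test_noiseless_symmetric_sigmoid(self):
        """Noise-free data from (1, 0, 53, 3) yield Tm = T_half = 53."""
        truth = GroundTruth(s_top=1.0, s_bottom=0.0, t_half=53.0, w=3.0, noise_sd=0.0)
        data, _ = gen_survival_dataset(truth)
        fit = fit_boltzmann(data)
        assert fit.tm == pytest.approx(53.0, abs=0.01)
        assert abs(float(fit.predict(np.array([fit.tm]))[0]) - 0.5) < 1e-6

    def test_lowered_plateau_shifts_tm_below_t_half(self):
        """With S_top=0.9 the 0.5 crossing sits below the inflection point:
        T = T_half + w·ln((S_top-0.5)/(0.5-S_bot)) = 53 + 3·ln(0.8)."""
        truth = GroundTruth(s_top=0.9, s_bottom=0.0, t_half=53.0, w=3.0, noise_sd=0.0)
        data, _ = gen_survival_dataset(truth)
        fit = fit_boltzmann(data)
        expected = 53.0 + 3.0 * np.log(0.4 / 0.5)
        assert fit.tm == pytest.approx(expected, abs=0.02)
        assert fit.tm < 53.0

    def test_temperature_shift_equivariance(self):
        truth = GroundTruth(t_half=60.0, noise_sd=0.05, seed=8)
        data, _ = gen_survival_dataset(truth)
        shifted = SurvivalDataset(
            data.table.assign(temperature_C=data.table.temperature_C + 7.0)
        )
        assert fit_boltzmann(shifted).tm == pytest.approx(fit_boltzmann(data).tm + 7.0, abs=1e-3)

    def test_tm_recovery_on_noisy_triplicates(self):
        """Over seeded noisy datasets the recovered Tm stays within 1 °C."""
        truth = GroundTruth(t_half=74.0, w=3.0, noise_sd=0.05)
        errors = []
        for seed in range(50):
            data, _ = gen_survival_dataset(truth, seed=seed)
            errors.append(abs(fit_boltzmann(data).tm - truth.true_tm()))
        errors = np.array(errors)
        assert np.median(errors) < 0.5
        assert np.mean(errors < 1.0) >= 0.95

    def test_constant_data_rejected(self):
        table = pd.DataFrame(
            {"temperature_C": [30, 40, 50, 60], "replicate": 0, "survival": 1.0}
        )
        with pytest.raises(FitError):
            fit_boltzmann(SurvivalDataset(table))

    def test_no_crossing_raises_tm_undefined(self):
        truth = GroundTruth(s_top=0.45, s_bottom=0.0, t_half=53.0, noise_sd=0.0)
        data, _ = gen_survival_dataset(truth)
        with pytest.raises(TmUndefinedError):
            fit_boltzmann(data)


class TestFitDoubleBoltzmann:
    def test_noiseless_two_stage_recovery(self):
        truth = GroundTruth(model="double", phi=0.5, t1=35.0, t2=60.0, w1=2.0, w2=2.5,
                            noise_sd=0.0, temperatures=tuple(range(25, 81, 2)))
        data, _ = gen_survival_dataset(truth)
        fit = fit_double_boltzmann(data)
        assert fit.params["t1"] == pytest.approx(35.0, abs=0.5)
        assert fit.params["t2"] == pytest.approx(60.0, abs=0.5)
        assert fit.params["t1"] < fit.params["t2"]

    def test_phi_one_reduces_to_single(self):
        truth = GroundTruth(model="double", phi=1.0, t1=53.0, t2=70.0, noise_sd=0.0)
        data, _ = gen_survival_dataset(truth)
        single = fit_boltzmann(data)
        double = fit_double_boltzmann(data)
        assert double.tm == pytest.approx(single.tm, abs=0.1)

    def test_single_stage_data_prefer_single_model(self):
        truth = GroundTruth(t_half=55.0, noise_sd=0.05, seed=17)
        data, _ = gen_survival_dataset(truth)
        comparison = compare_fits(fit_boltzmann(data), fit_double_boltzmann(data))
        assert comparison["preferred"] == "single"


class TestDeltaTm:
    def test_printed_case_arithmetic(self):
        """Ligated 74 °C vs unligated 53 °C gives a ΔTm of 21 °C."""
        lig, _ = gen_survival_dataset(GroundTruth(t_half=74.0, noise_sd=0.0))
        unlig, _ = gen_survival_dataset(GroundTruth(t_half=53.0, noise_sd=0.0))
        d = delta_tm(fit_boltzmann(lig), fit_boltzmann(unlig))
        assert d == pytest.approx(21.0, abs=0.05)

    def test_identical_fits_give_zero(self):
        data, _ = gen_survival_dataset(GroundTruth(noise_sd=0.0))
        fit = fit_boltzmann(data)
        assert delta_tm(fit, fit) == 0.0

    def test_recovery_of_generated_increment(self):
        """A generated ΔTm of 15 °C is recovered within 1.5 °C from noisy data."""
        diffs = []
        for seed in range(20):
            lig, _ = gen_survival_dataset(GroundTruth(t_half=68.0, noise_sd=0.05), seed=seed)
            unlig, _ = gen_survival_dataset(GroundTruth(t_half=53.0, noise_sd=0.05), seed=seed + 1000)
            diffs.append(delta_tm(fit_boltzmann(lig), fit_boltzmann(unlig)))
        assert np.median(np.abs(np.array(diffs) - 15.0)) < 1.5
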