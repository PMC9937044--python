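"""ERG amplitude extraction, V/log(I) fitting, curve building, schedules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opsintune.erg import (
    ERGTrace,
    FlashSeries,
    build_sensitivity_curve,
    fit_vlogi,
    linearize_responses,
    naka_rushton,
    response_amplitude,
    series_response,
    stimulus_schedule,
)
from opsintune.simulate import FlashProtocol, PhotoreceptorModel, simulate_trace
from opsintune.templates import SpectralTemplate, evaluate_template


def _trace(voltage, fs=1000.0, onset=0.2, offset=0.4, lam=500.0, flux=1e14):
    t = np.arange(len(voltage)) / fs
    return ERGTrace(t, np.asarray(voltage, float), onset, offset, lam, flux)


class TestResponseAmplitude:
    def test_flat_trace_zero(self):
        tr = _trace(np.full(600, -0.5))
        assert response_amplitude(tr) == pytest.approx(0.0)

    def test_step_plateau(self):
        v = np.zeros(600)
        v[210:401] = -8.0  # sustained plateau spanning the pre-offset window
        assert response_amplitude(_trace(v)) == pytest.approx(8.0)

    @settings(derandomize=True, max_examples=25)
    @given(offset=st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_invariant_to_constant_offset(self, offset):
        v = np.zeros(600)
        v[210:401] = -8.0
        base = response_amplitude(_trace(v))
        shifted = response_amplitude(_trace(v + offset))
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_synthetic_trace_with_transients_and_noise(self):
        """On/off transients sit outside the analysis window; amplitude
        recovers the known plateau depth within 0.3 mV at noise sd 0.1."""
        tpl = SpectralTemplate("stavenga_band", 500.0)
        model = PhotoreceptorModel(template=tpl, v_max=8.0, transient_amp=3.0,
                                   noise_sd=0.1)
        tr = simulate_trace(model, 500.0, 1e19, rng=123)  # saturating flux
        assert response_amplitude(tr) == pytest.approx(8.0, abs=0.3)

    def test_flash_window_outside_trace_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ERGTrace(np.arange(10) / 1000, np.zeros(10), 0.2, 0.4, 500.0, 1e14)

    def test_empty_analysis_window_rejected(self):
        # coarse 100 Hz sampling leaves no sample inside a tiny window that
        # ends between two sample times
        t = np.arange(60) / 100.0
        tr = ERGTrace(t, np.zeros(60), 0.2, 0.395, 500.0, 1e14)
        with pytest.raises(ValueError, match="window"):
            response_amplitude(tr, window_ms=1e-3)


class TestSeriesResponse:
    def test_identical_flashes(self):
        v = np.zeros(600)
        v[210:401] = -5.0
        series = FlashSeries([_trace(v) for _ in range(10)])
        assert series_response(series) == pytest.approx(5.0)

    def test_last_five_mean(self):
        traces = []
        for amp in range(1, 11):
            v = np.zeros(600)
            v[210:401] = -float(amp)
            traces.append(_trace(v))
        assert series_response(FlashSeries(traces), n_last=5) == pytest.approx(8.0)

    def test_too_few_flashes_rejected(self):
        v = np.zeros(600)
        v[210:401] = -5.0
        with pytest.raises(ValueError, match="flashes"):
            series_response(FlashSeries([_trace(v)] * 3), n_last=5)

    def test_adaptation_series_approaches_asymptote(self):
        from opsintune.simulate import simulate_flash_series

        tpl = SpectralTemplate("stavenga_band", 500.0)
        model = PhotoreceptorModel(template=tpl, noise_sd=0.0)
        series, truth = simulate_flash_series(model, 500.0, 1e14)
        asymptote = model.plateau_depth(500.0, 1e14)
        assert series_response(series) == pytest.approx(asymptote, rel=0.05)


class TestVlogI:
    I = np.geomspace(1.14e12, 3.6e16, 9)

    def test_half_saturation_identity(self):
        """For exact V = I/(I+K): fitted K equals the half-max intensity and
        becomes the test intensity."""
        V = self.I / (self.I + 1e14)
        fit = fit_vlogi(self.I, V)
        assert fit.K == pytest.approx(1e14, rel=1e-3)
        assert fit.n_exp == pytest.approx(1.0, rel=1e-3)
        assert fit.saturated
        assert fit.test_intensity == pytest.approx(fit.K)
        assert fit.predict(fit.K) == pytest.approx(fit.v_max / 2, rel=1e-6)

    def test_noiseless_parameter_recovery(self):
        V = naka_rushton(self.I, 12.0, 3e13, 0.8)
        fit = fit_vlogi(self.I, V)
        assert fit.v_max == pytest.approx(12.0, rel=1e-3)
        assert fit.K == pytest.approx(3e13, rel=1e-3)
        assert fit.n_exp == pytest.approx(0.8, rel=1e-3)

    def test_noisy_parameter_recovery_within_10pct(self):
        rng = np.random.default_rng(7)
        V = np.clip(naka_rushton(self.I, 12.0, 3e13, 0.8) + rng.normal(0, 0.2, 9), 0, None)
        fit = fit_vlogi(self.I, V)
        assert fit.v_max == pytest.approx(12.0, rel=0.10)
        assert fit.K == pytest.approx(3e13, rel=0.10)
        assert fit.n_exp == pytest.approx(0.8, rel=0.15)

    def test_linear_responses_not_saturated(self):
        V = np.log10(self.I) - 11.5
        fit = fit_vlogi(self.I, V)
        assert not fit.saturated
        assert self.I.min() <= fit.test_intensity <= self.I.max()

    def test_sigmoid_equivalent_and_auto_prefers_naka_rushton(self):
        V = naka_rushton(self.I, 12.0, 3e13, 0.8)
        sig = fit_vlogi(self.I, V, model="sigmoid")
        assert sig.K == pytest.approx(3e13, rel=1e-3)
        auto = fit_vlogi(self.I, V, model="auto")
        assert auto.model == "naka_rushton"

    def test_decreasing_responses_rejected(self):
        with pytest.raises(ValueError, match="Spearman|decrease"):
            fit_vlogi(self.I, np.linspace(5, 1, 9))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fit_vlogi(self.I[:3], np.array([1.0, 2.0, 3.0]))

    def test_linearization_inverts_the_nonlinearity(self):
        V = naka_rushton(self.I, 12.0, 1e14, 0.8)
        fit = fit_vlogi(self.I, V)
        S = linearize_responses(naka_rushton(np.array([5e13]), 12.0, 1e14, 0.8),
                                fit, test_intensity=1e14)
        assert S[0] == pytest.approx(0.5, rel=1e-3)


class TestBuildCurve:
    lam = np.arange(315.0, 551.0, 5.0)

    def test_single_smooth_curve_near_identity(self):
        y = evaluate_template(SpectralTemplate("stavenga_band", 450.0), self.lam)
        curve = build_sensitivity_curve([(self.lam, y)])
        assert np.allclose(curve.mean_sensitivity, y / y.max(), atol=0.01)

    def test_scale_invariance_across_animals(self):
        y = evaluate_template(SpectralTemplate("stavenga_band", 450.0), self.lam)
        curve = build_sensitivity_curve([(self.lam, y), (self.lam, 3.7 * y)])
        assert np.allclose(curve.sd, 0.0, atol=1e-12)
        assert curve.n_animals == 2

    def test_normalization_invariant(self):
        rng = np.random.default_rng(3)
        series = [
            (self.lam, np.clip(
                evaluate_template(SpectralTemplate("stavenga_band", 500.0), self.lam)
                + rng.normal(0, 0.05, self.lam.size), 0, None))
            for _ in range(4)
        ]
        curve = build_sensitivity_curve(series)
        assert curve.mean_sensitivity.max() == pytest.approx(1.0)
        assert np.all(curve.mean_sensitivity >= 0.0)

    def test_savgol_preserves_linear_polynomials(self):
        y = 0.001 * (self.lam - 300.0)  # linear in wavelength
        curve = build_sensitivity_curve([(self.lam, y)])
        assert np.allclose(curve.mean_sensitivity, y / y.max(), atol=1e-12)

    def test_mismatched_grids_rejected(self):
        y = np.ones(self.lam.size)
        with pytest.raises(ValueError, match="grid"):
            build_sensitivity_curve([(self.lam, y), (self.lam + 2.5, y)])

    def test_window_larger_than_span_rejected(self):
        lam = np.arange(400.0, 411.0, 5.0)
        with pytest.raises(ValueError, match="window"):
            build_sensitivity_curve([(lam, np.ones(3))], window_nm=50.0)


class TestSchedule:
    def test_permutation_covers_every_wavelength_once(self):
        order = stimulus_schedule(315.0, 550.0, 5.0, seed=0)
        assert len(order) == 48
        assert sorted(order) == list(np.arange(315.0, 551.0, 5.0))

    def test_cycles_low_mid_high(self):
        order = stimulus_schedule(315.0, 550.0, 5.0, seed=1)
        lams = np.arange(315.0, 551.0, 5.0)
        low, mid, high = np.array_split(lams, 3)
        assert all(x in low for x in order[0::3])
        assert all(x in mid for x in order[1::3])
        assert all(x in high for x in order[2::3])

    def test_deterministic_under_seed(self):
        a = stimulus_schedule(315.0, 550.0, 5.0, seed=11)
        b = stimulus_schedule(315.0, 550.0, 5.0, seed=11)
        c = stimulus_schedule(315.0, 550.0, 5.0, seed=12)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            stimulus_schedule(550.0, 315.0, 5.0, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            stimulus_schedule(315.0, 552.0, 5.0, seed=0)
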