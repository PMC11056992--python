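"""Dielectric loss model, HN peak-time conversion, fitting, shape metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amorphdyn import spectra
from amorphdyn.spectra import (
    EPS0, HNProcess, LossSpectrum, SpectrumModel, evaluate_model, fit_spectrum,
    hn_peak_time, hn_time_from_peak, shape_metrics,
)

F_GRID = np.logspace(-3, 5, 200)

DEBYE_FWHM_DECADES = np.log10((2 + np.sqrt(3)) / (2 - np.sqrt(3)))  # 1.1439


def numerical_peak_time(alpha, beta, tau_hn=1.0, n=400_001):
    """Independent oracle: maximise the HN loss on a dense log-omega grid."""
    w = 10.0 ** np.linspace(-6, 6, n) / tau_hn
    loss = -(1.0 / (1.0 + (1j * w * tau_hn) ** alpha) ** beta).imag
    return 1.0 / w[np.argmax(loss)]


class TestEvaluateModel:
    def test_debye_peak_position_and_height(self):
        model = SpectrumModel(processes=(HNProcess(1.0, 1.0, 1.0, 1.0),))
        f = np.logspace(-4, 4, 20001)
        loss = evaluate_model(model, f)
        i = np.argmax(loss)
        assert loss[i] == pytest.approx(0.5, rel=1e-6)
        assert f[i] == pytest.approx(1 / (2 * np.pi), rel=1e-3)

    def test_conductivity_only_slope_minus_one(self):
        model = SpectrumModel(processes=(HNProcess(1e-30, 1.0, 1.0, 1.0),),
                              sigma_dc=1e-11)
        loss = evaluate_model(model, F_GRID)
        slope = np.polyfit(np.log10(F_GRID), np.log10(loss), 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-9)

    def test_two_process_additivity(self):
        p1 = HNProcess(3.0, 1e-2, 0.8, 0.5)
        p2 = HNProcess(0.5, 1e-7, 0.6, 1.0)
        combined = evaluate_model(
            SpectrumModel(processes=(p1, p2), sigma_dc=2e-12), F_GRID)
        parts = (evaluate_model(SpectrumModel(processes=(p1,)), F_GRID)
                 + evaluate_model(SpectrumModel(processes=(p2,)), F_GRID)
                 + 2e-12 / (EPS0 * 2 * np.pi * F_GRID))
        np.testing.assert_allclose(combined, parts, rtol=1e-14)

    def test_complex_output_consistent_with_loss(self):
        model = SpectrumModel(processes=(HNProcess(2.0, 1e-3, 0.7, 0.6),),
                              sigma_dc=1e-12, eps_inf=2.5)
        z = evaluate_model(model, F_GRID, want="complex")
        np.testing.assert_allclose(-z.imag, evaluate_model(model, F_GRID),
                                   rtol=1e-12)
        assert np.all(z.real > 0)

    def test_rejects_nonpositive_frequency(self):
        model = SpectrumModel(processes=(HNProcess(1.0, 1.0, 1.0, 1.0),))
        with pytest.raises(ValueError):
            evaluate_model(model, np.array([-1.0, 1.0]))

    def test_rejects_invalid_shape_parameters(self):
        with pytest.raises(ValueError):
            HNProcess(1.0, 1.0, 1.4, 0.5)
        with pytest.raises(ValueError):
            HNProcess(1.0, 1.0, 0.5, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(alpha=st.floats(0.1, 1.0), beta=st.floats(0.1, 1.0),
           de=st.floats(1e-3, 1e3), ltau=st.floats(-9, 3))
    def test_loss_nonnegative_for_valid_parameters(self, alpha, beta, de, ltau):
        model = SpectrumModel(processes=(HNProcess(de, 10.0 ** ltau,
                                                   alpha, beta),))
        assert np.all(evaluate_model(model, F_GRID) >= 0)


class TestHNPeakTime:
    def test_debye_limit_is_identity(self):
        assert hn_peak_time(HNProcess(1.0, 1e-3, 1.0, 1.0)) == \
            pytest.approx(1e-3, rel=1e-12)

    def test_closed_form_matches_numerical_oracle(self):
        tau = hn_peak_time(HNProcess(1.0, 1.0, 0.8, 0.5))
        assert tau == pytest.approx(numerical_peak_time(0.8, 0.5), rel=1e-3)

    def test_peak_shift_monotone_in_beta(self):
        # direction established by the oracle: broader high-frequency flank
        # (smaller beta) pushes the peak to higher f, i.e. smaller tau_alpha
        oracle = [numerical_peak_time(0.8, b, n=100_001)
                  for b in (0.3, 0.6, 1.0)]
        assert oracle[0] < oracle[1] < oracle[2]
        closed = [hn_peak_time(HNProcess(1.0, 1.0, 0.8, b))
                  for b in (0.3, 0.6, 1.0)]
        assert closed[0] < closed[1] < closed[2]

    def test_inverse_round_trip(self):
        for a, b in [(0.3, 0.9), (0.85, 0.6), (1.0, 1.0)]:
            tau_hn = hn_time_from_peak(2.5e-4, a, b)
            assert hn_peak_time(HNProcess(1.0, tau_hn, a, b)) == \
                pytest.approx(2.5e-4, rel=1e-12)


def _make_spectrum(model, f=None, noise=0.0, seed=0, T=280.0, p=0.1):
    f = np.logspace(-2, 6, 321) if f is None else f
    loss = evaluate_model(model, f)
    if noise:
        loss = loss * np.exp(np.random.default_rng(seed).normal(0, noise,
                                                                loss.shape))
    return LossSpectrum(f, loss, temperature_K=T, pressure_MPa=p)


class TestFitSpectrum:
    def test_noise_free_single_process_recovery(self):
        truth = SpectrumModel(processes=(HNProcess(4.0, 2e-2, 0.85, 0.55),),
                              sigma_dc=3e-12)
        res = fit_spectrum(_make_spectrum(truth), n_processes=1)
        got = res.model.processes[0]
        want = truth.processes[0]
        assert res.converged
        assert got.delta_eps == pytest.approx(want.delta_eps, rel=1e-4)
        assert got.tau_hn_s == pytest.approx(want.tau_hn_s, rel=1e-4)
        assert got.alpha_shape == pytest.approx(want.alpha_shape, rel=1e-4)
        assert got.beta_shape == pytest.approx(want.beta_shape, rel=1e-4)
        assert res.model.sigma_dc == pytest.approx(truth.sigma_dc, rel=1e-4)

    def test_one_percent_noise_within_five_percent(self):
        truth = SpectrumModel(processes=(HNProcess(4.0, 2e-2, 0.85, 0.55),),
                              sigma_dc=3e-12)
        res = fit_spectrum(_make_spectrum(truth, noise=0.01, seed=42),
                           n_processes=1)
        got = res.model.processes[0]
        want = truth.processes[0]
        for g, w in [(got.delta_eps, want.delta_eps),
                     (got.tau_hn_s, want.tau_hn_s),
                     (got.alpha_shape, want.alpha_shape),
                     (got.beta_shape, want.beta_shape),
                     (res.model.sigma_dc, truth.sigma_dc)]:
            assert g == pytest.approx(w, rel=0.05)

    def test_conductivity_only_flags_unidentifiable_process(self):
        truth = SpectrumModel(processes=(HNProcess(1e-30, 1.0, 1.0, 1.0),),
                              sigma_dc=1e-11)
        f = np.logspace(-2, 2, 60)
        sp = LossSpectrum(f, 1e-11 / (EPS0 * 2 * np.pi * f),
                          temperature_K=280.0, pressure_MPa=0.1)
        res = fit_spectrum(sp, n_processes=1)
        de = res.model.processes[0].delta_eps
        err = res.param_stderr.get("delta_eps0")
        assert de < 1e-4 or err is None or err > de

    def test_too_few_points_raises(self):
        truth = SpectrumModel(processes=(HNProcess(1.0, 1.0, 1.0, 1.0),))
        f = np.logspace(-1, 1, 9)
        sp = LossSpectrum(f, evaluate_model(truth, f), temperature_K=280.0,
                          pressure_MPa=0.1)
        with pytest.raises(ValueError):
            fit_spectrum(sp, n_processes=2)

    def test_window_restricts_points_used(self):
        truth = SpectrumModel(processes=(HNProcess(4.0, 2e-2, 0.85, 0.55),),
                              sigma_dc=0.0)
        sp = _make_spectrum(truth)
        res = fit_spectrum(sp, n_processes=1, include_conductivity=False,
                           window=(1e-1, 1e4))
        assert res.n_points_used < len(sp.frequency_hz)
        assert res.model.processes[0].tau_hn_s == pytest.approx(2e-2, rel=1e-3)

    def test_deterministic_given_same_input(self):
        truth = SpectrumModel(processes=(HNProcess(4.0, 2e-2, 0.85, 0.55),),
                              sigma_dc=3e-12)
        sp = _make_spectrum(truth, noise=0.01, seed=3)
        r1 = fit_spectrum(sp, n_processes=1)
        r2 = fit_spectrum(sp, n_processes=1)
        assert r1.model == r2.model


class TestShapeMetrics:
    def test_debye_fwhm_closed_form(self):
        model = SpectrumModel(processes=(HNProcess(1.0, 1.0, 1.0, 1.0),))
        sm = shape_metrics(model)
        assert sm.fwhm_decades == pytest.approx(DEBYE_FWHM_DECADES, rel=1e-4)
        assert sm.left_halfwidth_decades == \
            pytest.approx(sm.right_halfwidth_decades, rel=1e-3)
        assert sm.f_max_hz == pytest.approx(1 / (2 * np.pi), rel=1e-3)

    def test_broadening_exceeds_debye(self):
        broad = shape_metrics(SpectrumModel(
            processes=(HNProcess(1.0, 1.0, 0.6, 1.0),)))
        assert broad.fwhm_decades > DEBYE_FWHM_DECADES

    def test_invariance_under_time_and_amplitude_rescaling(self):
        a = shape_metrics(SpectrumModel(processes=(HNProcess(1.0, 1.0,
                                                             0.8, 0.5),)))
        b = shape_metrics(SpectrumModel(processes=(HNProcess(7.0, 1e-4,
                                                             0.8, 0.5),)))
        assert a.fwhm_decades == pytest.approx(b.fwhm_decades, abs=2e-3)
        assert a.left_halfwidth_decades == \
            pytest.approx(b.left_halfwidth_decades, abs=2e-3)
        assert b.f_max_hz == pytest.approx(a.f_max_hz * 1e4, rel=1e-2)

    def test_monotone_spectrum_raises(self):
        f = np.logspace(-2, 2, 50)
        sp = LossSpectrum(f, 1.0 / f, temperature_K=280.0, pressure_MPa=0.1)
        with pytest.raises(ValueError):
            shape_metrics(sp)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        truth = SpectrumModel(processes=(HNProcess(4.0, 2e-2, 0.85, 0.55),),
                              sigma_dc=3e-12)
        sp = [_make_spectrum(truth, T=270.0), _make_spectrum(truth, T=280.0)]
        path = tmp_path / "spectra.csv"
        spectra.write_spectra(sp, path)
        back = spectra.read_spectra(path)
        assert len(back) == 2
        np.testing.assert_allclose(back[0].loss, sp[0].loss)
        assert {s.temperature_K for s in back} == {270.0, 280.0}
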