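import numpy as np
import pytest
from scipy import signal, special

import ctnet
from ctnet.errors import DegenerateSignalError
from ctnet.metrics import band_power

from .conftest import sine_result


class TestWelchPsd:
    def test_single_tone_power_concentrated_in_band(self):
        res = sine_result(10.0, fs=1000.0, duration=20.0)
        spec = ctnet.welch_psd(res)
        total = band_power(spec, (0.5, 499.0))[0]
        alpha = band_power(spec, (8, 13))[0]
        assert alpha / total >= 0.95

    def test_parseval_consistency_on_stationary_noise(self):
        rng = np.random.default_rng(5)
        series = rng.standard_normal((1, 50_000))
        res = ctnet.SimulationResult(series=series, fs=250.0, seed=5,
                                     params_hash="x")
        spec = ctnet.welch_psd(res)
        integral = np.trapezoid(spec.psd[0], spec.freqs)
        assert integral == pytest.approx(series.var(), rel=0.05)

    def test_white_noise_alpha_share_matches_flat_spectrum(self):
        # flat spectrum: alpha share of total power = 5 Hz / (fs/2)
        shares = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = ctnet.SimulationResult(
                series=rng.standard_normal((1, 20_000)), fs=250.0, seed=seed,
                params_hash="x",
            )
            spec = ctnet.welch_psd(res)
            shares.append(
                band_power(spec, (8, 13))[0] / band_power(spec, (0.0, 125.0))[0]
            )
        assert np.mean(shares) == pytest.approx(5.0 / 125.0, rel=0.10)

    def test_constant_signal_has_no_nonzero_frequency_power(self):
        res = ctnet.SimulationResult(
            series=np.full((1, 5000), 3.7), fs=250.0, seed=0, params_hash="x"
        )
        spec = ctnet.welch_psd(res)
        assert band_power(spec, (1.0, 120.0))[0] == pytest.approx(0.0, abs=1e-20)

    def test_series_shorter_than_window_rejected(self):
        res = ctnet.SimulationResult(
            series=np.zeros((1, 100)), fs=250.0, seed=0, params_hash="x"
        )
        with pytest.raises(ValueError, match="shorter than one"):
            ctnet.welch_psd(res, window_s=4.0)


class TestAlphaPower:
    def test_linearity_in_psd(self):
        res = sine_result(10.0, noise=0.1, seed=1)
        spec = ctnet.welch_psd(res)
        doubled = ctnet.SpectrumEstimate(
            freqs=spec.freqs, psd=2 * spec.psd,
            window_s=spec.window_s, overlap=spec.overlap,
        )
        assert ctnet.alpha_power(doubled) == pytest.approx(
            2 * ctnet.alpha_power(spec)
        )

    def test_region_mean_of_band_powers(self):
        spec = ctnet.welch_psd(sine_result(10.0, noise=0.05, n_regions=1, seed=2))
        psd2 = np.vstack([spec.psd, 3 * spec.psd])
        spec2 = ctnet.SpectrumEstimate(
            freqs=spec.freqs, psd=psd2, window_s=spec.window_s,
            overlap=spec.overlap,
        )
        p = band_power(spec, (8, 13))[0]
        assert ctnet.alpha_power(spec2) == pytest.approx(2 * p, rel=1e-10)

    def test_out_of_band_tone_leaks_negligibly(self):
        res = sine_result(20.0, fs=250.0, duration=40.0)
        spec = ctnet.welch_psd(res)
        tone = band_power(spec, (18, 22))[0]
        # Hann sidelobe leakage bound: alpha-band content far below the tone
        assert ctnet.alpha_power(spec) < 1e-6 * tone

    def test_band_outside_grid_rejected(self):
        spec = ctnet.welch_psd(sine_result(10.0, fs=250.0))
        with pytest.raises(ValueError, match="outside frequency range"):
            ctnet.alpha_power(spec, band=(8, 1000.0))

    def test_commutes_with_region_reordering(self):
        rng = np.random.default_rng(9)
        series = rng.standard_normal((5, 10_000))
        res = ctnet.SimulationResult(series=series, fs=250.0, seed=9,
                                     params_hash="x")
        perm = [3, 0, 4, 1, 2]
        res_p = ctnet.SimulationResult(series=series[perm], fs=250.0, seed=9,
                                       params_hash="x")
        assert ctnet.alpha_power(ctnet.welch_psd(res)) == pytest.approx(
            ctnet.alpha_power(ctnet.welch_psd(res_p))
        )


class TestPlv:
    def test_identical_series_give_unit_plv(self):
        base = sine_result(10.0, noise=0.2, seed=3)
        res = ctnet.SimulationResult(
            series=np.vstack([base.series, base.series]), fs=base.fs, seed=3,
            params_hash="x",
        )
        mat = ctnet.plv_matrix(res)
        assert mat.plv[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_constant_lag_within_band_gives_unit_plv(self):
        a = sine_result(10.0)
        b = sine_result(10.0, phase=np.pi / 3)
        res = ctnet.SimulationResult(
            series=np.vstack([a.series, b.series]), fs=a.fs, seed=0,
            params_hash="x",
        )
        mat = ctnet.plv_matrix(res)
        assert mat.plv[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_matches_rayleigh_oracle(self):
        # Monte-Carlo oracle: |mean of N unit phasors with iid phases|,
        # with N the effective number of independent phase samples derived
        # from the band-pass filter's analytic autocorrelation and the exact
        # Gaussian phase-difference phasor correlation
        # E[e^{i dphi}] = (pi/4) r 2F1(1/2, 1/2; 2; r^2) per process.
        fs, duration, band, trim = 250.0, 20.0, (8.0, 13.0), 1.0
        _, h = signal.sosfreqz(
            signal.butter(4, band, btype="bandpass", fs=fs, output="sos"),
            worN=2 ** 15, fs=fs,
        )
        spec = np.abs(h) ** 4  # forward-backward application squares |H|^2
        full = np.zeros(2 * spec.size - 2, dtype=complex)
        full[: spec.size] = spec  # one-sided spectrum -> analytic acf
        rho = np.fft.ifft(full)
        r = np.abs(rho) / np.abs(rho[0])
        phasor_acf = (
            (np.pi / 4) * r * special.hyp2f1(0.5, 0.5, 2.0, r ** 2)
        ) ** 2
        tau_eff = phasor_acf.sum() / fs  # both lag signs via wraparound
        n_eff = int(round((duration - 2 * trim) / tau_eff))
        rng = np.random.default_rng(11)
        oracle = np.abs(
            np.exp(1j * rng.uniform(0, 2 * np.pi, (1000, n_eff))).mean(axis=1)
        ).mean()
        plvs = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            res = ctnet.SimulationResult(
                series=r.standard_normal((2, int(duration * fs))), fs=fs,
                seed=seed, params_hash="x",
            )
            plvs.append(ctnet.plv_matrix(res, band=band).plv[0, 1])
        assert np.mean(plvs) == pytest.approx(oracle, rel=0.15)

    def test_invariant_to_amplitude_rescaling(self):
        rng = np.random.default_rng(13)
        series = rng.standard_normal((3, 6000))
        res = ctnet.SimulationResult(series=series, fs=250.0, seed=13,
                                     params_hash="x")
        scaled = ctnet.SimulationResult(
            series=series * np.array([[2.0], [0.01], [300.0]]), fs=250.0,
            seed=13, params_hash="x",
        )
        np.testing.assert_allclose(
            ctnet.plv_matrix(res).plv, ctnet.plv_matrix(scaled).plv, atol=1e-9
        )

    def test_constant_region_raises_degenerate_error(self):
        series = np.vstack([np.ones(6000), np.random.default_rng(0).standard_normal(6000)])
        res = ctnet.SimulationResult(series=series, fs=250.0, seed=0,
                                     params_hash="x")
        with pytest.raises(DegenerateSignalError):
            ctnet.plv_matrix(res)

    def test_single_region_rejected(self):
        res = sine_result(10.0)
        with pytest.raises(ValueError, match="at least 2 regions"):
            ctnet.plv_matrix(res)

    def test_matrix_invariants(self):
        rng = np.random.default_rng(17)
        res = ctnet.SimulationResult(
            series=rng.standard_normal((4, 8000)), fs=250.0, seed=17,
            params_hash="x",
        )
        mat = ctnet.plv_matrix(res)
        np.testing.assert_array_equal(mat.plv, mat.plv.T)
        np.testing.assert_allclose(np.diag(mat.plv), 1.0)
        assert np.all(mat.plv >= 0) and np.all(mat.plv <= 1)


class TestMeanPlv:
    def test_constant_off_diagonal(self):
        p = np.full((4, 4), 0.5)
        np.fill_diagonal(p, 1.0)
        assert ctnet.mean_plv(ctnet.ConnectivityMatrix(plv=p)) == pytest.approx(0.5)

    def test_three_by_three_mean(self):
        p = np.eye(3)
        p[0, 1] = p[1, 0] = 0.2
        p[0, 2] = p[2, 0] = 0.4
        p[1, 2] = p[2, 1] = 0.6
        assert ctnet.mean_plv(ctnet.ConnectivityMatrix(plv=p)) == pytest.approx(0.4)

    def test_identity_matrix_gives_zero(self):
        assert ctnet.mean_plv(ctnet.ConnectivityMatrix(plv=np.eye(5))) == 0.0

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            ctnet.mean_plv(ctnet.ConnectivityMatrix(plv=np.eye(1)))


class TestPercentChange:
    @pytest.mark.parametrize(
        "value,baseline,expected",
        [(2.566, 1.0, 156.6), (1.0, 1.0, 0.0), (0.41, 1.0, -59.0)],
    )
    def test_printed_percentages_reproduced(self, value, baseline, expected):
        assert ctnet.percent_change(value, baseline) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ctnet.percent_change(1.0, 0.0)
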