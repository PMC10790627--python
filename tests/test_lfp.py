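import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oscsync import assign_layers, detect_extrema, fit_spectral_model, welch_psd
from oscsync.lfp import LayerAssignmentError

FS = 1000.0
T = np.arange(0, 2.2, 1 / FS)


def _laminar_profile(depths, peak_depth, early=True):
    """Trial-averaged traces with an early response peaked at one depth."""
    lfp = np.zeros((len(depths), T.size))
    for i, d in enumerate(depths):
        gain = np.exp(-((d - peak_depth) ** 2) / (2 * 80.0**2))
        bump = np.exp(-((T - 0.6) ** 2) / (2 * 0.02**2))  # 100 ms post onset
        late = np.exp(-((T - 1.0) ** 2) / (2 * 0.05**2))
        lfp[i] = -60 * gain * bump + 30 * (1 - gain) * late
    return lfp


class TestAssignLayers:
    def test_middle_is_early_response_argmax(self):
        depths = np.array([100.0, 250.0, 400.0, 550.0, 700.0])
        cols = np.zeros(5, dtype=int)
        la = assign_layers(_laminar_profile(depths, 400.0), depths, cols)
        tri = la.columns[0]
        assert depths[tri.middle_channel] == 400.0
        assert tri.band == (300.0, 500.0)
        assert depths[tri.superficial_channel] < 300.0
        assert depths[tri.deep_channel] > 500.0

    def test_exact_tie_goes_to_shallower_channel(self):
        depths = np.array([100.0, 300.0, 600.0, 900.0])
        cols = np.zeros(4, dtype=int)
        lfp = np.zeros((4, T.size))
        bump = np.exp(-((T - 0.6) ** 2) / (2 * 0.02**2))
        lfp[1] = 50 * bump
        lfp[2] = 50 * bump  # exact tie with channel 1
        lfp[0] = 5 * bump
        lfp[3] = 5 * bump
        la = assign_layers(lfp, depths, cols)
        assert la.columns[0].middle_channel == 1  # shallower of the tied pair

    def test_too_few_channels_rejected(self):
        depths = np.array([100.0, 150.0])
        with pytest.raises(LayerAssignmentError, match=">= 3 channels"):
            assign_layers(np.zeros((2, T.size)), depths, np.zeros(2, dtype=int))

    def test_no_channel_below_band_rejected(self):
        depths = np.array([100.0, 200.0, 380.0, 400.0])
        cols = np.zeros(4, dtype=int)
        lfp = np.zeros((4, T.size))
        lfp[3] = 50 * np.exp(-((T - 0.6) ** 2) / (2 * 0.02**2))  # middle = deepest
        with pytest.raises(LayerAssignmentError, match="below"):
            assign_layers(lfp, depths, cols)

    def test_invariant_to_trial_order(self):
        rng = np.random.default_rng(0)
        depths = np.array([100.0, 300.0, 500.0, 700.0])
        trials = rng.standard_normal((6, 4, T.size)) * 5
        trials[:, 2] += 40 * np.exp(-((T - 0.6) ** 2) / (2 * 0.02**2))
        la1 = assign_layers(trials.mean(0), depths, np.zeros(4, dtype=int))
        la2 = assign_layers(trials[::-1].mean(0), depths, np.zeros(4, dtype=int))
        assert la1 == la2


class TestDetectExtrema:
    def test_sinusoid_extrema_spacing_and_amplitude(self):
        lfp = 40.0 * np.cos(2 * np.pi * 6 * (T - 0.5))
        ext = detect_extrema(lfp, onset=0.5)
        gaps = np.diff(ext.times)
        assert np.allclose(gaps, 1 / 12, atol=0.003)  # ~83.3 ms / 2 per extremum
        assert ext.mean_t2p_early == pytest.approx(80.0, rel=0.01)
        assert len(ext.times) >= 10

    def test_alternation(self):
        lfp = 40.0 * np.cos(2 * np.pi * 6 * (T - 0.5))
        ext = detect_extrema(lfp, onset=0.5)
        assert np.all(ext.is_peak[:-1] != ext.is_peak[1:])

    def test_below_threshold_gives_empty_set(self):
        lfp = 10.0 * np.cos(2 * np.pi * 6 * T)
        ext = detect_extrema(lfp, onset=0.5)
        assert len(ext.times) == 0

    def test_close_candidates_keep_larger(self):
        # two positive bumps 30 ms apart; only the larger may survive
        lfp = np.zeros(T.size)
        lfp += 40 * np.exp(-((T - 0.80) ** 2) / (2 * 0.005**2))
        lfp += 60 * np.exp(-((T - 0.83) ** 2) / (2 * 0.005**2))
        ext = detect_extrema(lfp, onset=0.5)
        peaks = ext.times[ext.is_peak]
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(0.83, abs=0.002)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariants_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        lfp = 60 * rng.standard_normal(T.size)
        # mild smoothing so extrema are well defined
        lfp = np.convolve(lfp, np.ones(25) / 25, mode="same")
        ext = detect_extrema(lfp, onset=0.5)
        assert np.all(np.abs(ext.amplitudes) > 25.0)
        if len(ext.times) > 1:
            assert np.all(np.diff(ext.times) >= 0.05 - 1e-9)
            assert np.all(ext.is_peak[:-1] != ext.is_peak[1:])


class TestWelchPsd:
    def test_pure_tone_peak_bin(self):
        x = 20 * np.sin(2 * np.pi * 6 * T)
        f, p = welch_psd(x)
        assert abs(f[np.argmax(p)] - 6.0) <= 1 / 0.7  # within one bin

    def test_quadratic_amplitude_scaling(self):
        x = np.sin(2 * np.pi * 6 * T)
        f, p1 = welch_psd(x)
        _, p2 = welch_psd(2 * x)
        band = (f >= 4) & (f <= 8)
        ratio = np.trapezoid(p2[band], f[band]) / np.trapezoid(p1[band], f[band])
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="window"):
            welch_psd(np.zeros(500))

    def test_white_noise_mean_exponent_near_zero(self):
        rng = np.random.default_rng(6)
        exps = []
        for _ in range(100):
            f, p = welch_psd(rng.standard_normal(2000))
            exps.append(fit_spectral_model(f, p).exponent)
        assert abs(np.mean(exps)) < 0.1


class TestSpectralFit:
    FREQS = np.linspace(1, 40, 120)

    def _forward(self, offset, exponent, peaks=()):
        logp = offset - exponent * np.log10(self.FREQS)
        for c, h, sd in peaks:
            logp = logp + h * np.exp(-((self.FREQS - c) ** 2) / (2 * sd**2))
        return 10.0**logp

    @pytest.mark.parametrize("exponent", [0.5, 1.0, 1.5, 2.0])
    def test_kneefree_exponent_recovery(self, exponent):
        fit = fit_spectral_model(self.FREQS, self._forward(1.0, exponent))
        assert fit.exponent == pytest.approx(exponent, abs=0.05)
        assert fit.peaks == []

    def test_injected_6hz_peak_recovered(self):
        spec = self._forward(1.0, 1.5, peaks=[(6.0, 0.3, 1.0)])
        fit = fit_spectral_model(self.FREQS, spec)
        assert fit.band_peak_power(4, 8) == pytest.approx(0.3, abs=0.05)
        assert fit.exponent == pytest.approx(1.5, abs=0.05)

    def test_flat_spectrum_zero_exponent(self):
        fit = fit_spectral_model(self.FREQS, np.full_like(self.FREQS, 3.7))
        assert fit.exponent == pytest.approx(0.0, abs=0.05)

    def test_scale_equivariance(self):
        spec = self._forward(0.5, 1.2, peaks=[(6.0, 0.4, 1.2)])
        f1 = fit_spectral_model(self.FREQS, spec)
        f2 = fit_spectral_model(self.FREQS, 100.0 * spec)
        assert f2.offset - f1.offset == pytest.approx(2.0, abs=1e-6)
        assert f2.exponent == pytest.approx(f1.exponent, abs=1e-6)
        assert f2.peaks[0][0] == pytest.approx(f1.peaks[0][0], abs=1e-6)

    def test_nonpositive_power_rejected(self):
        spec = self._forward(1.0, 1.0)
        spec[10] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_spectral_model(self.FREQS, spec)
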