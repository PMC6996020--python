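import numpy as np
import pytest
from scipy import signal as sps

import tmazephys as tp
from tmazephys import spectral

FS = 512.0


class TestMorletTfr:
    def test_pure_tone_ridge_constant_over_time(self, tone):
        freqs, power = tp.morlet_tfr(tone(9.0, 12.0), FS)
        ridge = power[np.argmax(power.mean(axis=1))]
        interior = ridge[int(FS):-int(FS)]
        assert np.ptp(interior) / interior.mean() < 0.01
        assert freqs[np.argmax(power.mean(axis=1))] == pytest.approx(9.0, abs=0.5)

    def test_trim_removes_one_second_each_side(self, tone):
        x = tone(9.0, 12.0)
        _, power = tp.morlet_tfr(x, FS)
        assert power.shape[1] == x.size - 2 * int(FS)

    def test_two_tones_no_cross_terms(self, tone):
        """Ridges at 9 and 80 Hz; elsewhere > 20 dB below the weaker ridge."""
        x = tone(9.0, 20.0) + tone(80.0, 20.0)
        freqs, power = tp.morlet_tfr(x, FS)
        spec = power.mean(axis=1)
        ridge9 = spec[np.abs(freqs - 9).argmin()]
        ridge80 = spec[np.abs(freqs - 80).argmin()]
        # between the ridges, away from both mainlobes
        mid = spec[(freqs > 25) & (freqs < 55)]
        assert mid.max() < 10 ** (-20 / 10) * min(ridge9, ridge80)

    def test_amplitude_step_transition_width(self, tone):
        """Ridge power settles within ~5 cycles of the target frequency."""
        x = tone(9.0, 20.0)
        n = x.size
        x[: n // 2] *= 0.2
        freqs, power = tp.morlet_tfr(x, FS)
        ridge = power[np.abs(freqs - 9).argmin()]
        t = np.arange(ridge.size) / FS
        t_step = (n // 2) / FS - 1.0  # step time in trimmed coordinates
        settle = 5 / 9.0
        lo = ridge[t < t_step - settle].mean()
        hi = ridge[t > t_step + settle].mean()
        assert hi / lo == pytest.approx(1 / 0.2 ** 2, rel=0.05)
        # the transition takes no longer than ~2 settle widths
        mid = ridge[(t > t_step - settle / 4) & (t < t_step + settle / 4)]
        assert lo < mid.mean() < hi

    def test_too_short_epoch_rejected(self, tone):
        with pytest.raises(ValueError):
            tp.morlet_tfr(tone(9.0, 1.5), FS)


class TestNormalizedSpectrum:
    def test_integral_is_one(self, tone):
        freqs, power = tp.morlet_tfr(tone(9.0, 12.0), FS)
        spec = tp.normalized_spectrum(power, freqs)
        df = np.median(np.diff(freqs))
        assert spec.power.sum() * df == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, tone):
        x = tone(9.0, 12.0) + 0.1 * tone(40.0, 12.0)
        freqs, p1 = tp.morlet_tfr(x, FS)
        _, p2 = tp.morlet_tfr(3.7 * x, FS)
        s1 = tp.normalized_spectrum(p1, freqs)
        s2 = tp.normalized_spectrum(p2, freqs)
        assert np.allclose(s1.power, s2.power, rtol=1e-10)

    def test_white_noise_approximately_flat(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(int(60 * FS))
        freqs, power = tp.morlet_tfr(x, FS)
        spec = tp.normalized_spectrum(power, freqs)
        sel = (freqs >= 20) & (freqs <= 120)
        assert spec.power[sel].max() / spec.power[sel].min() < 1.5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tp.normalized_spectrum(np.zeros((5, 100)), np.arange(1, 6.0))


class TestThetaSummary:
    def test_pure_tone_peak(self, tone):
        freqs, power = tp.morlet_tfr(tone(9.0, 30.0), FS)
        ts = tp.theta_summary(tp.normalized_spectrum(power, freqs))
        assert ts.peak_frequency == pytest.approx(9.0, abs=0.05)

    @pytest.mark.parametrize("f0", [6.5, 7.3, 8.63, 9.02, 10.1, 11.5])
    def test_peak_unbiased_across_band(self, tone, f0):
        freqs, power = tp.morlet_tfr(tone(f0, 30.0), FS)
        ts = tp.theta_summary(tp.normalized_spectrum(power, freqs))
        assert ts.peak_frequency == pytest.approx(f0, abs=0.05)

    def test_tie_breaks_to_lowest_frequency(self):
        freqs = np.arange(1, 160.5, 0.5)
        p = np.zeros_like(freqs)
        p[freqs == 7.0] = 1.0
        p[freqs == 11.0] = 1.0
        spec = spectral.PowerSpectrum(freqs, p / (p.sum() * 0.5))
        ts = tp.theta_summary(spec, tilt_correction=False)
        assert ts.peak_frequency == 7.0

    def test_coarse_grid_rejected(self):
        freqs = np.arange(1.0, 160.0, 2.0)
        with pytest.raises(ValueError):
            tp.theta_summary(spectral.PowerSpectrum(freqs, np.ones_like(freqs)))


class TestBandpassZeroPhase:
    def test_passband_tone_preserved(self, tone):
        x = tone(9.0, 10.0)
        y = tp.bandpass_zero_phase(x, (6, 12), FS)
        core = slice(int(2 * FS), int(8 * FS))
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.01)
        # zero phase: cross-correlation peaks at lag 0
        xc = np.correlate(x[core], y[core], mode="full")
        assert np.argmax(xc) == len(x[core]) - 1

    def test_stopband_tone_attenuated(self, tone):
        y = tp.bandpass_zero_phase(tone(40.0, 10.0), (6, 12), FS)
        core = slice(int(2 * FS), int(8 * FS))
        assert 20 * np.log10(np.abs(y[core]).max()) < -40

    def test_impulse_response_symmetric(self):
        x = np.zeros(4000)
        x[2000] = 1.0
        y = tp.bandpass_zero_phase(x, (6, 12), FS)
        assert np.allclose(y[1:], y[:0:-1][: len(y) - 1], atol=1e-12)

    def test_bad_band_rejected(self, tone):
        with pytest.raises(ValueError):
            tp.bandpass_zero_phase(tone(9, 10), (6, 300), FS)


class TestAnalyticFeatures:
    def test_tone_amplitude_and_frequency(self, tone):
        amp, phase, freq, rel = tp.analytic_features(tone(9.0, 10.0), FS)
        core = slice(int(FS), -int(FS))
        assert np.allclose(amp[core], 1.0, atol=0.01)
        assert np.abs(freq[core] - 9.0).max() < 0.02
        assert rel[core].all()

    def test_phase_zero_at_peaks(self, tone):
        x = tone(9.0, 10.0)
        _, phase, _, _ = tp.analytic_features(x, FS)
        peaks = sps.find_peaks(x)[0]
        peaks = peaks[(peaks > FS) & (peaks < x.size - FS)]
        # sampled peak may sit half a sample off the true peak: allow 2*pi*f/(2*fs)
        assert np.abs(phase[peaks]).max() < 2 * np.pi * 9.0 / FS

    def test_chirp_frequency_tracked(self):
        t = np.arange(int(10 * FS)) / FS
        x = sps.chirp(t, f0=7.0, t1=10.0, f1=11.0, method="linear")
        _, _, freq, _ = tp.analytic_features(x, FS)
        expect = 7.0 + (11.0 - 7.0) * t / 10.0
        core = slice(int(FS), -int(FS))
        assert np.abs(freq[core] - expect[core]).max() < 0.1

    def test_envelope_does_not_perturb_phase(self, tone):
        t = np.arange(int(10 * FS)) / FS
        env = 1.0 + 0.5 * np.cos(2 * np.pi * 0.5 * t)
        x = tone(9.0, 10.0)
        _, p_plain, _, _ = tp.analytic_features(x, FS)
        _, p_mod, _, _ = tp.analytic_features(env * x, FS)
        core = slice(int(FS), -int(FS))
        dphi = np.angle(np.exp(1j * (p_mod[core] - p_plain[core])))
        assert np.abs(dphi).max() < 0.02


class TestSpeedFrequencyFit:
    def test_generator_truth_recovered(self):
        cfg = tp.CohortConfig(theta_intercept=9.0, theta_slope=0.02,
                              noise_amp=20.0)
        dur = 300.0
        n_tr = int(dur * 25) + 1
        tt = np.arange(n_tr) / 25.0
        # running speed varies over seconds, well within the FM tracking band
        v = 12.0 + 8.0 * np.sin(2 * np.pi * 0.05 * tt)
        import pandas as pd
        trace = pd.DataFrame({"time_s": tt, "speed_cm_s": v})
        lfp, _ = tp.generate_lfp_pair(cfg, trace, dur, seed=8)
        xf = tp.trim_edges(tp.bandpass_zero_phase(lfp["hpc"], (6, 12), FS), FS)
        _, _, inst_f, _ = tp.analytic_features(xf, FS)
        t = (np.arange(int(dur * FS)) / FS)[int(FS):-int(FS)]
        speed = np.interp(t, trace["time_s"], trace["speed_cm_s"])
        fit = tp.speed_frequency_fit(inst_f, speed, speed >= 2.0)
        assert fit.slope == pytest.approx(0.02, abs=0.005)
        assert fit.intercept == pytest.approx(9.0, abs=0.05)

    def test_constant_frequency_zero_slope(self, tone):
        x = tone(9.0, 30.0)
        _, _, inst_f, _ = tp.analytic_features(x, FS)
        rng = np.random.default_rng(0)
        speed = rng.uniform(3, 20, inst_f.size)
        fit = tp.speed_frequency_fit(inst_f[512:-512], speed[512:-512],
                                     np.ones(inst_f.size - 1024, bool))
        assert abs(fit.slope) < 1e-3

    def test_all_immobile_rejected(self):
        with pytest.raises(ValueError):
            tp.speed_frequency_fit(np.ones(1000), np.ones(1000),
                                   np.zeros(1000, bool))

    def test_degenerate_speed_rejected(self):
        with pytest.raises(ValueError):
            tp.speed_frequency_fit(np.ones(1000), np.full(1000, 5.0),
                                   np.ones(1000, bool))


class TestOracleEquivalence:
    def test_band_power_matches_welch_on_stationary_signal(self):
        """Wavelet and Welch band powers agree within 10% (relative shares)."""
        rng = np.random.default_rng(3)
        x = (np.sin(2 * np.pi * 9 * np.arange(int(40 * FS)) / FS)
             + 0.5 * rng.standard_normal(int(40 * FS)))
        freqs, power = tp.morlet_tfr(x, FS)
        spec = tp.normalized_spectrum(power, freqs)
        f_w, p_w = sps.welch(x, fs=FS, nperseg=int(4 * FS))

        def share(f, p, band):
            sel_b = (f >= band[0]) & (f <= band[1])
            sel_t = (f >= 1) & (f <= 160)
            return np.trapezoid(p[sel_b], f[sel_b]) / np.trapezoid(p[sel_t], f[sel_t])

        for band in ((6, 12), (20, 60)):
            assert (share(freqs, spec.power, band)
                    == pytest.approx(share(f_w, p_w, band), rel=0.10))
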