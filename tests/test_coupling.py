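import numpy as np
import pytest

import tmazephys as tp
from tmazephys import coupling

FS = 512.0


class TestVectorLength:
    def test_independent_amplitude_near_zero(self):
        cfg = tp.CohortConfig(pac_depth_lg=0.0, pac_depth_hg=0.0,
                              theta_slope=0.0)
        lfp, _ = tp.generate_lfp_pair(cfg, tp.constant_speed(10, 200.0),
                                      200.0, seed=2)
        assert tp.pac_vector_length(lfp["hpc"], FS).vector_length < 0.02

    @pytest.mark.parametrize("k", [0.2, 0.5, 0.8])
    def test_envelope_model_half_k(self, k):
        x = tp.generate_envelope_model(k, 200.0, seed=1)
        vl = tp.pac_vector_length(x, FS).vector_length
        assert vl == pytest.approx(k / 2, abs=0.02)

    def test_point_mass_resultant_is_one(self):
        centers = coupling._phase_bins(30)[1]
        amp = np.zeros(30)
        amp[7] = 5.0
        assert coupling.vector_length_from_bins(centers, amp) == pytest.approx(1.0)

    def test_invariant_to_amplitude_scaling(self):
        x = tp.generate_envelope_model(0.5, 60.0, seed=4)
        a = tp.pac_vector_length(x, FS).vector_length
        b = tp.pac_vector_length(7.3 * x, FS).vector_length
        assert a == pytest.approx(b, abs=1e-12)

    def test_invariant_to_bin_rotation(self):
        """Rotating the amplitude distribution leaves the resultant length."""
        centers = coupling._phase_bins(30)[1]
        amp = 1.0 + 0.5 * np.cos(centers)
        a = coupling.vector_length_from_bins(centers, amp)
        b = coupling.vector_length_from_bins(centers, np.roll(amp, 7))
        assert a == pytest.approx(b, abs=1e-12)

    def test_too_short_signal_rejected(self, tone):
        with pytest.raises(ValueError):
            tp.pac_vector_length(tone(9.0, 1.0), FS)


class TestComodulogram:
    def test_coupled_generator_peaks_in_theta_lg_block(self):
        cfg = tp.CohortConfig(pac_depth_lg=0.6, pac_depth_hg=0.0,
                              theta_intercept=9.0, theta_slope=0.0)
        lfp, _ = tp.generate_lfp_pair(cfg, tp.constant_speed(10, 60.0), 60.0,
                                      seed=6)
        c = tp.comodulogram(lfp["hpc"], FS)
        i, j = np.unravel_index(np.argmax(c.coherence), c.coherence.shape)
        assert 6 <= c.phase_freqs[i] <= 12
        assert 60 <= c.amp_freqs[j] <= 120

    def test_two_blocks_in_hpc_none_in_mpfc(self):
        cfg = tp.CohortConfig(pac_depth_lg=0.6, pac_depth_hg=0.6,
                              theta_intercept=9.0, theta_slope=0.0)
        lfp, _ = tp.generate_lfp_pair(cfg, tp.constant_speed(10, 60.0), 60.0,
                                      seed=6)

        def block_mean(c, pband, aband):
            pi = (c.phase_freqs >= pband[0]) & (c.phase_freqs <= pband[1])
            ai = (c.amp_freqs >= aband[0]) & (c.amp_freqs <= aband[1])
            return c.coherence[np.ix_(pi, ai)].mean()

        def outside_mean(c):
            pi = (c.phase_freqs >= 20) & (c.phase_freqs <= 40)
            return c.coherence[pi].mean()

        ch = tp.comodulogram(lfp["hpc"], FS)
        cm = tp.comodulogram(lfp["mpfc"], FS)
        for band in ((60, 120), (140, 160)):
            assert block_mean(ch, (6, 12), band) > 3 * outside_mean(ch)
            assert block_mean(cm, (6, 12), band) < 2 * outside_mean(cm)

    def test_white_noise_below_surrogate_null(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(60 * FS))
        obs, p = tp.pac_surrogate_test(x, FS, rng=np.random.default_rng(4))
        assert p > 0.05

    def test_surrogate_detects_coupling_with_wandering_theta(self):
        """Coupling is detected once theta phase wanders as in real LFP
        (a perfectly stationary tone is equally coherent with its own
        surrogates, so frequency modulation is what carries the test)."""
        import pandas as pd
        hits = 0
        for i in range(5):
            tt = np.arange(int(30 * 25) + 1) / 25.0
            v = 12 + 8 * np.sin(2 * np.pi * 0.11 * tt + i)
            trace = pd.DataFrame({"time_s": tt, "speed_cm_s": v})
            cfg = tp.CohortConfig(theta_slope=0.1, pac_depth_lg=0.4,
                                  pac_depth_hg=0.0)
            lfp, _ = tp.generate_lfp_pair(cfg, trace, 30.0, seed=i)
            _, p = tp.pac_surrogate_test(lfp["hpc"], FS,
                                         rng=np.random.default_rng(i))
            hits += p <= 0.05
        assert hits >= 4

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            tp.comodulogram(np.zeros(int(5 * FS)), FS)

    def test_cells_bounded(self):
        rng = np.random.default_rng(5)
        c = tp.comodulogram(rng.standard_normal(int(15 * FS)), FS)
        assert (c.coherence >= 0).all() and (c.coherence <= 1).all()


class TestPeakAlignedPac:
    def test_frequency_shift_confound_removed(self):
        """Same depth, different theta: a fixed narrow phase band differs
        between animals (one theta falls outside it and noise corrupts the
        phase), while peak-aligned bands recover equal coupling."""
        vls_fixed, vls_aligned = [], []
        for f0, seed in ((7.0, 1), (10.5, 2)):
            cfg = tp.CohortConfig(theta_intercept=f0, theta_slope=0.0,
                                  pac_depth_lg=0.5, pac_depth_hg=0.0)
            lfp, _ = tp.generate_lfp_pair(cfg, tp.constant_speed(10, 120.0),
                                          120.0, seed=seed)
            vls_fixed.append(tp.pac_vector_length(
                lfp["hpc"], FS, phase_band=(9.5, 12.5)).vector_length)
            vls_aligned.append(tp.pac_peak_aligned(
                lfp["hpc"], FS, peak_frequency=f0,
                amp_band=(60, 120)).vector_length)
        assert abs(vls_fixed[0] - vls_fixed[1]) > 0.05
        assert abs(vls_aligned[0] - vls_aligned[1]) < 0.02

    def test_depth_difference_preserved_when_frequency_equal(self):
        a = tp.generate_envelope_model(0.6, 120.0, theta_freq=9.0, seed=3)
        b = tp.generate_envelope_model(0.3, 120.0, theta_freq=9.0, seed=4)
        res = tp.residualize_pac_theta_peak([a, b], FS, [9.0, 9.0])
        assert res[0].vector_length - res[1].vector_length == pytest.approx(
            0.15, abs=0.03)

    def test_peak_too_near_band_edge_rejected(self):
        x = tp.generate_envelope_model(0.5, 20.0, seed=5)
        with pytest.raises(ValueError):
            tp.pac_peak_aligned(x, FS, peak_frequency=6.5, amp_band=(60, 120))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            tp.residualize_pac_theta_peak([np.zeros(100)], FS, [9.0, 10.0])
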