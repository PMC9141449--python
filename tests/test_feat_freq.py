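"""Frequency-domain features: PSD, power law, band power, bispectrum,
coherence and asymmetry."""

import numpy as np
import pytest

from emosda import feat_freq, montage, synthio

T = np.arange(3840) / 128.0


def _trial(signal40):
    return synthio.TrialRecording(1, 1, signal40)


class TestWelchPSD:
    def test_tone_peak_location(self):
        psd = feat_freq.welch_psd(np.sin(2 * np.pi * 10 * T))
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(10.0, abs=0.2)

    def test_parseval_white_noise(self):
        """Integral of the density matches the signal power within 5%."""
        devs = []
        for s in range(5):
            x = np.random.default_rng(s).normal(size=3840)
            psd = feat_freq.welch_psd(x)
            df = psd.freqs[1] - psd.freqs[0]
            devs.append(np.sum(psd.power) * df / np.mean(x ** 2))
        assert np.mean(devs) == pytest.approx(1.0, abs=0.05)

    def test_segment_count(self):
        # floor((3840 - 853) / 427) + 1 = 7 averaged segments
        assert (3840 - feat_freq.NFFT) // (feat_freq.NFFT - feat_freq.NOVERLAP) + 1 == 7

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            feat_freq.welch_psd(np.zeros(500))

    def test_time_reversal_invariance(self, rng):
        """With the segment grid tiling the signal exactly (853 + 6*427
        samples), reversal permutes and reverses the segments; up to the
        one-sample asymmetry of the periodic Hamming taper the averaged
        periodograms agree."""
        x = rng.normal(size=853 + 6 * 427)
        a = feat_freq.welch_psd(x)
        b = feat_freq.welch_psd(x[::-1].copy())
        assert np.allclose(a.power, b.power, rtol=0.02)


class TestPowerLaw:
    def test_white_noise_eta_near_zero(self):
        etas = [feat_freq.power_law_index(
            feat_freq.welch_psd(np.random.default_rng(s).normal(size=3840))).eta
            for s in range(5)]
        assert abs(np.mean(etas)) < 0.15

    def test_one_over_f_signal(self):
        """Spectrally shaped noise with P(f) ~ 1/f has eta near 1."""
        etas = []
        for s in range(3):
            rng = np.random.default_rng(s)
            n = 3840
            freqs = np.fft.rfftfreq(n, 1 / 128.0)
            spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
            shape = np.zeros_like(freqs)
            shape[1:] = freqs[1:] ** -0.5
            x = np.fft.irfft(spec * shape, n)
            etas.append(feat_freq.power_law_index(feat_freq.welch_psd(x)).eta)
        assert np.mean(etas) == pytest.approx(1.0, abs=0.2)

    def test_scaling_invariance_exact(self, rng):
        x = rng.normal(size=3840)
        e1 = feat_freq.power_law_index(feat_freq.welch_psd(x)).eta
        e2 = feat_freq.power_law_index(feat_freq.welch_psd(5.0 * x)).eta
        assert e1 == pytest.approx(e2, abs=1e-12)


class TestBandPower:
    def test_alpha_tone_dominates(self):
        bp = feat_freq.band_power_features(np.sin(2 * np.pi * 10 * T))
        assert bp.log_avg_power["alpha"] > max(
            bp.log_avg_power[b] for b in ("theta", "beta", "gamma"))

    def test_equal_tones_beta_alpha_ratio(self):
        x = np.sin(2 * np.pi * 10 * T) + np.sin(2 * np.pi * 20 * T)
        assert feat_freq.band_power_features(x).ratio_beta_alpha == \
            pytest.approx(1.0, abs=0.2)

    def test_frame_count_and_ordering(self, rng):
        x = rng.normal(size=3840)
        assert feat_freq._stft_band_powers(x, 128.0).shape == (30, 4)
        bp = feat_freq.band_power_features(x)
        for b in montage.BAND_ORDER:
            assert bp.log_max_power[b] >= bp.log_avg_power[b] >= bp.log_min_power[b]

    def test_vector_has_14_values(self, rng):
        vals, names = feat_freq.band_power_features(rng.normal(size=3840)).as_vector()
        assert len(vals) == len(names) == 14


class TestBispectrum:
    def test_symmetry(self, rng):
        b = feat_freq.bispectrum_estimate(rng.normal(size=3840))
        mag = np.abs(b.B)
        assert np.max(np.abs(mag - mag.T)) / np.max(mag) < 1e-8

    def test_sign_flip_preserves_magnitude(self, rng):
        x = rng.normal(size=3840)
        b1 = feat_freq.bispectrum_estimate(x)
        b2 = feat_freq.bispectrum_estimate(-x)
        assert np.allclose(np.abs(b1.B), np.abs(b2.B), atol=1e-10)

    def test_quadratic_phase_coupling_peak(self):
        """Tones at f1, f2 and f1+f2 with coupled phases put the maximal
        bispectral magnitude at the bin pair nearest {f1, f2}."""
        rng = np.random.default_rng(1)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        x = (np.cos(2 * np.pi * 12 * T + p1) + np.cos(2 * np.pi * 20 * T + p2)
             + np.cos(2 * np.pi * 32 * T + p1 + p2) + 0.1 * rng.normal(size=3840))
        b = feat_freq.bispectrum_estimate(x)
        mag = np.where(b.principal_region, np.abs(b.B), 0.0)
        i, j = np.unravel_index(np.argmax(mag), mag.shape)
        assert sorted([b.freqs[i], b.freqs[j]]) == pytest.approx([12.0, 20.0], abs=1.0)

    def test_noise_magnitude_much_smaller_than_coupled(self):
        rng = np.random.default_rng(1)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        coupled = (np.cos(2 * np.pi * 12 * T + p1) + np.cos(2 * np.pi * 20 * T + p2)
                   + np.cos(2 * np.pi * 32 * T + p1 + p2))
        noise = 0.5 * rng.normal(size=3840)
        bc = feat_freq.bispectrum_estimate(coupled)
        bn = feat_freq.bispectrum_estimate(noise)
        mc = np.abs(bc.B)[bc.principal_region].mean()
        mn = np.abs(bn.B)[bn.principal_region].mean()
        assert mc > 10 * mn

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            feat_freq.bispectrum_estimate(np.zeros(1000))


class TestBispectralSummaries:
    def _estimate(self, mag, omega):
        b = feat_freq.BispectrumEstimate(B=mag.astype(complex),
                                         freqs=np.zeros(mag.shape[0]),
                                         principal_region=omega)
        return feat_freq.bispectral_summaries(b)

    def test_uniform_magnitude_maximum_entropy(self):
        omega = np.zeros((8, 8), dtype=bool)
        omega[:3, :3] = True          # L = 9 points
        mag = np.where(omega, 2.0, 0.0)
        s = self._estimate(mag, omega)
        assert s.be1 == pytest.approx(np.log(9))
        assert s.be2 == pytest.approx(np.log(9))
        assert s.mmob == pytest.approx(2.0)

    def test_point_mass_zero_entropy(self):
        omega = np.zeros((8, 8), dtype=bool)
        omega[:3, :3] = True
        mag = np.zeros((8, 8))
        mag[1, 1] = 5.0
        s = self._estimate(mag, omega)
        assert s.be1 == 0.0 and s.be2 == 0.0

    def test_matches_direct_transcription(self, rng):
        omega = np.zeros((16, 16), dtype=bool)
        omega[2:9, 2:9] = True
        mag = np.abs(rng.normal(size=(16, 16))) + 0.1
        s = self._estimate(mag, omega)
        m = mag[omega]
        pn = m / m.sum()
        qn = m ** 2 / (m ** 2).sum()
        assert s.be1 == pytest.approx(-np.sum(pn * np.log(pn)))
        assert s.be2 == pytest.approx(-np.sum(qn * np.log(qn)))
        assert s.mmob == pytest.approx(m.mean())
        assert s.fosm == pytest.approx(np.sum(np.log(mag)))

    def test_all_zero_rejected(self):
        omega = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            self._estimate(np.zeros((4, 4)), omega)


class TestCoherence:
    def test_identical_channels_full_coherence(self, rng):
        sig = np.tile(rng.normal(size=3840), (40, 1))
        coh = feat_freq.msce_features(_trial(sig), [(0, 1)])
        assert np.allclose(coh.coherence, 1.0, atol=1e-6)

    def test_bounded_and_symmetric(self, rng):
        sig = rng.normal(size=(40, 3840))
        a = feat_freq.msce_features(_trial(sig), [(2, 3)])
        b = feat_freq.msce_features(_trial(sig), [(3, 2)])
        assert (a.coherence >= 0).all() and (a.coherence <= 1).all()
        assert np.allclose(a.coherence, b.coherence)

    def test_independent_noise_low_band_coherence(self, rng):
        sig = rng.normal(size=(40, 3840))
        coh = feat_freq.msce_features(_trial(sig))
        assert coh.band_coherence.shape == (14, 4)
        assert coh.band_coherence.max() < 0.5

    def test_identical_indices_rejected(self, rng):
        sig = rng.normal(size=(40, 3840))
        with pytest.raises(ValueError):
            feat_freq.msce_features(_trial(sig), [(4, 4)])


class TestAsymmetry:
    def test_symmetric_input(self, rng):
        sig = np.zeros((40, 3840))
        sig[:32] = rng.normal(size=3840)
        asym = feat_freq.asymmetry_features(_trial(sig))
        assert asym.dasm.shape == (14, 4) and asym.rasm.shape == (14, 4)
        assert np.allclose(asym.dasm, 0.0)
        assert np.allclose(asym.rasm, 1.0)

    def test_amplitude_ratio_squares_to_power(self, rng):
        base = rng.normal(size=3840)
        sig = np.tile(base, (40, 1))
        pairs = montage.symmetric_pair_indices()
        l, r = pairs[0]
        sig[l] = np.sqrt(2.0) * base
        asym = feat_freq.asymmetry_features(_trial(sig), [(l, r)])
        assert np.allclose(asym.rasm[0], 2.0, rtol=0.05)

    def test_56_values_from_14_pairs(self):
        assert len(montage.symmetric_pair_indices()) * 4 == 56
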