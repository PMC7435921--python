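import numpy as np
import pytest

import vfegm as v
from conftest import uniform_spectrum
from oracles import direct_welch_unit_area

MAINLOBE = 200 / 256  # Hz


class TestWelch:
    def test_matches_direct_dft_oracle(self, default_pair):
        rec = v.segment_window(default_pair, "W1").lv
        spec = v.welch_psd(rec)
        freqs, pn = direct_welch_unit_area(rec.samples, rec.fs)
        np.testing.assert_allclose(spec.freqs, freqs)
        assert np.max(np.abs(spec.pn - pn)) / np.max(pn) < 1e-9

    def test_unit_area_normalization(self, default_pair):
        spec = v.welch_psd(default_pair.rv)
        assert abs(spec.pn.sum() * spec.resolution - 1.0) < 1e-9

    def test_short_input_rejected(self):
        rec = v.EGMRecording("P01", "LV", np.random.default_rng(0).standard_normal(255))
        with pytest.raises(v.ValidationError, match="256"):
            v.welch_psd(rec)

    def test_sinusoid_peak_within_mainlobe(self, sinusoid_pair):
        spec = v.welch_psd(sinusoid_pair.lv)
        assert abs(spec.freqs[np.argmax(spec.pn)] - 5.0) < MAINLOBE


class TestHarmonicDetection:
    def test_noiseless_ladder_recovered(self, harmonic_pair):
        spec = v.welch_psd(v.segment_window(harmonic_pair, "W1").lv)
        harm = v.detect_harmonics(spec)
        assert abs(harm.f0 - 4.74) < MAINLOBE
        targets = 4.74 * np.arange(1, harm.freqs.size + 1)
        assert np.all(np.abs(harm.freqs - targets) < MAINLOBE)

    def test_pure_tone_fundamental_equals_dominant(self, sinusoid_pair):
        spec = v.welch_psd(sinusoid_pair.lv)
        harm = v.detect_harmonics(spec)
        assert harm.f0 == v.dominant_frequency(spec)
        # higher harmonic slots fall back to the noise floor
        assert np.all(harm.powers[1:] < 0.01 * harm.powers[0])

    def test_flat_spectrum_has_no_harmonic_structure(self):
        with pytest.raises(v.NoHarmonicStructureError):
            v.detect_harmonics(uniform_spectrum())


class TestScalarParameters:
    def test_dominant_frequency_tracks_envelope_peak(self):
        cfg = v.VFSignalConfig(
            f0=4.74, envelope_lv=(0.2, 0.2, 0.2, 0.2, 1.0), envelope_rv=(1.0,),
            jitter_sd=0.0, noise_sd_lv=0.0, noise_sd_rv=0.0, seed=3,
        )
        spec = v.welch_psd(v.segment_window(v.generate_vf_pair(cfg), "W1").lv)
        assert abs(v.dominant_frequency(spec) - 5 * 4.74) < MAINLOBE

    def test_mean_frequency_of_symmetric_two_peak_spectrum(self):
        base = uniform_spectrum()
        pn = base.pn * 1e-6
        for f in (10.0, 20.0):
            pn[np.argmin(np.abs(base.freqs - f))] = 1.0
        pn /= pn.sum() * base.resolution
        spec = v.SpectrumEstimate(base.freqs, pn, base.resolution, base.mainlobe)
        # tolerance covers grid quantization of the two peak positions
        assert abs(v.mean_frequency(spec) - 15.0) < 0.05

    def test_mean_frequency_of_uniform_density_is_band_midpoint(self):
        assert abs(v.mean_frequency(uniform_spectrum()) - 16.0) < 0.05

    def test_mean_frequency_of_sinusoid(self, sinusoid_pair):
        spec = v.welch_psd(sinusoid_pair.lv)
        assert abs(v.mean_frequency(spec) - 5.0) < 0.5


class TestBandwidth:
    def test_sinusoid_peak_narrower_than_mainlobe_scale(self, sinusoid_pair):
        spec = v.welch_psd(sinusoid_pair.lv)
        bw = v.bandwidth_75(spec, v.dominant_frequency(spec))
        assert 0 < bw.width < 1.5
        assert not bw.one_sided

    def test_constructed_plateau_width(self):
        base = uniform_spectrum()
        pn = base.pn.copy() * 0.1
        mask = (base.freqs >= 10.0) & (base.freqs <= 12.0)
        pn[mask] = 1.0
        pn /= pn.sum() * base.resolution
        spec = v.SpectrumEstimate(base.freqs, pn, base.resolution, base.mainlobe)
        bw = v.bandwidth_75(spec, 11.0)
        assert abs(bw.width - 2.0) < 2 * base.resolution

    def test_edge_peak_flagged_one_sided(self):
        base = uniform_spectrum()
        pn = base.pn.copy() * 0.1
        pn[0] = 1.0  # monotone drop from the DC edge
        pn /= pn.sum() * base.resolution
        spec = v.SpectrumEstimate(base.freqs, pn, base.resolution, base.mainlobe)
        assert v.bandwidth_75(spec, 0.0).one_sided


class TestOrganizationIndex:
    def test_white_noise_single_band_is_band_length_ratio(self):
        spec = uniform_spectrum()
        oi = v.organization_index(spec, np.array([10.0]), half_width=0.5)
        assert abs(oi - 1.0 / 28.0) < 0.005

    def test_noiseless_harmonic_signal_is_highly_organized(self, harmonic_pair):
        spec = v.welch_psd(v.segment_window(harmonic_pair, "W1").lv)
        harm = v.detect_harmonics(spec)
        assert v.organization_index(spec, harm.freqs) > 0.9

    def test_overlapping_bands_merged_not_double_counted(self):
        spec = uniform_spectrum()
        one = v.organization_index(spec, np.array([10.0]), half_width=0.5)
        doubled = v.organization_index(spec, np.array([10.0, 10.2]), half_width=0.5)
        assert doubled < 2 * one

    def test_out_of_band_harmonics_dropped(self):
        spec = uniform_spectrum()
        with pytest.raises(v.ValidationError):
            v.organization_index(spec, np.array([40.0]))

    def test_rv_preset_more_organized_than_lv_preset(self):
        wins = 0
        for seed in range(10):
            pair = v.generate_vf_pair(v.VFSignalConfig(seed=seed))
            lv, rv = v.extract_spectral_params(pair, "W1")
            wins += rv.oi > lv.oi
        assert wins >= 8


class TestLeakage:
    def test_exact_sinusoid_with_phase_offset(self):
        t = np.arange(600) / 200.0
        rec = v.EGMRecording("P01", "LV", np.sin(2 * np.pi * 5.0 * t + 1.3))
        assert v.leakage(rec, 5.0) > 1.0 - 1e-6

    def test_equal_power_noise_attenuates_to_inverse_sqrt2(self):
        # corr = sqrt(SNR / (1 + SNR)) with SNR = 1
        t = np.arange(6000) / 200.0
        rng = np.random.default_rng(0)
        signal = np.sqrt(2.0) * np.sin(2 * np.pi * 5.0 * t)  # power 1
        rec = v.EGMRecording("P01", "LV", signal + rng.standard_normal(t.size))
        assert abs(v.leakage(rec, 5.0) - 1 / np.sqrt(2)) < 0.05

    def test_constant_signal_rejected(self):
        rec = v.EGMRecording("P01", "LV", np.ones(600))
        with pytest.raises(v.DegenerateSignalError):
            v.leakage(rec, 5.0)


class TestInvariancesAndComposition:
    def test_amplitude_scaling_leaves_oi_and_lk_unchanged(self, default_pair):
        lv = v.segment_window(default_pair, "W1").lv
        scaled = v.EGMRecording(lv.patient_id, "LV", 7.3 * lv.samples, lv.fs)
        for rec_a, rec_b in [(lv, scaled)]:
            sa, sb = v.welch_psd(rec_a), v.welch_psd(rec_b)
            ha, hb = v.detect_harmonics(sa), v.detect_harmonics(sb)
            assert abs(
                v.organization_index(sa, ha.freqs) - v.organization_index(sb, hb.freqs)
            ) < 1e-9
            assert abs(v.leakage(rec_a, ha.f0) - v.leakage(rec_b, hb.f0)) < 1e-9

    def test_dominant_at_least_fundamental_minus_resolution(self):
        for seed in range(5):
            pair = v.generate_vf_pair(v.VFSignalConfig(seed=seed))
            spec = v.welch_psd(v.segment_window(pair, "W1").lv)
            harm = v.detect_harmonics(spec)
            assert v.dominant_frequency(spec) >= harm.f0 - spec.resolution

    def test_noise_never_increases_median_organization(self):
        medians_oi, medians_lk = [], []
        for sd in (0.0, 0.5, 1.5):
            oi, lk = [], []
            for seed in range(20):
                cfg = v.VFSignalConfig(
                    envelope_lv=(1.0, 0.6, 0.4), envelope_rv=(1.0, 0.6, 0.4),
                    jitter_sd=0.0, noise_sd_lv=sd, noise_sd_rv=sd, seed=seed,
                )
                lv, _ = v.extract_spectral_params(v.generate_vf_pair(cfg), "W1")
                oi.append(lv.oi)
                lk.append(lv.lk)
            medians_oi.append(np.median(oi))
            medians_lk.append(np.median(lk))
        assert medians_oi[0] >= medians_oi[1] >= medians_oi[2]
        assert medians_lk[0] >= medians_lk[1] >= medians_lk[2]

    def test_extract_on_pure_sinusoid_pair(self, sinusoid_pair):
        lv, rv = v.extract_spectral_params(sinusoid_pair, "W1")
        assert lv.f0 == lv.dominant_f
        assert lv.oi > 0.9
        assert lv.lk > 0.999
        assert rv.lk > 0.999

    def test_stationary_signal_windows_agree(self):
        pair = v.generate_vf_pair(v.VFSignalConfig(seed=21, jitter_sd=0.0))
        w1_lv, _ = v.extract_spectral_params(pair, "W1")
        w2_lv, _ = v.extract_spectral_params(pair, "W2")
        assert abs(w1_lv.f0 - w2_lv.f0) < MAINLOBE
        assert abs(w1_lv.oi - w2_lv.oi) < 0.15
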