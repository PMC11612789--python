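"""Acoustic parameter extraction: analytic limits and brute-force oracles."""

import numpy as np
import pytest

import shrewvoc as sv
from shrewvoc.features import (ALL_CALLS_PARAMS, FEATURE_COLUMNS, FrameTrack,
                               FeatureConfig, availability_mask,
                               classify_tonality, extract_feature_table,
                               f0_features, formant_features, spectral_shape,
                               time_features, tonality_features, track_pitch)

SR = 200_000


class TestPitchTracking:
    def test_pure_tone_fully_voiced_at_tone_frequency(self, tone):
        track = track_pitch(tone, SR)
        assert track.voiced_percentage == 100.0
        assert abs(np.nanmean(track.f0_hz) - 20_000) / 20_000 < 0.02

    def test_white_noise_nearly_unvoiced(self, white_noise):
        track = track_pitch(white_noise, SR)
        assert 100.0 * np.mean(track.voiced) < 5.0

    def test_screech_scream_voiced_fraction_near_half(self):
        spec = sv.preset("screech_scream")  # tonal_fraction 0.5
        x = sv.synth_screech_scream(spec, SR, 9)
        track = track_pitch(x, SR)
        assert abs(track.voiced_percentage - 50.0) <= 10.0

    def test_subwindow_segment_flagged_degenerate(self):
        track = track_pitch(np.ones(100), SR)
        assert track.degenerate


class TestTonality:
    def test_voiced_percentage_is_stated_ratio(self):
        n = 10
        voiced = np.array([True] * 8 + [False] * 2)
        f0 = np.where(voiced, 20e3, np.nan)
        track = FrameTrack(frame_times=np.arange(n) * 5e-4, f0_hz=f0,
                           voiced=voiced, strength=np.where(voiced, 0.9, 0.1),
                           frame_energy=np.ones(n))
        x = np.sin(2 * np.pi * 20e3 * np.arange(1000) / SR)
        ton = tonality_features(x, SR, track)
        assert ton.voiced_percentage == pytest.approx(80.0)

    def test_white_noise_flatness_near_unity(self, white_noise):
        track = track_pitch(white_noise, SR)
        ton = tonality_features(white_noise, SR, track)
        assert 0.85 <= ton.wiener_entropy_linear <= 1.0

    def test_pure_tone_periodic_limits(self, tone):
        track = track_pitch(tone, SR)
        ton = tonality_features(tone, SR, track)
        assert ton.wiener_entropy_db < -20.0
        assert ton.hnr_db > 20.0
        assert ton.hnr_linear == pytest.approx(10 ** (ton.hnr_db / 10))

    def test_zero_energy_segment_rejected(self):
        track = track_pitch(np.zeros(2000), SR)
        with pytest.raises(ValueError, match="zero-energy"):
            tonality_features(np.zeros(2000), SR, track)


class TestF0Features:
    def test_linear_chirp_contour_statistics(self):
        # 15 -> 25 kHz over 0.1 s: analytic contour oracle
        t = np.arange(int(0.1 * SR)) / SR
        f_inst = 15e3 + (25e3 - 15e3) * t / 0.1
        x = np.sin(2 * np.pi * np.cumsum(f_inst) / SR)
        track = track_pitch(x, SR)
        ff = f0_features(track, duration=0.1)
        assert ff.available
        assert ff.min_f0 == pytest.approx(15.0, rel=0.03)
        assert ff.max_f0 == pytest.approx(25.0, rel=0.03)
        assert ff.mean_f0 == pytest.approx(20.0, rel=0.03)
        assert ff.mean_abs_slope == pytest.approx(100.0, rel=0.05)
        assert ff.time_of_max_f0 > 0.09

    def test_constant_tone_zero_sd_and_slope(self):
        t = np.arange(int(0.1 * SR)) / SR
        x = np.sin(2 * np.pi * 24_000 * t)
        ff = f0_features(track_pitch(x, SR), duration=0.1)
        assert ff.sd_f0 < 0.05
        assert ff.mean_abs_slope < 5.0

    def test_single_voiced_frame_unavailable(self):
        track = FrameTrack(frame_times=np.array([0.0, 5e-4]),
                           f0_hz=np.array([20e3, np.nan]),
                           voiced=np.array([True, False]),
                           strength=np.array([0.9, 0.1]),
                           frame_energy=np.ones(2))
        assert not f0_features(track, duration=0.01).available


class TestSpectralShape:
    def test_pure_tone_concentrated_spectrum(self, tone):
        sm = spectral_shape(tone, SR)
        assert sm.cog == pytest.approx(20.0, abs=0.1)
        assert sm.spectral_sd < 0.5

    def test_flat_spectrum_uniform_moments(self, white_noise):
        # oracle: moments of the uniform distribution on [0, Nyquist]
        B = SR / 2 / 1000.0
        sm = spectral_shape(white_noise, SR)
        assert sm.cog == pytest.approx(B / 2, rel=0.03)
        assert sm.spectral_sd == pytest.approx(B / np.sqrt(12), rel=0.05)
        assert abs(sm.skewness) < 0.15

    def test_two_equal_tones_symmetric(self):
        t = np.arange(int(0.1 * SR)) / SR
        x = np.sin(2 * np.pi * 10e3 * t) + np.sin(2 * np.pi * 30e3 * t)
        sm = spectral_shape(x, SR)
        assert sm.cog == pytest.approx(20.0, abs=0.2)
        assert abs(sm.skewness) < 0.05

    def test_moments_match_bruteforce_oracle(self):
        """Direct weighted sums over the discrete spectrum, 1e-9 relative."""
        from scipy.signal import periodogram

        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.standard_normal(4096) * rng.uniform(0.1, 1.0)
            sm = spectral_shape(x, SR)
            freqs, psd = periodogram(x, fs=SR, window="hann")
            tot = sum(psd)
            cog = sum(f * p for f, p in zip(freqs, psd)) / tot
            var = sum((f - cog) ** 2 * p for f, p in zip(freqs, psd)) / tot
            sd = var ** 0.5
            skew = sum((f - cog) ** 3 * p for f, p in zip(freqs, psd)) / tot / sd**3
            kurt = sum((f - cog) ** 4 * p for f, p in zip(freqs, psd)) / tot / sd**4 - 3
            assert sm.cog == pytest.approx(cog / 1000, rel=1e-9)
            assert sm.spectral_sd == pytest.approx(sd / 1000, rel=1e-9)
            assert sm.skewness == pytest.approx(skew, rel=1e-9, abs=1e-12)
            assert sm.kurtosis == pytest.approx(kurt, rel=1e-9, abs=1e-12)


class TestFormants:
    def test_single_resonance_recovered_within_10pct(self):
        from scipy.signal import lfilter

        rng = np.random.default_rng(1)
        f_res, bw = 15_000.0, 800.0
        r = np.exp(-np.pi * bw / SR)
        a = [1.0, -2 * r * np.cos(2 * np.pi * f_res / SR), r * r]
        x = lfilter([1.0], a, rng.standard_normal(int(0.1 * SR)))
        fm = formant_features(x, SR, vtl_cm=1.2)
        assert fm.n_found >= 1
        assert abs(fm.f1 * 1000 - f_res) / f_res < 0.10

    def test_formants_below_ceiling_with_positive_bandwidths(self, white_noise):
        from shrewvoc.features import formant_ceiling_hz

        fm = formant_features(white_noise, SR, vtl_cm=1.2)
        ceiling = formant_ceiling_hz(1.2)
        for f, bw in [(fm.f1, fm.bw1), (fm.f2, fm.bw2), (fm.f3, fm.bw3)]:
            if np.isfinite(f):
                assert 0 < f * 1000 < ceiling
                assert bw > 0

    def test_tonal_call_has_formants_masked(self):
        x = sv.synth_tonal_call(sv.preset("scream"), SR, 0)
        feats = sv.extract_features(x, SR)
        assert feats["tonality_class"] == "tonal"
        assert np.isnan(feats["f1"]) and np.isnan(feats["bw3"])
        mask = availability_mask("tonal")
        assert not mask["f1"] and mask["mean_f0"]


class TestTimeFeatures:
    def test_duration_from_sample_count(self):
        tf = time_features(np.ones(32_000), SR)
        assert tf.duration == pytest.approx(0.16)

    def test_peak_at_first_sample(self):
        x = np.zeros(4000)
        x[0] = 1.0
        assert time_features(x, SR).time_peak_amplitude < 0.002

    def test_synthesized_peak_position_recovered(self):
        # triangular envelope peaking at 0.04 s on a 24 kHz carrier
        n = int(0.1 * SR)
        t = np.arange(n) / SR
        env = np.minimum(t / 0.04, (0.1 - t) / 0.06)
        x = env * np.sin(2 * np.pi * 24e3 * t)
        assert time_features(x, SR).time_peak_amplitude == pytest.approx(0.04, abs=0.002)

    def test_times_invariant_to_amplitude_scaling(self, tone):
        a = time_features(tone, SR)
        b = time_features(0.01 * tone, SR)
        assert a == b


class TestFeatureTable:
    def test_tonality_class_boundaries(self):
        assert classify_tonality(100.0) == "tonal"
        assert classify_tonality(95.0) == "tonal"
        assert classify_tonality(94.9) == "mixed"
        assert classify_tonality(0.0) == "non_tonal"

    def test_clipped_call_excluded_and_screech_masked(self):
        from shrewvoc.audio import AudioRecording
        from shrewvoc.segmentation import CallSegment

        rng = np.random.default_rng(0)
        screech = sv.synth_screech(sv.preset("screech"), SR, 2)
        clipped = np.clip(3.0 * sv.synth_tonal_call(sv.preset("scream"), SR, 0),
                          -1.0, 1.0)
        pad = 1e-4 * rng.standard_normal(2000)
        samples = np.concatenate([pad, screech, pad, clipped, pad])
        rec = AudioRecording(samples, SR, "r0")
        off1 = (2000 + len(screech)) / SR
        segs = [
            CallSegment("c0", 2000 / SR, off1, recording_ref="r0"),
            CallSegment("c1", off1 + 2000 / SR,
                        off1 + (2000 + len(clipped)) / SR, recording_ref="r0"),
        ]
        with pytest.warns(UserWarning, match="clipped"):
            table = extract_feature_table(segs, {"r0": rec})
        assert list(table.call_id) == ["c0"]          # clipped call dropped
        row = table.iloc[0]
        assert row.tonality_class == "non_tonal"
        assert np.isnan(row.mean_f0) and np.isfinite(row.f1)
        assert len(FEATURE_COLUMNS) == 22
        assert set(FEATURE_COLUMNS) <= set(table.columns)


def test_voiced_percentage_mae_under_5_points(calls200):
    """Measured voiced percentage tracks the generator's tonal fraction."""
    errors = []
    for spec, wave in calls200:
        track = track_pitch(wave, SR)
        errors.append(abs(track.voiced_percentage - 100.0 * spec.tonal_fraction))
    assert float(np.mean(errors)) < 5.0
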