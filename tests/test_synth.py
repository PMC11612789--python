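"""Synthetic call generator: waveform contracts and ground-truth bookkeeping."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import shrewvoc as sv
from shrewvoc.synth import CallSpec, CallType, true_voiced_fraction

SR = 200_000


def zero_crossing_f0(x: np.ndarray, sr: float) -> float:
    """Independent F0 oracle for a pure tone: zero-crossing count."""
    signs = np.signbit(x)
    crossings = np.count_nonzero(signs[1:] != signs[:-1])
    return crossings / 2.0 / (len(x) / sr)


class TestTonalCalls:
    def test_sample_count_is_duration_times_rate(self):
        spec = replace(sv.preset("scream"), duration=0.16)
        assert len(sv.synth_tonal_call(spec, SR, 0)) == 32_000

    def test_constant_tone_f0_roundtrip_within_2pct(self):
        spec = CallSpec(CallType.SCREAM, duration=0.16, f0_start=24.5,
                        f0_end=24.5, f0_mean_target=24.5, call_noise_db=None,
                        snr_db=80.0)
        x = sv.synth_tonal_call(spec, SR, 0)
        # oracle on the fundamental alone (filter off harmonics 2,3)
        from scipy.signal import butter, sosfilt
        sos = butter(8, [15e3, 35e3], btype="bandpass", fs=SR, output="sos")
        f0_zc = zero_crossing_f0(sosfilt(sos, x)[2000:-2000], SR)
        assert abs(f0_zc - 24_500) / 24_500 < 0.02
        track = sv.track_pitch(x, SR)
        assert abs(np.nanmean(track.f0_hz) - 24_500) / 24_500 < 0.02

    def test_pup_scream_higher_f0_and_longer_than_adult(self):
        adult, pup = sv.preset("scream", "adult"), sv.preset("scream", "pup")
        assert pup.duration > adult.duration
        fa = sv.extract_features(sv.synth_tonal_call(adult, SR, 0), SR)
        fp = sv.extract_features(sv.synth_tonal_call(pup, SR, 0), SR)
        assert fp["mean_f0"] > fa["mean_f0"]
        assert fp["duration"] > fa["duration"]

    def test_pup_chirp_gaps_stay_silent(self):
        spec = replace(sv.preset("chirp", "pup"), duration=0.06, gap_ms=20.0,
                       snr_db=80.0)
        x = sv.synth_tonal_call(spec, SR, 0)
        gap = x[int(len(x) / 3) + 100: int(len(x) / 3) + 300]
        # only the recording noise floor remains inside the gap
        assert np.abs(gap).max() < 0.005 * np.abs(x).max()

    def test_onset_offset_ramps_avoid_clicks(self):
        x = sv.synth_tonal_call(sv.preset("scream"), SR, 0)
        assert np.abs(x[:20]).max() < 0.1 * np.abs(x).max()

    @pytest.mark.parametrize("bad", [
        dict(f0_start=120.0, f0_end=120.0),   # above Nyquist
    ])
    def test_supernyquist_f0_rejected(self, bad):
        spec = replace(sv.preset("scream"), **bad)
        with pytest.raises(ValueError, match="Nyquist"):
            sv.synth_tonal_call(spec, SR, 0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            CallSpec(CallType.SCREAM, duration=0.0)


class TestScreech:
    def test_envelope_spectrum_peaks_at_tremolo_rate(self):
        spec = replace(sv.preset("screech"), duration=0.5, tremolo_rate=80.0)
        x = sv.synth_screech(spec, SR, 0)
        # oracle: DFT of the rectified envelope
        env = np.abs(x)
        env = env - env.mean()
        spec_env = np.abs(np.fft.rfft(env))
        freqs = np.fft.rfftfreq(len(env), 1.0 / SR)
        band = (freqs > 20) & (freqs < 500)
        peak = freqs[band][np.argmax(spec_env[band])]
        assert abs(peak - 80.0) < 5.0

    def test_screech_measures_zero_voiced(self):
        for seed in range(3):
            f = sv.extract_features(sv.synth_screech(sv.preset("screech"), SR, seed), SR)
            assert f["voiced_percentage"] == 0.0

    def test_seeded_determinism(self):
        a = sv.synth_screech(sv.preset("screech"), SR, 11)
        b = sv.synth_screech(sv.preset("screech"), SR, 11)
        assert np.array_equal(a, b)
        c = sv.synth_screech(sv.preset("screech"), SR, 12)
        assert not np.array_equal(a, c)

    def test_inverted_noise_band_rejected(self):
        spec = replace(sv.preset("screech"), noise_band=(45.0, 8.0))
        with pytest.raises(ValueError, match="band"):
            sv.synth_screech(spec, SR, 0)


class TestScreechScream:
    @pytest.mark.parametrize("tf", [0.3, 0.5, 0.7])
    def test_voiced_percentage_tracks_tonal_fraction(self, tf):
        spec = replace(sv.preset("screech_scream"), tonal_fraction=tf)
        f = sv.extract_features(sv.synth_screech_scream(spec, SR, 3), SR)
        assert abs(f["voiced_percentage"] - 100.0 * tf) < 10.0

    def test_limits_approach_parent_types(self):
        near_tonal = replace(sv.preset("screech_scream"), tonal_fraction=0.99)
        f = sv.extract_features(sv.synth_screech_scream(near_tonal, SR, 0), SR)
        assert f["voiced_percentage"] > 95.0
        near_noisy = replace(sv.preset("screech_scream"), tonal_fraction=0.01)
        f = sv.extract_features(sv.synth_screech_scream(near_noisy, SR, 0), SR)
        assert f["voiced_percentage"] < 5.0

    @pytest.mark.parametrize("tf", [0.0, 1.0])
    def test_degenerate_tonal_fraction_rejected(self, tf):
        with pytest.raises(ValueError):
            CallSpec(CallType.SCREECH_SCREAM, tonal_fraction=tf)

    def test_ground_truth_voiced_fraction_rule(self):
        assert true_voiced_fraction(sv.preset("scream")) == 100.0
        assert true_voiced_fraction(sv.preset("chirp")) == 100.0
        assert true_voiced_fraction(sv.preset("screech")) == 0.0
        spec = replace(sv.preset("screech_scream"), tonal_fraction=0.4)
        assert true_voiced_fraction(spec) == pytest.approx(40.0)


@pytest.fixture(scope="module")
def small():
    cfg = sv.ExperimentConfig(
        adult_counts={"scream": 15, "screech": 15, "screech_scream": 8,
                      "chirp": 8},
        pup_counts={"chirp": 8, "scream": 6},
        n_experiments=4)
    return cfg, sv.generate_experiment(cfg, seed=5)


class TestGenerateExperiment:

    def test_ground_truth_bookkeeping(self, small):
        cfg, exp = small
        gt = exp.ground_truth
        assert len(gt) == cfg.total_calls
        counts = gt.true_type.value_counts()
        assert counts["scream"] == 21 and counts["chirp"] == 16

    def test_same_seed_identical_tables(self, small):
        cfg, exp = small
        again = sv.generate_experiment(cfg, seed=5)
        pd.testing.assert_frame_equal(exp.ground_truth, again.ground_truth)
        assert np.array_equal(exp.recording_audio("exp00"),
                              again.recording_audio("exp00"))

    def test_different_seeds_differ(self, small):
        cfg, exp = small
        other = sv.generate_experiment(cfg, seed=6)
        assert not exp.ground_truth.onset.equals(other.ground_truth.onset)

    def test_chirps_placed_only_in_caravanning(self, small):
        _, exp = small
        gt = exp.ground_truth
        adult_chirps = gt[(gt.true_type == "chirp") & (gt.age_group == "adult")]
        assert (adult_chirps.context_label == "caravanning").all()
        negatives = gt[gt.true_type.isin(["scream", "screech", "screech_scream"])
                       & (gt.age_group == "adult")]
        assert negatives.context_label.isin(["socio_negative", "avoidance"]).all()

    def test_calls_do_not_overlap(self, small):
        _, exp = small
        for _, grp in exp.ground_truth.groupby("recording_id"):
            g = grp.sort_values("onset")
            assert (g.onset.values[1:] >= g.offset.values[:-1]).all()

    def test_overfull_schedule_rejected(self):
        cfg = sv.ExperimentConfig(
            adult_counts={"scream": 4000, "screech": 0, "screech_scream": 0,
                          "chirp": 0},
            pup_counts={}, n_experiments=2)
        with pytest.raises(ValueError, match="exceed"):
            sv.generate_experiment(cfg, seed=0)
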