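"""Acoustic parameter extraction for ultrasonic calls.

Implements the 22-parameter feature set used to describe the shrew
repertoire: time features (duration, time of peak amplitude), tonality
features (voiced percentage, harmonics-to-noise ratio, Wiener entropy),
F0-contour statistics over voiced frames, power-spectral moments (centre of
gravity, spectral SD, skewness, excess kurtosis) and LPC formant-like
resonances for non-tonal calls.  Availability of the parameters depends on
the tonality class of a call: F0-contour parameters exist only for tonal
calls, formants only for non-tonal or mixed calls, and nine parameters are
defined for all calls.

Analysis frames are 2 ms with a 0.5 ms hop: at 200 kHz sampling a 2 ms
window holds >= 40 periods of a 20 kHz fundamental, so per-frame
autocorrelation pitch estimates are stable.  HNR and Wiener entropy are
measured in dB and transformed to a linear scale (power ratios,
``10**(dB/10)``) for all downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.linalg import solve_toeplitz

__all__ = [
    "FRAME_WIN_S", "FRAME_HOP_S", "FEATURE_COLUMNS", "ALL_CALLS_PARAMS",
    "TONAL_ONLY_PARAMS", "NON_TONAL_ONLY_PARAMS", "PitchConfig", "FrameTrack",
    "frame_signal", "track_pitch", "tonality_features", "f0_features",
    "spectral_shape", "formant_features", "time_features",
    "classify_tonality", "availability_mask", "extract_feature_table",
    "FeatureConfig",
]

FRAME_WIN_S = 0.002
FRAME_HOP_S = 0.0005

# canonical feature-table columns; frequencies in kHz, times in s
ALL_CALLS_PARAMS = [
    "duration", "time_peak_amplitude", "voiced_percentage", "hnr",
    "wiener_entropy", "cog", "spectral_sd", "skewness", "kurtosis",
]
TONAL_ONLY_PARAMS = [
    "time_min_f0", "time_max_f0", "min_f0", "max_f0", "mean_f0", "sd_f0",
    "mean_abs_slope",
]
NON_TONAL_ONLY_PARAMS = ["f1", "bw1", "f2", "bw2", "f3", "bw3"]
FEATURE_COLUMNS = (
    ["duration", "time_peak_amplitude", "time_min_f0", "time_max_f0",
     "voiced_percentage", "hnr", "wiener_entropy",
     "min_f0", "max_f0", "mean_f0", "sd_f0", "mean_abs_slope",
     "cog", "spectral_sd", "skewness", "kurtosis",
     "f1", "bw1", "f2", "bw2", "f3", "bw3"]
)
assert len(FEATURE_COLUMNS) == 22


def frame_signal(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Slice ``x`` into overlapping frames (n_frames x win), last partial
    frame dropped."""
    x = np.asarray(x)
    if len(x) < win:
        return x[:0].reshape(0, win)
    n = (len(x) - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


@dataclass
class PitchConfig:
    """Autocorrelation F0-tracker settings.

    A frame is voiced when the height of its normalized-autocorrelation peak
    (the periodicity strength) reaches ``voicing_threshold``.  Among local
    maxima within ``peak_margin`` of the best one, the shortest lag (highest
    frequency) wins, which resolves the period-multiple ambiguity of purely
    periodic signals.  Runs of fewer than ``min_voiced_run`` voiced frames
    are pruned as spurious.
    """

    fmin_hz: float = 5_000.0
    fmax_hz: float = 100_000.0
    voicing_threshold: float = 0.45
    peak_margin: float = 0.02
    min_voiced_run: int = 3
    win_s: float = FRAME_WIN_S
    hop_s: float = FRAME_HOP_S


@dataclass
class FrameTrack:
    """Per-frame F0 track of one call segment."""

    frame_times: np.ndarray          # s, frame centres from segment onset
    f0_hz: np.ndarray                # NaN where unvoiced
    voiced: np.ndarray               # bool
    strength: np.ndarray             # normalized autocorrelation peak height
    frame_energy: np.ndarray         # linear RMS
    degenerate: bool = False

    def __post_init__(self) -> None:
        assert np.all(np.isnan(self.f0_hz[~self.voiced]))

    @property
    def voiced_percentage(self) -> float:
        if len(self.voiced) == 0:
            return 0.0
        return 100.0 * float(np.mean(self.voiced))


def track_pitch(x: np.ndarray, sample_rate: float,
                config: PitchConfig | None = None) -> FrameTrack:
    """Track the fundamental frequency of one call segment.

    Boersma-style normalized autocorrelation per frame (signal
    autocorrelation divided by the window autocorrelation), peak picked by
    parabolic interpolation inside the configured search range.  Pure tones
    come out fully voiced at the tone frequency; broadband noise yields
    (near-)zero voiced frames.
    """
    cfg = config or PitchConfig()
    if cfg.fmax_hz >= sample_rate / 2.0:
        cfg = PitchConfig(**{**cfg.__dict__, "fmax_hz": sample_rate / 2.0 - 1.0})
    x = np.asarray(x, dtype=np.float64)
    win = max(4, int(round(cfg.win_s * sample_rate)))
    hop = max(1, int(round(cfg.hop_s * sample_rate)))
    degenerate = False
    if len(x) < win:
        # shorter than one analysis window: single degenerate frame
        x = np.pad(x, (0, win - len(x)))
        degenerate = True
    frames = frame_signal(x, win, hop)
    n_frames = frames.shape[0]
    energy = np.sqrt(np.mean(frames**2, axis=1))

    # autocorrelation via the power spectrum, sinc-upsampled 4x in lag so
    # periods falling between integer lags keep their full peak height
    ups = 4
    w = np.hanning(win)
    nfft = 1 << int(np.ceil(np.log2(2 * win)))
    spec_pow = np.abs(np.fft.rfft(frames * w, nfft, axis=1)) ** 2
    ac = np.fft.irfft(spec_pow, ups * nfft, axis=1)[:, :ups * win]
    ac0 = ac[:, :1].copy()
    ac0[ac0 <= 0] = 1.0
    ac = ac / ac0
    wac = np.fft.irfft(np.abs(np.fft.rfft(w, nfft)) ** 2, ups * nfft)[:ups * win]
    wac = wac / wac[0]
    valid_norm = wac > 1e-6
    acn = np.zeros_like(ac)
    acn[:, valid_norm] = ac[:, valid_norm] / wac[valid_norm]

    lag_min = max(2 * ups, int(np.floor(ups * sample_rate / cfg.fmax_hz)))
    lag_max = min(ups * (win - 2), int(np.ceil(ups * sample_rate / cfg.fmin_hz)))
    f0 = np.full(n_frames, np.nan)
    strength = np.zeros(n_frames)
    for i in range(n_frames):
        seg = acn[i, lag_min:lag_max + 2]
        interior = np.where((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]))[0] + 1
        if len(interior) == 0:
            continue
        # parabolic interpolation of every local maximum: sampled values
        # misrank candidates whenever the true period falls between lags
        y0, y1, y2 = seg[interior - 1], seg[interior], seg[interior + 1]
        den = y0 - 2.0 * y1 + y2
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(den != 0, 0.5 * (y0 - y2) / den, 0.0)
        d = np.clip(d, -0.5, 0.5)
        heights = y1 - 0.25 * (y0 - y2) * d
        # window-corrected estimates can exceed 1 at larger lags; cap so the
        # margin keeps the true (shortest-lag) period among the candidates
        heights = np.minimum(heights, 1.0)
        cand = heights >= heights.max() - cfg.peak_margin
        j = int(np.argmax(cand))  # first (shortest-lag) candidate
        lag = (lag_min + interior[j] + d[j]) / ups
        strength[i] = float(heights[j])
        f0[i] = sample_rate / lag

    voiced = strength >= cfg.voicing_threshold
    voiced &= np.isfinite(f0)
    voiced = _prune_short_runs(voiced, cfg.min_voiced_run)
    f0[~voiced] = np.nan
    times = (np.arange(n_frames) * hop + win / 2.0) / sample_rate
    return FrameTrack(frame_times=times, f0_hz=f0, voiced=voiced,
                      strength=strength, frame_energy=energy,
                      degenerate=degenerate)


def _prune_short_runs(voiced: np.ndarray, min_run: int) -> np.ndarray:
    if min_run <= 1 or not voiced.any():
        return voiced
    out = voiced.copy()
    i = 0
    n = len(out)
    while i < n:
        if out[i]:
            j = i
            while j < n and out[j]:
                j += 1
            if j - i < min_run:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


class TonalityFeatures(NamedTuple):
    voiced_percentage: float
    hnr_db: float
    hnr_linear: float
    wiener_entropy_db: float
    wiener_entropy_linear: float


def tonality_features(x: np.ndarray, sample_rate: float,
                      track: FrameTrack) -> TonalityFeatures:
    """Voiced percentage, HNR and Wiener entropy of one call.

    * voiced percentage = 100 x voiced frames / all frames;
    * HNR per voiced frame from the normalized autocorrelation peak ``r`` as
      ``10 log10(r / (1 - r))`` dB, averaged over voiced frames, then
      linearized as ``10**(dB/10)``;
    * Wiener entropy = spectral flatness, the geometric-to-arithmetic-mean
    ratio of a Welch-averaged power spectrum (0 dB for white noise, strongly
    negative for pure tones), reported in dB and linear.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) == 0 or not np.any(x != 0.0):
        raise ValueError("zero-energy segment: tonality undefined")
    vp = track.voiced_percentage
    # averaged over *all* frames, so calls mixing tonal and noisy parts get
    # an HNR graded by their tonal fraction; r is clipped to keep single
    # degenerate frames from dominating the mean
    r = np.clip(track.strength, 0.01, 0.9999)
    hnr_db = float(np.mean(10.0 * np.log10(r / (1.0 - r))))
    win = max(16, int(round(FRAME_WIN_S * sample_rate)))
    nper = min(len(x), win)
    _, psd = sps.welch(x, fs=sample_rate, nperseg=nper,
                       noverlap=nper // 2, window="hann")
    psd = psd[psd > 0]
    flat_db = float(10.0 * (np.mean(np.log10(psd)) - np.log10(np.mean(psd))))
    return TonalityFeatures(
        voiced_percentage=vp,
        hnr_db=hnr_db,
        hnr_linear=10.0 ** (hnr_db / 10.0),
        wiener_entropy_db=flat_db,
        wiener_entropy_linear=10.0 ** (flat_db / 10.0),
    )


class F0Features(NamedTuple):
    min_f0: float
    max_f0: float
    mean_f0: float
    sd_f0: float
    time_of_min_f0: float
    time_of_max_f0: float
    mean_abs_slope: float
    available: bool


def f0_features(track: FrameTrack, duration: float | None = None) -> F0Features:
    """F0-contour statistics over voiced frames (kHz; times in s from call
    onset).  Mean absolute slope is the sum of |delta F0| between consecutive
    voiced detection points divided by the call duration.  With fewer than
    two voiced frames the features are unavailable."""
    voiced_idx = np.where(track.voiced)[0]
    if len(voiced_idx) < 2:
        nan = float("nan")
        return F0Features(nan, nan, nan, nan, nan, nan, nan, available=False)
    f0 = track.f0_hz[voiced_idx] / 1000.0
    t = track.frame_times[voiced_idx]
    if duration is None:
        duration = float(track.frame_times[-1] + (track.frame_times[1] - track.frame_times[0]))
    i_min, i_max = int(np.argmin(f0)), int(np.argmax(f0))
    slope_sum = float(np.sum(np.abs(np.diff(f0))))
    return F0Features(
        min_f0=float(f0[i_min]), max_f0=float(f0[i_max]),
        mean_f0=float(np.mean(f0)), sd_f0=float(np.std(f0)),
        time_of_min_f0=float(t[i_min]), time_of_max_f0=float(t[i_max]),
        mean_abs_slope=slope_sum / duration, available=True)


class SpectralMoments(NamedTuple):
    cog: float          # kHz
    spectral_sd: float  # kHz
    skewness: float
    kurtosis: float     # excess


def spectral_shape(x: np.ndarray, sample_rate: float) -> SpectralMoments:
    """Power-spectrum-weighted moments over the full call spectrum.

    Centre of gravity is the first moment of the Hann periodogram, spectral
    SD the square root of the second central moment; skewness and kurtosis
    are the standardized third/fourth central moments, kurtosis as excess
    over the Gaussian value of 3.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) == 0 or not np.any(x != 0.0):
        raise ValueError("zero-energy segment: spectrum undefined")
    freqs, psd = sps.periodogram(x, fs=sample_rate, window="hann")
    total = psd.sum()
    cog = float((freqs * psd).sum() / total)
    var = float((((freqs - cog) ** 2) * psd).sum() / total)
    sd = np.sqrt(var)
    if sd > 0:
        skew = float((((freqs - cog) ** 3) * psd).sum() / total / sd**3)
        kurt = float((((freqs - cog) ** 4) * psd).sum() / total / sd**4) - 3.0
    else:
        skew, kurt = 0.0, 0.0
    return SpectralMoments(cog=cog / 1000.0, spectral_sd=sd / 1000.0,
                           skewness=skew, kurtosis=kurt)


class Formants(NamedTuple):
    f1: float
    bw1: float
    f2: float
    bw2: float
    f3: float
    bw3: float
    n_found: int


def formant_ceiling_hz(vtl_cm: float) -> float:
    """Formant ceiling from vocal-tract length by uniform-tube scaling
    (5500 Hz for a 17.5 cm human tract)."""
    if vtl_cm <= 0:
        raise ValueError("vocal tract length must be positive")
    return 5500.0 * 17.5 / vtl_cm


def formant_features(x: np.ndarray, sample_rate: float, vtl_cm: float = 1.2,
                     ceiling_hz: float | None = None, order: int = 10,
                     pre_emphasis: float = 0.97) -> Formants:
    """Estimate the three lowest formant-like resonances of a non-tonal call.

    Linear-predictive (autocorrelation method) resonance estimation after
    pre-emphasis, on the signal resampled to twice the formant ceiling.  The
    ceiling derives from the vocal tract length (default 1.2 cm, giving
    ~80.2 kHz).  Candidate resonances must lie between 1 kHz and the
    ceiling with a bandwidth below 30 % of the ceiling; missing entries are
    NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) == 0 or not np.any(x != 0.0):
        raise ValueError("zero-energy segment: formants undefined")
    ceiling = ceiling_hz if ceiling_hz is not None else formant_ceiling_hz(vtl_cm)
    target = min(2.0 * ceiling, sample_rate)
    frac = Fraction(int(round(target)), int(round(sample_rate))).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator) \
        if frac != 1 else x.copy()
    fs = sample_rate * frac.numerator / frac.denominator
    y = sps.lfilter([1.0, -pre_emphasis], [1.0], y)
    y = y * np.hanning(len(y))
    ac = np.correlate(y, y, "full")[len(y) - 1: len(y) + order]
    if ac[0] <= 0:
        raise ValueError("degenerate autocorrelation in formant estimation")
    try:
        coeffs = solve_toeplitz((ac[:-1], ac[:-1]), ac[1:])
    except np.linalg.LinAlgError:
        return Formants(*([float("nan")] * 6), 0)
    poly = np.concatenate([[1.0], -coeffs])
    roots = np.roots(poly)
    roots = roots[np.imag(roots) > 1e-9]
    freqs = np.angle(roots) * fs / (2.0 * np.pi)
    bws = -np.log(np.clip(np.abs(roots), 1e-12, None)) * fs / np.pi
    ok = (freqs > 1000.0) & (freqs < ceiling - 50.0) & (bws > 0) & (bws < 0.3 * ceiling)
    freqs, bws = freqs[ok], bws[ok]
    idx = np.argsort(freqs)
    freqs, bws = freqs[idx], bws[idx]
    vals = []
    for i in range(3):
        if i < len(freqs):
            vals += [freqs[i] / 1000.0, bws[i] / 1000.0]
        else:
            vals += [float("nan"), float("nan")]
    return Formants(*vals, n_found=int(min(len(freqs), 3)))


class TimeFeatures(NamedTuple):
    duration: float
    time_peak_amplitude: float


def time_features(x: np.ndarray, sample_rate: float) -> TimeFeatures:
    """Duration and time from onset to the peak of the amplitude envelope."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("empty segment")
    win = max(1, int(round(FRAME_WIN_S * sample_rate)))
    env = np.convolve(np.abs(x), np.ones(win) / win, mode="same")
    return TimeFeatures(duration=len(x) / sample_rate,
                        time_peak_amplitude=float(np.argmax(env)) / sample_rate)


def classify_tonality(voiced_percentage: float, tonal_threshold: float = 95.0) -> str:
    """Tonality class from the voiced percentage: fully tonal calls (>=
    threshold), solely non-tonal calls (0 %), and mixed calls in between."""
    if voiced_percentage >= tonal_threshold:
        return "tonal"
    if voiced_percentage == 0.0:
        return "non_tonal"
    return "mixed"


def availability_mask(tonality_class: str) -> dict[str, bool]:
    """Which of the 22 parameters are defined for a tonality class."""
    mask = {c: True for c in ALL_CALLS_PARAMS}
    tonal = tonality_class == "tonal"
    mask.update({c: tonal for c in TONAL_ONLY_PARAMS})
    mask.update({c: not tonal for c in NON_TONAL_ONLY_PARAMS})
    return mask


@dataclass
class FeatureConfig:
    pitch: PitchConfig = field(default_factory=PitchConfig)
    tonal_threshold: float = 95.0
    vtl_cm: float = 1.2
    formant_ceiling_hz: float | None = None
    clip_level: float = 0.999


def extract_features(x: np.ndarray, sample_rate: float,
                     config: FeatureConfig | None = None) -> dict[str, float | str]:
    """Compute the full feature vector of one call waveform.

    Unavailable parameters (per the tonality class) are NaN; the returned
    dict additionally carries ``tonality_class``.
    """
    cfg = config or FeatureConfig()
    out: dict[str, float | str] = {c: float("nan") for c in FEATURE_COLUMNS}
    tf = time_features(x, sample_rate)
    out["duration"] = tf.duration
    out["time_peak_amplitude"] = tf.time_peak_amplitude
    track = track_pitch(x, sample_rate, cfg.pitch)
    ton = tonality_features(x, sample_rate, track)
    out["voiced_percentage"] = ton.voiced_percentage
    out["hnr"] = ton.hnr_linear
    out["wiener_entropy"] = ton.wiener_entropy_linear
    sm = spectral_shape(x, sample_rate)
    out["cog"], out["spectral_sd"] = sm.cog, sm.spectral_sd
    out["skewness"], out["kurtosis"] = sm.skewness, sm.kurtosis
    tclass = classify_tonality(ton.voiced_percentage, cfg.tonal_threshold)
    out["tonality_class"] = tclass
    if tclass == "tonal":
        ff = f0_features(track, duration=tf.duration)
        if ff.available:
            out.update(min_f0=ff.min_f0, max_f0=ff.max_f0, mean_f0=ff.mean_f0,
                       sd_f0=ff.sd_f0, time_min_f0=ff.time_of_min_f0,
                       time_max_f0=ff.time_of_max_f0,
                       mean_abs_slope=ff.mean_abs_slope)
    else:
        fm = formant_features(x, sample_rate, vtl_cm=cfg.vtl_cm,
                              ceiling_hz=cfg.formant_ceiling_hz)
        out.update(f1=fm.f1, bw1=fm.bw1, f2=fm.f2, bw2=fm.bw2,
                   f3=fm.f3, bw3=fm.bw3)
    return out


def extract_feature_table(segments: Sequence, recordings: dict,
                          config: FeatureConfig | None = None,
                          metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build the per-call feature table (one row per high-quality call).

    ``segments`` are :class:`~shrewvoc.segmentation.CallSegment` objects,
    ``recordings`` maps ``recording_ref`` to
    :class:`~shrewvoc.audio.AudioRecording`.  Clipped calls (any
    |sample| >= clip level) and calls flagged ``quality='low'`` are excluded
    from the returned table; exclusions are reported via warnings.
    ``metadata`` (indexed like call_ids, optional) contributes
    ``individual_id`` / ``age_group`` columns.
    """
    cfg = config or FeatureConfig()
    rows = []
    excluded: list[tuple[str, str]] = []
    for seg in segments:
        if seg.recording_ref not in recordings:
            raise KeyError(f"segment {seg.call_id} references unknown recording "
                           f"{seg.recording_ref!r}")
        rec = recordings[seg.recording_ref]
        i0 = int(round(seg.onset * rec.sample_rate))
        i1 = int(round(seg.offset * rec.sample_rate))
        x = rec.samples[i0:i1]
        if seg.quality == "low":
            excluded.append((seg.call_id, "flagged low quality"))
            continue
        if np.any(np.abs(x) >= cfg.clip_level):
            excluded.append((seg.call_id, "clipped (over-amplified)"))
            continue
        feats = extract_features(x, rec.sample_rate, cfg)
        feats["call_id"] = seg.call_id
        feats["recording_id"] = seg.recording_ref
        feats["onset"] = seg.onset
        feats["offset"] = seg.offset
        feats["quality"] = "high"
        rows.append(feats)
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} call(s) from the high-quality table: "
            + "; ".join(f"{cid} ({why})" for cid, why in excluded[:10]))
    cols = ["call_id", "recording_id", "onset", "offset"] + FEATURE_COLUMNS \
        + ["tonality_class", "quality"]
    table = pd.DataFrame(rows, columns=cols if rows else cols)
    if metadata is not None and len(table):
        table = table.merge(metadata, on="call_id", how="left")
    return table
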