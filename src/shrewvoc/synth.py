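"""Synthetic generator for Etruscan-shrew-like ultrasonic calls.

Produces waveform datasets of the four call types of the shrew repertoire
(screams, screeches, screech-screams, chirps) with known ground truth, plus
dyad behaviour-event streams and experiment metadata, so the whole analysis
chain can be exercised and validated without any recorded data.

Call structure follows the field description of the repertoire:

* **scream** -- long, weakly modulated tonal call (adult mean F0 around
  24.5 kHz; pup screams are longer with a higher F0),
* **screech** -- solely non-tonal call, band-limited noise with a tremolo
  (pulsed amplitude) structure,
* **screech-scream** -- graded call concatenating a screech-like and a
  scream-like part, with a controllable tonal fraction,
* **chirp** -- short, soft tonal call with an ascending contour (adults) or
  a reversed-U contour with optional sub-50-ms gaps (pups), emitted in bouts.

Tonal calls carry three harmonics at -6 dB per harmonic: enough harmonic
structure to give a clear HNR / spectral-flatness contrast against the noisy
calls without attempting a vocal-tract model.  A white background-noise floor
(default SNR 30 dB) keeps segmentation non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "CallType",
    "AgeGroup",
    "CallSpec",
    "preset",
    "synth_tonal_call",
    "synth_screech",
    "synth_screech_scream",
    "synth_call",
    "ExperimentConfig",
    "SyntheticExperiment",
    "generate_experiment",
    "DEFAULT_SAMPLE_RATE",
]

DEFAULT_SAMPLE_RATE = 200_000  # Hz; 192 kHz equally supported

HARMONIC_AMPLITUDES = (1.0, 0.5, 0.25)  # -6 dB per harmonic


class CallType(str, Enum):
    SCREAM = "scream"
    SCREECH = "screech"
    SCREECH_SCREAM = "screech_scream"
    CHIRP = "chirp"


class AgeGroup(str, Enum):
    ADULT = "adult"
    PUP = "pup"


@dataclass(frozen=True)
class CallSpec:
    """Parameters of one synthetic call.

    Frequencies are in kHz, durations in seconds, ``tremolo_rate`` in Hz.
    ``tonal_fraction`` is the fraction of the call duration occupied by the
    tonal part: 1 for screams/chirps, 0 for screeches, strictly between 0 and
    1 for screech-screams.
    """

    call_type: CallType
    age_group: AgeGroup = AgeGroup.ADULT
    duration: float = 0.16
    f0_start: float = 24.0
    f0_end: float = 25.0
    f0_mean_target: float = 24.5
    tremolo_rate: float = 80.0
    tonal_fraction: float = 1.0
    amplitude: float = 0.5
    noise_band: tuple[float, float] = (8.0, 45.0)
    snr_db: float = 30.0
    bout_size: int = 1
    gap_ms: float = 0.0
    # pup chirps may follow a reversed-U (parabolic) F0 trajectory
    contour: str = "linear"  # "linear" | "reversed_u"
    ramp_s: float = 0.002
    noisy_part_first: bool = True
    # broadband turbulence noise inside tonal parts, dB below the harmonic
    # RMS; keeps the harmonics-to-noise ratio of tonal calls in a realistic
    # range instead of the near-infinite HNR of a clean oscillator
    call_noise_db: float = 18.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if not 0.0 <= self.tonal_fraction <= 1.0:
            raise ValueError("tonal_fraction must lie in [0, 1]")
        expected = {
            CallType.SCREAM: lambda tf: tf == 1.0,
            CallType.CHIRP: lambda tf: tf == 1.0,
            CallType.SCREECH: lambda tf: tf == 0.0,
            CallType.SCREECH_SCREAM: lambda tf: 0.0 < tf < 1.0,
        }
        if not expected[self.call_type](self.tonal_fraction):
            raise ValueError(
                f"tonal_fraction={self.tonal_fraction} invalid for {self.call_type.value}"
            )
        if not 0.0 < self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in (0, 1]")


# Presets emulate the reported scale of the repertoire: adult screams
# 0.16 +/- 0.07 s at mean F0 24.5 kHz, screeches 0.11 s of pulsed noise,
# screech-screams 0.15 s, chirps 0.03 s with an ascending contour.  Pup
# screams are longer with higher F0; pup chirps are longer, reversed-U.
_PRESETS: dict[tuple[CallType, AgeGroup], CallSpec] = {
    (CallType.SCREAM, AgeGroup.ADULT): CallSpec(
        CallType.SCREAM, AgeGroup.ADULT, duration=0.16,
        f0_start=23.5, f0_end=25.0, f0_mean_target=24.5),
    (CallType.SCREAM, AgeGroup.PUP): CallSpec(
        CallType.SCREAM, AgeGroup.PUP, duration=0.24,
        f0_start=30.0, f0_end=28.5, f0_mean_target=29.5),
    (CallType.SCREECH, AgeGroup.ADULT): CallSpec(
        CallType.SCREECH, AgeGroup.ADULT, duration=0.11, tonal_fraction=0.0,
        tremolo_rate=80.0, noise_band=(8.0, 45.0)),
    (CallType.SCREECH, AgeGroup.PUP): CallSpec(
        CallType.SCREECH, AgeGroup.PUP, duration=0.10, tonal_fraction=0.0,
        tremolo_rate=50.0, noise_band=(8.0, 45.0)),
    (CallType.SCREECH_SCREAM, AgeGroup.ADULT): CallSpec(
        CallType.SCREECH_SCREAM, AgeGroup.ADULT, duration=0.15,
        f0_start=23.5, f0_end=25.0, f0_mean_target=24.5, tonal_fraction=0.5),
    (CallType.SCREECH_SCREAM, AgeGroup.PUP): CallSpec(
        CallType.SCREECH_SCREAM, AgeGroup.PUP, duration=0.16,
        f0_start=29.0, f0_end=28.0, f0_mean_target=28.5, tonal_fraction=0.5,
        tremolo_rate=50.0),
    (CallType.CHIRP, AgeGroup.ADULT): CallSpec(
        CallType.CHIRP, AgeGroup.ADULT, duration=0.03,
        f0_start=14.0, f0_end=24.0, f0_mean_target=19.9, ramp_s=0.0015),
    (CallType.CHIRP, AgeGroup.PUP): CallSpec(
        CallType.CHIRP, AgeGroup.PUP, duration=0.05,
        f0_start=15.0, f0_end=16.0, f0_mean_target=21.0,
        contour="reversed_u", ramp_s=0.0015),
}


def preset(call_type: CallType | str, age_group: AgeGroup | str = AgeGroup.ADULT) -> CallSpec:
    """Return the default :class:`CallSpec` for a call type and age group."""
    return _PRESETS[(CallType(call_type), AgeGroup(age_group))]


def _check_nyquist(spec: CallSpec, sample_rate: float) -> None:
    nyq_khz = sample_rate / 2000.0
    top = max(spec.f0_start, spec.f0_end) * len(HARMONIC_AMPLITUDES)
    if max(spec.f0_start, spec.f0_end) > nyq_khz:
        raise ValueError(
            f"fundamental {max(spec.f0_start, spec.f0_end):.1f} kHz exceeds the "
            f"Nyquist frequency {nyq_khz:.1f} kHz at sample rate {sample_rate} Hz"
        )
    del top  # harmonics above Nyquist are simply omitted during synthesis


def _ramp_envelope(n: int, sample_rate: float, ramp_s: float) -> np.ndarray:
    env = np.ones(n)
    nr = min(int(round(ramp_s * sample_rate)), n // 2)
    if nr > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = r
        env[-nr:] = r[::-1]
    return env


def _f0_contour_hz(spec: CallSpec, n: int) -> np.ndarray:
    """Instantaneous F0 in Hz over ``n`` samples."""
    x = np.linspace(0.0, 1.0, n, endpoint=False)
    f_start, f_end = spec.f0_start * 1000.0, spec.f0_end * 1000.0
    if spec.contour == "reversed_u":
        # parabola through f_start at onset/offset, peaking mid-call
        peak = spec.f0_mean_target * 1000.0 * 1.25
        f = f_start + (peak - f_start) * (1.0 - (2.0 * x - 1.0) ** 2)
    else:
        f = f_start + (f_end - f_start) * x
    return f


def _add_noise_floor(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        return x
    sigma = rms * 10.0 ** (-snr_db / 20.0)
    return x + sigma * rng.standard_normal(len(x))


def synth_tonal_call(spec: CallSpec, sample_rate: float = DEFAULT_SAMPLE_RATE,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Synthesize a tonal call (scream or chirp).

    The instantaneous frequency follows a linear contour between
    ``f0_start`` and ``f0_end`` (or the reversed-U parabola for pup chirps);
    three harmonics decay at -6 dB per harmonic.  Pup chirps with
    ``gap_ms > 0`` carry silent gaps shorter than 50 ms.  Onset/offset ramps
    avoid clicks.
    """
    if spec.call_type not in (CallType.SCREAM, CallType.CHIRP):
        raise ValueError(f"synth_tonal_call expects scream or chirp, got {spec.call_type.value}")
    _check_nyquist(spec, sample_rate)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(spec.duration * sample_rate))
    f = _f0_contour_hz(spec, n)
    phase = 2.0 * np.pi * np.cumsum(f) / sample_rate
    nyq = sample_rate / 2.0
    x = np.zeros(n)
    for h, a in enumerate(HARMONIC_AMPLITUDES, start=1):
        valid = f * h < nyq
        x[valid] += a * np.sin(h * phase[valid])
    env = _ramp_envelope(n, sample_rate, spec.ramp_s)
    if spec.gap_ms > 0:
        if spec.gap_ms >= 50.0:
            raise ValueError("intra-call gaps must stay below 50 ms")
        gap_n = int(round(spec.gap_ms / 1000.0 * sample_rate))
        # two gaps at one third and two thirds of the call
        for frac in (1.0 / 3.0, 2.0 / 3.0):
            start = int(frac * n)
            stop = min(start + gap_n, n)
            env[start:stop] = 0.0
    x *= env
    if spec.call_noise_db is not None and np.any(x != 0.0):
        # turbulence noise confined to the call band, like the screech noise
        lo, hi = spec.noise_band
        hi = min(hi, sample_rate / 2000.0 * 0.95)
        sos = signal.butter(6, [lo * 1000.0, hi * 1000.0], btype="bandpass",
                            fs=sample_rate, output="sos")
        turb = signal.sosfilt(sos, rng.standard_normal(n))
        turb_rms = np.sqrt(np.mean(turb**2))
        if turb_rms > 0:
            sigma = np.sqrt(np.mean(x**2)) * 10.0 ** (-spec.call_noise_db / 20.0)
            x += sigma * (turb / turb_rms) * env
    x = _add_noise_floor(x, spec.snr_db, rng)
    peak = np.abs(x).max()
    if peak > 0:
        x *= spec.amplitude / peak
    return x


def synth_screech(spec: CallSpec, sample_rate: float = DEFAULT_SAMPLE_RATE,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Synthesize a screech: band-limited noise amplitude-modulated at the
    tremolo rate, with no stable harmonic structure."""
    if spec.call_type is not CallType.SCREECH:
        raise ValueError(f"synth_screech expects a screech spec, got {spec.call_type.value}")
    if spec.tremolo_rate <= 0:
        raise ValueError("tremolo_rate must be positive")
    lo, hi = spec.noise_band
    if not 0.0 < lo < hi:
        raise ValueError(f"noise_band ({lo}, {hi}) kHz is empty or inverted")
    if hi * 1000.0 >= sample_rate / 2.0:
        raise ValueError("noise_band upper edge exceeds Nyquist")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(spec.duration * sample_rate))
    noise = rng.standard_normal(n)
    sos = signal.butter(6, [lo * 1000.0, hi * 1000.0], btype="bandpass",
                        fs=sample_rate, output="sos")
    x = signal.sosfilt(sos, noise)
    t = np.arange(n) / sample_rate
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    tremolo = 0.55 + 0.45 * np.sin(2.0 * np.pi * spec.tremolo_rate * t + phase0)
    x *= tremolo
    x *= _ramp_envelope(n, sample_rate, spec.ramp_s)
    x = _add_noise_floor(x, spec.snr_db, rng)
    peak = np.abs(x).max()
    if peak > 0:
        x *= spec.amplitude / peak
    return x


def synth_screech_scream(spec: CallSpec, sample_rate: float = DEFAULT_SAMPLE_RATE,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Synthesize a graded screech-scream: a screech-like part and a
    scream-like tonal part concatenated (noisy part first by default),
    RMS-matched at the junction."""
    if spec.call_type is not CallType.SCREECH_SCREAM:
        raise ValueError("synth_screech_scream expects a screech_scream spec")
    if not 0.0 < spec.tonal_fraction < 1.0:
        raise ValueError(
            f"tonal_fraction must lie strictly in (0, 1) for screech_scream, "
            f"got {spec.tonal_fraction}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tonal_spec = replace(
        spec, call_type=CallType.SCREAM, tonal_fraction=1.0,
        duration=spec.duration * spec.tonal_fraction)
    noisy_spec = replace(
        spec, call_type=CallType.SCREECH, tonal_fraction=0.0,
        duration=spec.duration * (1.0 - spec.tonal_fraction))
    tonal = synth_tonal_call(tonal_spec, sample_rate, rng)
    noisy = synth_screech(noisy_spec, sample_rate, rng)
    # amplitude-match the two parts at the junction
    rms_t = np.sqrt(np.mean(tonal**2))
    rms_n = np.sqrt(np.mean(noisy**2))
    if rms_n > 0:
        noisy *= rms_t / rms_n
    parts = (noisy, tonal) if spec.noisy_part_first else (tonal, noisy)
    x = np.concatenate(parts)
    peak = np.abs(x).max()
    if peak > 0:
        x *= spec.amplitude / peak
    return x


def synth_call(spec: CallSpec, sample_rate: float = DEFAULT_SAMPLE_RATE,
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Dispatch synthesis by call type."""
    if spec.call_type is CallType.SCREECH:
        return synth_screech(spec, sample_rate, seed)
    if spec.call_type is CallType.SCREECH_SCREAM:
        return synth_screech_scream(spec, sample_rate, seed)
    return synth_tonal_call(spec, sample_rate, seed)


def true_voiced_fraction(spec: CallSpec) -> float:
    """Ground-truth voiced fraction in percent (100 x tonal fraction)."""
    return 100.0 * spec.tonal_fraction


# ---------------------------------------------------------------------------
# experiment-level generation
# ---------------------------------------------------------------------------

SEX_COMPOSITIONS = ("MM", "FF", "MF")
FAMILIARITY = ("familiar", "unfamiliar")
HOUSING = ("pair", "same_sex_group")

# ethogram categories of the dyad confrontation experiments
BEHAVIOR_CATEGORIES = (
    "avoidance", "box", "caravanning", "combination", "socio_negative",
    "wire_mesh", "no_physical_interaction",
)


@dataclass
class ExperimentConfig:
    """Sizing and factor levels of a synthetic recording campaign.

    ``adult_counts`` / ``pup_counts`` give per-call-type call counts; adult
    calls are placed in dyad confrontation recordings (chirps inside
    caravanning events, the socio-negative types inside socio-negative or
    avoidance events), pup calls in isolation recordings without behaviour
    annotation.  Durations are in seconds.
    """

    adult_counts: dict[str, int] = field(default_factory=lambda: {
        "scream": 140, "screech": 190, "screech_scream": 95, "chirp": 20})
    pup_counts: dict[str, int] = field(default_factory=lambda: {
        "scream": 60, "screech": 10, "screech_scream": 5, "chirp": 80})
    n_experiments: int = 12
    closed_door_s: float = 10.0
    open_door_s: float = 60.0
    pup_session_s: float = 40.0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    snr_db: float = 30.0
    amplitude: float = 0.5
    tonal_fraction_range: tuple[float, float] = (0.15, 0.85)
    chirp_bout_size: int = 4
    min_call_gap_s: float = 0.15

    @property
    def total_calls(self) -> int:
        return sum(self.adult_counts.values()) + sum(self.pup_counts.values())


_SOCIO_NEG_TYPES = ("scream", "screech", "screech_scream")

# relative scatter applied to the preset scales per call
_DURATION_SD = {"scream": 0.35, "screech": 0.4, "screech_scream": 0.3, "chirp": 0.4}
_F0_SD_KHZ = {"scream": 2.0, "screech": 0.0, "screech_scream": 1.5, "chirp": 1.5}


def _randomized_spec(call_type: str, age_group: str, cfg: ExperimentConfig,
                     rng: np.random.Generator) -> CallSpec:
    base = preset(call_type, age_group)
    dur = float(base.duration * np.exp(rng.normal(0.0, _DURATION_SD[call_type])))
    dur = float(np.clip(dur, 0.015, 0.6))
    df0 = rng.normal(0.0, _F0_SD_KHZ[call_type])
    kwargs: dict = dict(duration=dur, snr_db=cfg.snr_db, amplitude=cfg.amplitude)
    if call_type != "screech":
        kwargs.update(
            f0_start=max(6.0, base.f0_start + df0),
            f0_end=max(6.0, base.f0_end + df0),
            f0_mean_target=max(6.0, base.f0_mean_target + df0),
        )
    if call_type == "screech_scream":
        lo, hi = cfg.tonal_fraction_range
        kwargs["tonal_fraction"] = float(rng.uniform(lo, hi))
        kwargs["noisy_part_first"] = bool(rng.integers(0, 2))
    if call_type in ("screech", "screech_scream"):
        kwargs["tremolo_rate"] = float(base.tremolo_rate * np.exp(rng.normal(0.0, 0.15)))
    return replace(base, **kwargs)


def _coarse_class(call_type: str, tonal_fraction: float) -> str:
    """Coarse acoustic class of a call: graded calls side with whichever
    discrete class dominates their duration."""
    if call_type == "screech_scream":
        return "scream_like" if tonal_fraction >= 0.5 else "screech_like"
    return {"scream": "scream_like", "screech": "screech_like", "chirp": "chirp"}[call_type]


@dataclass
class SyntheticExperiment:
    """Result bundle of :func:`generate_experiment`.

    Audio is synthesized lazily per recording (deterministically from the
    stored seed) to keep memory bounded; :meth:`recording_audio` returns the
    waveform of one recording, :meth:`write` materializes WAV files plus the
    ground-truth, behaviour and dyad tables.
    """

    config: ExperimentConfig
    seed: int
    ground_truth: pd.DataFrame
    behavior: pd.DataFrame
    dyads: pd.DataFrame
    recording_ids: list[str]
    _durations: dict[str, float]

    def recording_duration(self, recording_id: str) -> float:
        return self._durations[recording_id]

    def recording_audio(self, recording_id: str) -> np.ndarray:
        cfg = self.config
        sr = cfg.sample_rate
        n = int(round(self._durations[recording_id] * sr))
        rid_index = self.recording_ids.index(recording_id)
        rng = np.random.default_rng((self.seed, 7919, rid_index))
        # silent floor well below call SNR so thresholding is non-trivial
        x = 10.0 ** (-65.0 / 20.0) * rng.standard_normal(n)
        rows = self.ground_truth[self.ground_truth.recording_id == recording_id]
        for row in rows.itertuples():
            spec = _spec_from_row(row, cfg)
            call_rng = np.random.default_rng((self.seed, 104729, int(row.call_index)))
            w = synth_call(spec, sr, call_rng)
            i0 = int(round(row.onset * sr))
            x[i0:i0 + len(w)] += w
        return x

    def iter_recordings(self) -> Iterator[tuple[str, np.ndarray]]:
        for rid in self.recording_ids:
            yield rid, self.recording_audio(rid)

    def write(self, outdir: str | Path) -> None:
        from .audio import write_wav
        from .textgrid import write_textgrid

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rid, x in self.iter_recordings():
            write_wav(outdir / f"{rid}.wav", x, int(self.config.sample_rate))
        self.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        self.behavior.to_csv(outdir / "behavior.csv", index=False)
        self.dyads.to_csv(outdir / "dyads.csv", index=False)
        for rid in self.behavior.recording_id.unique():
            ev = self.behavior[self.behavior.recording_id == rid]
            tier = list(zip(ev.onset, ev.offset, ev.category))
            write_textgrid(outdir / f"{rid}.TextGrid", {"behavior": tier},
                           xmax=self._durations[rid])


def _spec_from_row(row, cfg: ExperimentConfig) -> CallSpec:
    rng = np.random.default_rng((int(row.spec_seed),))
    spec = _randomized_spec(row.true_type, row.age_group, cfg, rng)
    # pin the exact randomized values recorded in the table
    spec = replace(spec, duration=float(row.duration))
    if row.true_type == "screech_scream":
        spec = replace(spec, tonal_fraction=float(row.true_voiced_fraction) / 100.0)
    return spec


def generate_experiment(config: ExperimentConfig | None = None,
                        seed: int = 0) -> SyntheticExperiment:
    """Generate a full synthetic recording campaign with ground truth.

    Calls are placed at non-overlapping times inside behaviour events of the
    open-door phase (chirps exclusively in caravanning, the socio-negative
    types in socio-negative interaction or avoidance events).  Fully
    reproducible from ``seed``.
    """
    cfg = config or ExperimentConfig()
    rng = np.random.default_rng((seed, 13))
    sr = cfg.sample_rate

    # --- dyad metadata: cross the factor levels across experiments
    dyad_rows = []
    for e in range(cfg.n_experiments):
        dyad_rows.append({
            "experiment_id": f"exp{e:02d}",
            "individual_1": f"ad{2 * e:02d}",
            "individual_2": f"ad{2 * e + 1:02d}",
            "sex_composition": SEX_COMPOSITIONS[e % 3],
            "familiarity": FAMILIARITY[(e // 3) % 2],
            "housing_type": HOUSING[(e // 6) % 2],
            "closed_door_min": cfg.closed_door_s / 60.0,
            "open_door_min": cfg.open_door_s / 60.0,
        })
    dyads = pd.DataFrame(dyad_rows)

    # --- behaviour event streams (open-door phase only)
    behavior_rows = []
    event_slots: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for e in range(cfg.n_experiments):
        rid = f"exp{e:02d}"
        t = cfg.closed_door_s
        t_end = cfg.closed_door_s + cfg.open_door_s
        slots: dict[str, list[tuple[float, float]]] = {
            "caravanning": [], "socio_negative": [], "avoidance": []}
        pattern = ["no_physical_interaction", "socio_negative", "box",
                   "caravanning", "avoidance", "wire_mesh", "socio_negative",
                   "caravanning"]
        k = 0
        while t < t_end - 1.0:
            cat = pattern[k % len(pattern)]
            dur = float(rng.uniform(3.0, 8.0))
            onset, offset = t, min(t + dur, t_end)
            behavior_rows.append({
                "experiment_id": rid, "recording_id": rid, "category": cat,
                "onset": onset, "offset": offset, "phase": "open_door"})
            if cat in slots:
                slots[cat].append((onset, offset))
            t = offset + float(rng.uniform(0.2, 1.0))
            k += 1
        event_slots[rid] = slots
    behavior = pd.DataFrame(behavior_rows)

    # --- assign calls to experiments and slots
    gt_rows: list[dict] = []
    call_index = 0

    def _place_adult_calls() -> None:
        nonlocal call_index
        per_exp_cursor: dict[tuple[str, str], tuple[int, float]] = {}
        type_order: list[str] = []
        for ct, cnt in cfg.adult_counts.items():
            type_order.extend([ct] * cnt)
        rng.shuffle(type_order)
        exp_cycle = 0
        for ct in type_order:
            slot_kind = "caravanning" if ct == "chirp" else (
                "socio_negative" if rng.uniform() < 0.8 else "avoidance")
            placed = False
            for attempt in range(cfg.n_experiments):
                rid = f"exp{(exp_cycle + attempt) % cfg.n_experiments:02d}"
                slots = event_slots[rid][slot_kind]
                key = (rid, slot_kind)
                si, tpos = per_exp_cursor.get(key, (0, -1.0))
                spec_seed = int(rng.integers(0, 2**31 - 1))
                spec = _randomized_spec(ct, "adult", cfg,
                                        np.random.default_rng((spec_seed,)))
                while si < len(slots):
                    s0, s1 = slots[si]
                    start = max(s0 + 0.05, tpos)
                    if start + spec.duration + 0.05 <= s1:
                        _record(rid, ct, "adult", spec, spec_seed, start, slot_kind)
                        per_exp_cursor[key] = (si, start + spec.duration + cfg.min_call_gap_s)
                        placed = True
                        break
                    si += 1
                    tpos = -1.0
                    per_exp_cursor[key] = (si, tpos)
                if placed:
                    exp_cycle = (exp_cycle + 1) % cfg.n_experiments
                    break
            if not placed:
                raise ValueError(
                    f"requested calls exceed available {slot_kind} time for type {ct}; "
                    "increase open_door_s or n_experiments")

    def _record(rid: str, ct: str, age: str, spec: CallSpec, spec_seed: int,
                onset: float, context: str) -> None:
        nonlocal call_index
        dyad = dyads[dyads.experiment_id == rid.split("_")[0]]
        if age == "adult":
            ind = str(dyad.iloc[0][f"individual_{1 + call_index % 2}"])
        else:
            ind = rid.split("_")[0].replace("pup", "pup")
        gt_rows.append({
            "call_id": f"call{call_index:05d}",
            "call_index": call_index,
            "true_type": ct,
            "true_voiced_fraction": true_voiced_fraction(spec),
            "coarse_class": _coarse_class(ct, spec.tonal_fraction),
            "onset": onset,
            "offset": onset + spec.duration,
            "duration": spec.duration,
            "individual_id": ind,
            "experiment_id": rid if age == "adult" else rid,
            "recording_id": rid,
            "context_label": context,
            "age_group": age,
            "spec_seed": spec_seed,
        })
        call_index += 1

    _place_adult_calls()

    # --- pup isolation sessions: pack pup calls sequentially
    pup_type_order: list[str] = []
    for ct, cnt in cfg.pup_counts.items():
        pup_type_order.extend([ct] * cnt)
    rng.shuffle(pup_type_order)
    pup_recordings: list[str] = []
    if pup_type_order:
        session = 0
        t = 0.5
        rid = f"pup{session:02d}"
        pup_recordings.append(rid)
        for ct in pup_type_order:
            spec_seed = int(rng.integers(0, 2**31 - 1))
            spec = _randomized_spec(ct, "pup", cfg, np.random.default_rng((spec_seed,)))
            if t + spec.duration + 0.1 > cfg.pup_session_s:
                session += 1
                rid = f"pup{session:02d}"
                pup_recordings.append(rid)
                t = 0.5
            gt_rows.append({
                "call_id": f"call{call_index:05d}",
                "call_index": call_index,
                "true_type": ct,
                "true_voiced_fraction": true_voiced_fraction(spec),
                "coarse_class": _coarse_class(ct, spec.tonal_fraction),
                "onset": t,
                "offset": t + spec.duration,
                "duration": spec.duration,
                "individual_id": f"pup_ind{session % 6:02d}",
                "experiment_id": rid,
                "recording_id": rid,
                "context_label": "isolation",
                "age_group": "pup",
                "spec_seed": spec_seed,
            })
            call_index += 1
            t += spec.duration + cfg.min_call_gap_s + float(rng.uniform(0.0, 0.1))

    ground_truth = pd.DataFrame(gt_rows).sort_values(
        ["recording_id", "onset"]).reset_index(drop=True)

    durations = {f"exp{e:02d}": cfg.closed_door_s + cfg.open_door_s
                 for e in range(cfg.n_experiments)}
    durations.update({rid: cfg.pup_session_s for rid in pup_recordings})
    recording_ids = [f"exp{e:02d}" for e in range(cfg.n_experiments)] + pup_recordings

    return SyntheticExperiment(
        config=cfg, seed=seed, ground_truth=ground_truth, behavior=behavior,
        dyads=dyads, recording_ids=recording_ids, _durations=durations)
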