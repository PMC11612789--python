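"""Call-unit detection from the energy envelope.

A vocal unit is the smallest stretch of continuous sound energy.  In pup
mode, adjacent units separated by gaps shorter than the merge threshold
(default 50 ms) are merged into one call, because pup calls often carry
short silent gaps; in adult mode no merging is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioRecording
from .features import FRAME_HOP_S, FRAME_WIN_S, frame_signal

__all__ = ["CallSegment", "SegmentationConfig", "segment_calls"]


@dataclass(frozen=True)
class CallSegment:
    """One detected vocal unit, a half-open interval [onset, offset)."""

    call_id: str
    onset: float
    offset: float
    age_mode: str = "adult"
    quality: str = "high"
    recording_ref: str = ""

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SegmentationConfig:
    """Energy-threshold detection settings.

    ``rel_threshold`` multiplies the median frame RMS of the recording
    (a noise-floor proxy); ``abs_threshold`` is an absolute RMS floor.  A
    frame is active when its RMS exceeds both.  ``merge_gap_s`` is the pup
    merge rule; ``min_duration_s`` drops spurious blips.
    """

    rel_threshold: float = 6.0
    abs_threshold: float = 1e-4
    merge_gap_s: float = 0.050
    min_duration_s: float = 0.008


def segment_calls(recording: AudioRecording, age_mode: str = "adult",
                  config: SegmentationConfig | None = None) -> list[CallSegment]:
    """Detect call units in a recording.

    Returns segments snapped to the analysis-frame grid, non-overlapping and
    sorted by onset.  A silent recording yields an empty list.
    """
    if age_mode not in ("adult", "pup"):
        raise ValueError(f"age_mode must be 'adult' or 'pup', got {age_mode!r}")
    cfg = config or SegmentationConfig()
    x = np.asarray(recording.samples, dtype=np.float64)
    sr = recording.sample_rate
    hop = max(1, int(round(FRAME_HOP_S * sr)))
    win = max(2, int(round(FRAME_WIN_S * sr)))
    if len(x) < win:
        return []
    frames = frame_signal(x, win, hop)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    thr = max(cfg.abs_threshold, cfg.rel_threshold * float(np.median(rms)))
    active = rms > thr
    if not active.any():
        return []

    # frame runs -> candidate units (frame i covers [i*hop, i*hop + win))
    edges = np.diff(active.astype(np.int8))
    starts = list(np.where(edges == 1)[0] + 1)
    stops = list(np.where(edges == -1)[0] + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        stops.append(len(active))
    units = [(s * hop / sr, ((e - 1) * hop + win) / sr) for s, e in zip(starts, stops)]

    if age_mode == "pup":
        merged: list[tuple[float, float]] = [units[0]]
        for a, b in units[1:]:
            if a - merged[-1][1] < cfg.merge_gap_s:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        units = merged

    units = [(a, min(b, len(x) / sr)) for a, b in units
             if b - a >= cfg.min_duration_s]
    return [
        CallSegment(call_id=f"{recording.source_path or 'rec'}:{i:04d}",
                    onset=a, offset=b, age_mode=age_mode,
                    recording_ref=recording.source_path)
        for i, (a, b) in enumerate(units)
    ]
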