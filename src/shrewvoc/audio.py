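"""WAV I/O and the in-memory recording container.

Recordings are mono, PCM 16-bit on disk (the acquisition format of the
ultrasound recorders: 192-200 kHz sampling), held in memory as float64 in
[-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass
class AudioRecording:
    """A mono recording: samples in [-1, 1] plus its sample rate."""

    samples: np.ndarray
    sample_rate: float
    source_path: str = ""

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise ValueError("recording is empty")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def read_wav(path: str | Path) -> AudioRecording:
    """Read a mono PCM WAV file into floats in [-1, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"WAV file not found: {path}")
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return AudioRecording(samples=samples, sample_rate=float(sr),
                          source_path=str(path))


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """Write floats in [-1, 1] as PCM 16-bit WAV."""
    clipped = np.clip(samples, -1.0, 1.0)
    data = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(Path(path), int(sample_rate), data)
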