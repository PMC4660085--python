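"""Audio containers and PCM16 WAV round-trip.

Waveforms are held as float64 in [-1, 1]; WAV interchange is 16-bit PCM
(RIFF), so a write/read round trip loses at most half a quantization step
(~1.5e-5), well inside the 2^-15 contract asserted in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

_PCM16_SCALE = 32767.0


@dataclass
class AudioClip:
    """A mono waveform with its sample rate and corpus identifier."""

    samples: np.ndarray
    sample_rate: int
    id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class Annotation:
    """Label and time interval for one clip (cough vs noncough)."""

    clip_id: str
    label: str  # "cough" | "noncough"
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in ("cough", "noncough"):
            raise ValueError(f"unknown label {self.label!r}")
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError("require 0 <= start_s < end_s")


def write_wav(clip: AudioClip, path: str | Path) -> None:
    """Write a clip as 16-bit PCM WAV, clipping to [-1, 1]."""
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.floor(x * _PCM16_SCALE + 0.5).astype(np.int16)
    wavfile.write(str(path), int(clip.sample_rate), pcm)


def read_wav(path: str | Path, clip_id: str | None = None) -> AudioClip:
    """Read a mono PCM WAV into float64 samples in [-1, 1]."""
    sr, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    if data.dtype == np.int16:
        x = data.astype(np.float64) / _PCM16_SCALE
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        info = np.iinfo(data.dtype)
        x = data.astype(np.float64) / max(abs(info.min), info.max)
    if clip_id is None:
        clip_id = Path(path).stem
    return AudioClip(samples=x, sample_rate=int(sr), id=clip_id)
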