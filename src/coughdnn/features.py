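"""39-D MFCC front end for the acoustic models.

Per frame: pre-emphasis, 25 ms Hamming window at a 10 ms shift, power
spectrum on the next power-of-two FFT, a 40-band triangular mel filterbank
(HTK mel scale, 0..Nyquist), log with a 1e-10 floor, orthonormal DCT-II
keeping c0..c12, and sinusoidal liftering

    c'(n) = (1 + (L/2) sin(n pi / L)) c(n),   L = 22.

First- and second-order regression deltas complete the 39-D vector
[static, delta, delta-delta]. For the neural network the per-frame vectors
are spliced with +-k context frames (edge replication) and standardized with
training-set statistics; the GMM emissions consume the raw 39-D vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft

from .audio import AudioClip

LOG_FLOOR = 1e-10


@dataclass
class FeatureConfig:
    win_s: float = 0.025
    shift_s: float = 0.010
    n_mels: int = 40
    n_ceps: int = 13
    lifter: int = 22
    preemph: float = 0.97
    delta_window: int = 2
    splice_k: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.shift_s <= self.win_s):
            raise ValueError("require 0 < shift_s <= win_s")
        if self.n_ceps > self.n_mels:
            raise ValueError("n_ceps must not exceed n_mels")
        if self.lifter <= 0:
            raise ValueError("lifter L must be positive")

    def win_len(self, sr: int) -> int:
        return int(np.floor(self.win_s * sr + 0.5))

    def shift_len(self, sr: int) -> int:
        return int(np.floor(self.shift_s * sr + 0.5))


@dataclass
class FeatureMatrix:
    """Per-frame feature vectors for one clip."""

    values: np.ndarray  # T x D
    frame_times: np.ndarray  # frame-center times in seconds
    clip_id: str

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def n_frames(n_samples: int, win_len: int, shift_len: int) -> int:
    """Number of full frames: 1 + floor((n - win) / shift)."""
    if n_samples < win_len:
        raise ValueError("clip shorter than one analysis window")
    return 1 + (n_samples - win_len) // shift_len


def preemphasize(clip: AudioClip, alpha: float) -> AudioClip:
    """First-difference high-pass: y[t] = x[t] - alpha x[t-1], y[0] = x[0]."""
    if not (0.0 <= alpha < 1.0):
        raise ValueError("require 0 <= alpha < 1")
    x = clip.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return AudioClip(samples=y, sample_rate=clip.sample_rate, id=clip.id)


def frame_and_window(clip: AudioClip, cfg: FeatureConfig) -> np.ndarray:
    """Slice into overlapping frames and apply a Hamming window.

    Trailing samples that do not fill a window are dropped.
    """
    sr = clip.sample_rate
    wl, sl = cfg.win_len(sr), cfg.shift_len(sr)
    T = n_frames(clip.samples.size, wl, sl)
    idx = np.arange(wl)[None, :] + sl * np.arange(T)[:, None]
    frames = clip.samples[idx]
    return frames * np.hamming(wl)


def mel_filterbank(n_mels: int, n_fft: int, sr: int) -> np.ndarray:
    """Triangular filters on the HTK mel scale, spanning 0..Nyquist.

    Returns an (n_mels, n_fft//2 + 1) weight matrix; each filter is
    nonnegative and peaks at its center bin.
    """

    def mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    pts_hz = imel(np.linspace(mel(0.0), mel(sr / 2.0), n_mels + 2))
    bins = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    fb = np.zeros((n_mels, bins.size))
    for m in range(n_mels):
        lo, ctr, hi = pts_hz[m], pts_hz[m + 1], pts_hz[m + 2]
        up = (bins - lo) / max(ctr - lo, 1e-12)
        down = (hi - bins) / max(hi - ctr, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_power(frames: np.ndarray, cfg: FeatureConfig, sr: int) -> np.ndarray:
    """Log mel-filterbank energies of windowed frames (floored at 1e-10)."""
    wl = frames.shape[1]
    n_fft = 1 << (wl - 1).bit_length()
    power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(cfg.n_mels, n_fft, sr)
    return np.log(np.maximum(power @ fb.T, LOG_FLOOR))


def dct_lifter(log_mel: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Orthonormal DCT-II to cepstra c0..c12, then sinusoidal liftering."""
    ceps = dct(log_mel, type=2, norm="ortho", axis=1)[:, : cfg.n_ceps]
    n = np.arange(cfg.n_ceps)
    lift = 1.0 + (cfg.lifter / 2.0) * np.sin(np.pi * n / cfg.lifter)
    return ceps * lift


def add_deltas(static: np.ndarray, delta_window: int = 2) -> np.ndarray:
    """Append regression deltas and delta-deltas: output is T x 3D.

    Delta_t = sum_{d=1..W} d (c_{t+d} - c_{t-d}) / (2 sum d^2), with edge
    frames replicated; the same operator applied twice gives delta-delta.
    """

    def delta(x: np.ndarray) -> np.ndarray:
        W = delta_window
        pad = np.pad(x, ((W, W), (0, 0)), mode="edge")
        denom = 2.0 * sum(d * d for d in range(1, W + 1))
        out = np.zeros_like(x)
        for d in range(1, W + 1):
            out += d * (pad[W + d : W + d + x.shape[0]] - pad[W - d : W - d + x.shape[0]])
        return out / denom

    d1 = delta(static)
    d2 = delta(d1)
    return np.hstack([static, d1, d2])


def splice(feat: np.ndarray, k: int) -> np.ndarray:
    """Concatenate each frame with its +-k neighbours (edge replication)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return feat.copy()
    T = feat.shape[0]
    pad = np.pad(feat, ((k, k), (0, 0)), mode="edge")
    return np.hstack([pad[j : j + T] for j in range(2 * k + 1)])


def mfcc(clip: AudioClip, cfg: FeatureConfig | None = None) -> FeatureMatrix:
    """Full 39-D MFCC pipeline for one clip."""
    cfg = cfg or FeatureConfig()
    emphasized = preemphasize(clip, cfg.preemph)
    frames = frame_and_window(emphasized, cfg)
    log_mel = mel_power(frames, cfg, clip.sample_rate)
    static = dct_lifter(log_mel, cfg)
    values = add_deltas(static, cfg.delta_window)
    sr = clip.sample_rate
    wl, sl = cfg.win_len(sr), cfg.shift_len(sr)
    times = (sl * np.arange(values.shape[0]) + wl / 2.0) / sr
    return FeatureMatrix(values=values, frame_times=times, clip_id=clip.id)


@dataclass
class NormStats:
    """Per-dimension standardization statistics (fitted on training data)."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean is not None


def fit_norm(feats: np.ndarray) -> NormStats:
    """Fit per-dimension mean/std; std floored at 1e-6."""
    mean = feats.mean(axis=0)
    std = np.maximum(feats.std(axis=0), 1e-6)
    return NormStats(mean=mean, std=std)


def apply_norm(feats: np.ndarray, stats: NormStats) -> np.ndarray:
    if not stats.fitted:
        raise ValueError("NormStats not fitted")
    return (feats - stats.mean) / stats.std


def invert_norm(feats: np.ndarray, stats: NormStats) -> np.ndarray:
    if not stats.fitted:
        raise ValueError("NormStats not fitted")
    return feats * stats.std + stats.mean
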