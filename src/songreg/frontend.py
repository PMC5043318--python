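"""Acoustic front end: phrase segmentation, onset detection, point processes.

A raw mono recording is segmented into phrases using the long silences that
separate them, syllable onsets are detected as local maxima of the smoothed
amplitude-envelope derivative above a robust (median + k*MAD) threshold, and
each phrase becomes a binary point process sampled at 1000 Hz, aligned so
its first onset sits at time zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, filtfilt, find_peaks, stft

__all__ = [
    "PointProcessPhrase",
    "OnsetCollisionError",
    "segment_phrases",
    "detect_onsets",
    "to_point_process",
    "pitch_trace",
    "read_wav",
    "write_wav",
]


class OnsetCollisionError(ValueError):
    """Two onsets fell on the same point-process sample."""


@dataclass(frozen=True)
class PointProcessPhrase:
    """A phrase as a binary onset train sampled at ``rate`` Hz."""

    phrase_index: int
    onset_times: tuple[float, ...]
    onsets_binary: np.ndarray
    rate: float = 1000.0

    def __post_init__(self) -> None:
        t = np.asarray(self.onset_times)
        if len(t) == 0:
            raise ValueError("a point-process phrase needs at least one onset")
        if t[0] != 0.0:
            raise ValueError("first onset must be aligned to time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("onset times must be strictly increasing")
        b = np.asarray(self.onsets_binary)
        if not np.all((b == 0) | (b == 1)):
            raise ValueError("onsets_binary must be 0/1")
        if int(b.sum()) != len(t):
            raise ValueError("onsets_binary must contain exactly one 1 per onset")
        if b[0] != 1:
            raise ValueError("binary train must start with an onset")


def _envelope(
    x: np.ndarray, sample_rate: float, smooth_ms: float, passes: int = 1
) -> np.ndarray:
    # repeated moving averages (triangular kernel for passes=2) strongly
    # attenuate the 2f rectification ripple of tonal signals
    w = max(1, int(round(smooth_ms * sample_rate / 1000.0)))
    kernel = np.ones(w) / w
    env = np.abs(x)
    for _ in range(passes):
        env = np.convolve(env, kernel, mode="same")
    return env


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def bandpass(
    x: np.ndarray, sample_rate: float, low: float = 500.0, high: float = 3000.0
) -> np.ndarray:
    """Zero-phase band-pass to the song frequency band."""
    nyq = sample_rate / 2.0
    b, a = butter(4, [low / nyq, min(high / nyq, 0.99)], btype="band")
    return filtfilt(b, a, x)


def segment_phrases(
    waveform: np.ndarray,
    sample_rate: float,
    min_pause: float = 1.5,
    smooth_ms: float = 50.0,
    threshold_k: float = 5.0,
    rel_threshold: float = 0.05,
    min_duration: float = 0.05,
) -> list[tuple[float, float]]:
    """Maximal above-noise regions separated by >= ``min_pause`` of silence.

    Returns (start, end) pairs in seconds, in temporal order; an all-silent
    input returns an empty list.
    """
    if min_pause <= 0:
        raise ValueError("min_pause must be positive")
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if len(x) == 0 or np.max(np.abs(x)) == 0:
        return []
    env = _envelope(x, sample_rate, smooth_ms)
    thr = max(
        float(np.median(env)) + threshold_k * _mad(env),
        rel_threshold * float(env.max()),
    )
    active = env > thr
    if not np.any(active):
        return []
    padded = np.concatenate([[False], active, [False]])
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive

    merged: list[list[int]] = []
    gap = int(min_pause * sample_rate)
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    out = [
        (s / sample_rate, e / sample_rate)
        for s, e in merged
        if (e - s) / sample_rate >= min_duration
    ]
    return out


def detect_onsets(
    waveform: np.ndarray,
    sample_rate: float,
    smooth_ms: float = 10.0,
    threshold_k: float = 5.0,
    min_separation_ms: float = 20.0,
    apply_bandpass: bool = False,
    rel_floor: float = 0.2,
) -> np.ndarray:
    """Syllable-onset times (seconds) from an amplitude-envelope derivative.

    The signal is peak-normalized (making detection invariant to global
    amplitude scaling), optionally band-passed to 0.5-3 kHz, rectified and
    smoothed with two ``smooth_ms`` moving-average passes; onsets are local
    maxima of the envelope derivative exceeding both
    median + ``threshold_k`` * MAD and ``rel_floor`` times the largest
    derivative peak.
    """
    if smooth_ms <= 0:
        raise ValueError("smooth_ms must be positive")
    x = np.asarray(waveform, dtype=float)
    if len(x) == 0:
        raise ValueError("empty signal")
    peak = np.max(np.abs(x))
    if peak == 0:
        return np.empty(0)
    x = x / peak
    if apply_bandpass:
        x = bandpass(x, sample_rate)
    env = _envelope(x, sample_rate, smooth_ms, passes=2)
    deriv = np.gradient(env) * sample_rate
    thr = float(np.median(deriv)) + threshold_k * _mad(deriv)
    height = max(thr, rel_floor * float(deriv.max(initial=0.0)), 1e-9)
    distance = max(1, int(round(min_separation_ms * sample_rate / 1000.0)))
    peaks, _ = find_peaks(deriv, height=height, distance=distance)
    return peaks / sample_rate


def to_point_process(
    onset_times: np.ndarray, rate: float = 1000.0, phrase_index: int = 1
) -> PointProcessPhrase:
    """Binarize onset times at ``rate`` Hz, aligned to the first onset.

    Raises :class:`OnsetCollisionError` if two onsets round to the same
    sample (lower the jitter or raise the rate).
    """
    t = np.asarray(onset_times, dtype=float)
    if len(t) == 0:
        raise ValueError("onset_times must be non-empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("onset_times must be strictly increasing")
    shifted = t - t[0]
    idx = np.round(shifted * rate).astype(np.int64)
    if len(np.unique(idx)) != len(idx):
        raise OnsetCollisionError(
            f"two onsets fall on the same {1000.0 / rate:.3g} ms sample"
        )
    binary = np.zeros(int(idx[-1]) + 1, dtype=np.uint8)
    binary[idx] = 1
    return PointProcessPhrase(
        phrase_index=phrase_index,
        onset_times=tuple(float(x) for x in shifted),
        onsets_binary=binary,
        rate=rate,
    )


def pitch_trace(
    waveform: np.ndarray, sample_rate: float, frame_ms: float = 10.0
) -> np.ndarray:
    """Per-frame dominant frequency (Hz) — presentation aid for raster plots."""
    nper = max(16, int(round(frame_ms * sample_rate / 1000.0)))
    f, _, z = stft(np.asarray(waveform, dtype=float), fs=sample_rate, nperseg=nper)
    mag = np.abs(z)
    return f[np.argmax(mag, axis=0)]


def read_wav(path: str | os.PathLike) -> tuple[np.ndarray, int]:
    """Read a WAV file as a mono float array in [-1, 1]."""
    sr, data = wavfile.read(path)
    x = np.asarray(data)
    if x.ndim > 1:
        x = x.mean(axis=1)
    if np.issubdtype(x.dtype, np.integer):
        x = x / float(np.iinfo(data.dtype).max)
    return x.astype(float), int(sr)


def write_wav(path: str | os.PathLike, waveform: np.ndarray, sample_rate: int) -> Path:
    """Write a mono float waveform as 16-bit PCM WAV."""
    path = Path(path)
    x = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(x)) if len(x) else 0.0
    if peak > 1.0:
        x = x / peak
    wavfile.write(path, sample_rate, (x * 32767).astype(np.int16))
    return path
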