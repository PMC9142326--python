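"""Audio ingestion and preprocessing.

Covers the front end of the evaluation pipeline: reading PCM WAV files into
a normalized mono :class:`AudioSignal`, DC removal, SNR-controlled noise
superposition, framing, and energy-based extraction of the voiced ("useful
information") segments that carry the sung material.

Sample indexing is 0-based throughout; segment intervals are half-open
``[start, end)`` in samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import DegenerateInputError, InputFormatError, ParameterError

_WINDOWS = ("none", "hamming", "hann")


@dataclass(frozen=True)
class AudioSignal:
    """A sampled mono waveform.

    samples
        Amplitudes, dimensionless, nominally in [-1, 1].
    sample_rate
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if samples.ndim != 1 or samples.size < 1:
            raise ParameterError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ParameterError("samples must be finite (no NaN/Inf)")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class FrameSequence:
    """Fixed-length analysis frames cut from a signal.

    ``frames`` holds the tapered frames (slice times window weight);
    ``raw_frames`` the untapered slices, kept so that window-weighted
    energies can be formed as sum(x^2 * w) rather than sum((x*w)^2).
    """

    frames: np.ndarray          # (n_frames, frame_length), tapered
    raw_frames: np.ndarray      # (n_frames, frame_length), verbatim slices
    frame_length: int
    hop: int
    start_offsets: np.ndarray   # (n_frames,) 0-based sample indices
    window_id: str
    window: np.ndarray          # (frame_length,) taper weights
    sample_rate: int

    def __post_init__(self) -> None:
        if self.frame_length < 2:
            raise ParameterError("frame_length must be >= 2")
        if self.hop < 1:
            raise ParameterError("hop must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_centers(self) -> np.ndarray:
        """Center of each frame in seconds."""
        return (self.start_offsets + self.frame_length / 2.0) / self.sample_rate


@dataclass(frozen=True)
class SegmentList:
    """Sorted, non-overlapping half-open voiced intervals in samples."""

    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.segments:
            if end <= start:
                raise ParameterError(f"empty segment ({start}, {end})")
            if start < prev_end:
                raise ParameterError("segments overlap or are unsorted")
            prev_end = end

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def contains(self, sample_index: float) -> bool:
        return any(start <= sample_index < end for start, end in self.segments)

    def total_samples(self) -> int:
        return sum(end - start for start, end in self.segments)


def read_wav(path) -> AudioSignal:
    """Read a PCM WAV file as a mono signal scaled to [-1, 1].

    Multichannel input is downmixed by averaging channels.  Integer PCM is
    scaled by the full-scale value of its dtype; float PCM is taken as-is.
    """
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise InputFormatError(f"cannot read WAV file {path!r}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise InputFormatError(f"unsupported WAV sample format {data.dtype} in {path!r}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, sample_rate=int(rate))


def write_wav(path, signal: AudioSignal) -> None:
    """Write a signal as 16-bit PCM WAV (values clipped to [-1, 1])."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, signal.sample_rate, pcm)


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Polyphase resampling to ``target_rate`` Hz."""
    if target_rate <= 0:
        raise ParameterError("target_rate must be positive")
    if target_rate == signal.sample_rate:
        return signal
    g = np.gcd(int(target_rate), int(signal.sample_rate))
    out = resample_poly(signal.samples, target_rate // g, signal.sample_rate // g)
    return AudioSignal(samples=out, sample_rate=int(target_rate))


def remove_dc(signal: AudioSignal) -> AudioSignal:
    """Subtract the arithmetic mean, leaving a zero-mean signal.

    Idempotent; length and rate are unchanged.
    """
    return AudioSignal(samples=signal.samples - signal.samples.mean(),
                       sample_rate=signal.sample_rate)


def add_noise_at_snr(signal: AudioSignal, snr_db: float, seed: int) -> AudioSignal:
    """Superimpose white Gaussian noise at an exact signal-to-noise ratio.

    The generated noise realization is rescaled so that the *realized*
    10*log10(P_signal / P_noise) equals ``snr_db`` to float precision.
    Deterministic for a fixed seed.
    """
    if not np.isfinite(snr_db):
        raise ParameterError("snr_db must be finite")
    p_signal = float(np.mean(signal.samples ** 2))
    if p_signal == 0.0:
        raise DegenerateInputError("zero-power signal: SNR is undefined")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(signal.samples.size)
    p_noise_target = p_signal / 10.0 ** (snr_db / 10.0)
    noise *= np.sqrt(p_noise_target / np.mean(noise ** 2))
    return AudioSignal(samples=signal.samples + noise, sample_rate=signal.sample_rate)


def window_weights(window_id: str, frame_length: int) -> np.ndarray:
    if window_id not in _WINDOWS:
        raise ParameterError(f"unknown window {window_id!r}; expected one of {_WINDOWS}")
    if window_id == "hamming":
        return np.hamming(frame_length)
    if window_id == "hann":
        return np.hanning(frame_length)
    return np.ones(frame_length)


def frame_signal(signal: AudioSignal, frame_length: int, hop: int,
                 window_id: str = "none") -> FrameSequence:
    """Cut a signal into overlapping fixed-length frames.

    The number of frames is floor((N - frame_length) / hop) + 1; trailing
    samples that do not fill a frame are dropped.
    """
    n = signal.samples.size
    if frame_length > n:
        raise ParameterError(
            f"frame_length {frame_length} exceeds signal length {n}: no frames")
    if hop < 1:
        raise ParameterError("hop must be >= 1")
    n_frames = (n - frame_length) // hop + 1
    starts = np.arange(n_frames) * hop
    idx = starts[:, None] + np.arange(frame_length)[None, :]
    raw = signal.samples[idx]
    window = window_weights(window_id, frame_length)
    return FrameSequence(frames=raw * window, raw_frames=raw,
                         frame_length=frame_length, hop=hop,
                         start_offsets=starts, window_id=window_id,
                         window=window, sample_rate=signal.sample_rate)


def extract_voiced_segments(signal: AudioSignal,
                            energy_threshold_fraction: float = 0.05,
                            min_segment_ms: float = 50.0,
                            frame_length: int | None = None,
                            hop: int | None = None) -> SegmentList:
    """Find the voiced / useful segments of a recording by energy gating.

    Frames whose short-time energy exceeds ``energy_threshold_fraction``
    times the maximum frame energy are flagged; maximal runs of flagged
    frames become segments, runs shorter than ``min_segment_ms`` are
    discarded, and sample intervals that overlap (because frames overlap)
    are merged.  A silent signal yields an empty list.
    """
    if energy_threshold_fraction <= 0 or min_segment_ms <= 0:
        raise ParameterError("thresholds must be positive")
    if frame_length is None:
        frame_length = max(2, round(0.040 * signal.sample_rate))
    if hop is None:
        hop = max(1, round(0.010 * signal.sample_rate))
    if frame_length > signal.samples.size:
        frame_length = signal.samples.size
        hop = max(1, min(hop, frame_length))
    frames = frame_signal(signal, frame_length, hop, "none")
    energy = np.sum(frames.raw_frames ** 2, axis=1)
    peak = energy.max()
    if peak == 0.0:
        return SegmentList([])
    active = energy > energy_threshold_fraction * peak
    min_samples = min_segment_ms * 1e-3 * signal.sample_rate

    intervals: list[tuple[int, int]] = []
    run_start = None
    padded = np.concatenate([active, [False]])
    for i, flag in enumerate(padded):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            start = int(frames.start_offsets[run_start])
            end = int(min(frames.start_offsets[i - 1] + frame_length,
                          signal.samples.size))
            if end - start >= min_samples:
                intervals.append((start, end))
            run_start = None

    merged: list[tuple[int, int]] = []
    for start, end in intervals:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return SegmentList(merged)
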