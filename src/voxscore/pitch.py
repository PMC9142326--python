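"""Pitch-period detection and fundamental-frequency perturbation (jitter).

The detector follows the wavelet-assisted scheme: the signal is rebuilt
from the approximation (low-frequency) coefficients of a multilevel DWT,
suppressing harmonics and noise above ~1 kHz; each analysis frame is then
center-clipped and its normalized autocorrelation searched for a peak in
the admissible lag range.  The peak lag, refined by parabolic
interpolation, gives the pitch period; the normalized peak height gates
the voiced/unvoiced decision.

Jitter is the mean absolute difference of successive pitch periods,

    Jitter = (1 / (N-1)) * sum_{i=2}^{N} | 1/F0_i - 1/F0_{i-1} |   [seconds]

computed here over the per-frame F0 estimates of the longest voiced run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .config import RunConfig
from .errors import InsufficientDataError, ParameterError
from .signal_io import AudioSignal, frame_signal

# Periodization mode keeps the DWT orthogonal, so reconstruction from the
# approximation band alone is an exact projection (and thus idempotent).
_DWT_MODE = "periodization"


@dataclass(frozen=True)
class PitchTrack:
    """Per-frame voicing flags and pitch estimates.

    ``period`` and ``f0`` are NaN on unvoiced frames; on voiced frames
    f0 = 1 / period exactly.
    """

    frame_times: np.ndarray  # seconds, frame centers
    voiced: np.ndarray       # bool per frame
    period: np.ndarray       # seconds, NaN where unvoiced
    f0: np.ndarray           # Hz, NaN where unvoiced

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]

    def longest_voiced_run(self) -> np.ndarray:
        """Indices of the longest consecutive run of voiced frames."""
        best_start, best_len = 0, 0
        start = None
        padded = np.concatenate([self.voiced, [False]])
        for i, flag in enumerate(padded):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if i - start > best_len:
                    best_start, best_len = start, i - start
                start = None
        return np.arange(best_start, best_start + best_len)

    def to_frame(self):
        """Export as a pandas DataFrame with columns time_s, voiced, f0_hz."""
        import pandas as pd

        return pd.DataFrame({"time_s": self.frame_times,
                             "voiced": self.voiced,
                             "f0_hz": self.f0})


def dwt_reconstruct_lowband(signal: AudioSignal, wavelet_id: str = "db4",
                            level: int = 3) -> AudioSignal:
    """Reconstruct a signal from its DWT approximation coefficients only.

    All detail coefficients of a ``level``-deep decomposition are zeroed
    before inverse transform, leaving content below roughly
    sample_rate / 2^(level+1) Hz.  Output has the same length and rate.
    """
    if level < 1:
        raise ParameterError("level must be >= 1")
    n = signal.samples.size
    if 2 ** level >= n:
        raise ParameterError(
            f"decomposition level {level} too deep for signal of length {n}")
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet_id).dec_len)
    if level > max_level:
        raise ParameterError(
            f"level {level} exceeds maximum {max_level} for length {n}")
    coeffs = pywt.wavedec(signal.samples, wavelet_id, mode=_DWT_MODE, level=level)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wavelet_id, mode=_DWT_MODE)[:n]
    return AudioSignal(samples=out, sample_rate=signal.sample_rate)


def center_clip(frame: np.ndarray, clip_ratio: float) -> np.ndarray:
    """Center-clip a frame at CL = clip_ratio * max|frame|.

    Samples above CL are shifted down by CL, samples below -CL shifted up
    by CL, and everything in between is zeroed.  Sharpening the waveform
    this way strips formant structure and makes the autocorrelation pitch
    peak stand out.
    """
    if not 0 < clip_ratio < 1:
        raise ParameterError("clip_ratio must be in (0, 1)")
    frame = np.asarray(frame, dtype=np.float64)
    cl = clip_ratio * np.max(np.abs(frame)) if frame.size else 0.0
    out = np.zeros_like(frame)
    above = frame > cl
    below = frame < -cl
    out[above] = frame[above] - cl
    out[below] = frame[below] + cl
    return out


# a shorter lag is preferred over a longer one whose autocorrelation peak
# is at most this much higher (guards against octave-down errors when
# r(2T) ~= r(T) on nearly periodic frames)
_TIE_TOLERANCE = 0.02


def _normalized_autocorr(frame: np.ndarray) -> np.ndarray | None:
    r = np.correlate(frame, frame, mode="full")[frame.size - 1:]
    if r[0] <= 0.0:
        return None
    return r / r[0]


def _sinc_refine(values: np.ndarray, lag: int, span: float = 2.0,
                 half_width: int = 10,
                 resolution: float = 1.0 / 128.0) -> tuple[float, float]:
    """Continuous peak position and height near ``lag`` by band-limited
    (sinc) interpolation of the autocorrelation sequence."""
    lo = max(half_width, int(np.floor(lag - span)))
    hi = min(values.size - 1 - half_width, int(np.ceil(lag + span)))
    if hi <= lo:
        return float(lag), float(values[lag]) if lag < values.size else 0.0
    taus = np.arange(lo, hi + resolution, resolution)
    k = np.arange(-half_width, half_width + 1)
    idx = np.round(taus)[:, None].astype(int) + k[None, :]
    weights = np.sinc(taus[:, None] - idx)
    interp = np.sum(values[idx] * weights, axis=1)
    best = int(np.argmax(interp))
    return float(taus[best]), float(interp[best])


def autocorr_pitch_period(frame: np.ndarray, sample_rate: int,
                          f_min: float = 80.0, f_max: float = 1000.0,
                          voicing_ratio_threshold: float = 0.30,
                          clip_ratio: float = 0.68,
                          refine_frame: np.ndarray | None = None) -> float | None:
    """Estimate the pitch period of one frame, or ``None`` if unvoiced.

    The frame is center-clipped, its normalized autocorrelation r(l)/r(0)
    evaluated over lags [sample_rate/f_max, sample_rate/f_min], and the
    best peak accepted when it reaches ``voicing_ratio_threshold``.
    Among peaks within a small tolerance of the maximum the smallest lag
    (highest F0) wins, which avoids octave-down errors.  The integer lag
    is then refined to sub-sample precision by sinc interpolation of the
    autocorrelation — of ``refine_frame`` when given (e.g. the unfiltered
    frame, whose autocorrelation is free of wavelet-band aliasing), else
    of the clipped frame itself.
    """
    if f_min >= f_max:
        raise ParameterError("f_min must be < f_max")
    frame = np.asarray(frame, dtype=np.float64)
    clipped = center_clip(frame, clip_ratio)
    norm = _normalized_autocorr(clipped)
    if norm is None:
        return None
    lag_min = max(1, int(np.ceil(sample_rate / f_max)))
    lag_max = min(frame.size - 1, int(np.floor(sample_rate / f_min)))
    if lag_max < lag_min:
        return None
    search = norm[lag_min:lag_max + 1]
    peak_value = float(search.max())
    if peak_value < voicing_ratio_threshold:
        return None
    # local maxima of the search range (flat interior counts once)
    interior = np.flatnonzero((search[1:-1] >= search[:-2])
                              & (search[1:-1] > search[2:])) + 1
    candidates = interior[search[interior] >= peak_value - _TIE_TOLERANCE]
    if candidates.size == 0:
        candidates = np.array([int(np.argmax(search))])
    lag = lag_min + int(candidates[0])  # smallest qualifying lag

    if refine_frame is not None:
        refine_norm = _normalized_autocorr(np.asarray(refine_frame, dtype=np.float64))
        if refine_norm is None:
            refine_norm = norm
    else:
        refine_norm = norm
    # Sub-multiple verification: reconstruction from the approximation band
    # alone leaves aliased components that can suppress the true-period
    # peak, landing the low-band candidate an octave (or more) low.  Test
    # lag/d on the refinement autocorrelation and keep the smallest
    # sub-multiple whose peak is competitive with the best one.
    candidates: list[tuple[float, float]] = []
    for divisor in (1, 2, 3, 4, 5, 6):
        cand = lag / divisor
        if cand < lag_min - 0.5:
            continue
        tau, value = _sinc_refine(refine_norm, int(round(cand)))
        candidates.append((tau, value))
    best_value = max(v for _, v in candidates)
    lag_refined = min(tau for tau, v in candidates
                      if v >= best_value - _TIE_TOLERANCE)
    period = lag_refined / sample_rate
    # keep the estimate inside the admissible band after refinement
    period = float(np.clip(period, 1.0 / f_max, 1.0 / f_min))
    return period


def extract_pitch_track(signal: AudioSignal, config: RunConfig | None = None) -> PitchTrack:
    """Run the full frame-based pitch detector over a (DC-free) signal.

    Detection runs on the wavelet low-band reconstruction; the sub-sample
    refinement of each detected period uses the corresponding full-band
    frame.
    """
    if config is None:
        config = RunConfig(sample_rate=signal.sample_rate)
    level = config.resolved_dwt_level()
    low = dwt_reconstruct_lowband(signal, config.wavelet, level)
    frames = frame_signal(low, config.frame_length, config.hop, "none")
    raw_frames = frame_signal(signal, config.frame_length, config.hop, "none")
    n = frames.n_frames
    voiced = np.zeros(n, dtype=bool)
    period = np.full(n, np.nan)
    for i in range(n):
        p = autocorr_pitch_period(frames.raw_frames[i], signal.sample_rate,
                                  config.f_min, config.f_max,
                                  config.voicing_threshold, config.clip_ratio,
                                  refine_frame=raw_frames.raw_frames[i])
        if p is not None:
            voiced[i] = True
            period[i] = p
    f0 = np.where(voiced, 1.0 / period, np.nan)
    return PitchTrack(frame_times=frames.frame_centers(), voiced=voiced,
                      period=period, f0=f0)


def perturbation(values: np.ndarray) -> float:
    """Mean absolute successive difference of reciprocals: the common core
    of jitter and formant perturbation.

    For a sequence F_1..F_N (Hz) returns
    (1/(N-1)) * sum |1/F_i - 1/F_{i-1}|.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise InsufficientDataError(
            f"perturbation needs >= 2 values, got {values.size}")
    if np.any(values <= 0):
        raise ParameterError("frequencies must be positive")
    periods = 1.0 / values
    return float(np.mean(np.abs(np.diff(periods))))


def jitter(track: PitchTrack) -> float:
    """Fundamental-frequency perturbation, in seconds, over the longest
    voiced run of the track."""
    run = track.longest_voiced_run()
    if run.size < 2:
        raise InsufficientDataError(
            "jitter needs at least 2 consecutive voiced frames")
    return perturbation(track.f0[run])
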