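"""AR-model formant extraction, formant perturbation, and short-time energy.

Formants are estimated per voiced frame by fitting an all-pole (AR / LPC)
model with the autocorrelation method and reading resonance frequencies off
the complex pole pairs: a pole at radius r and angle w maps to frequency
w * fs / (2*pi) and 3-dB bandwidth -fs/pi * ln(r).  Candidates outside
(90 Hz, nyquist - 50 Hz) or broader than 700 Hz are rejected as non-formant
poles (DC / glottal-tilt and noise poles).  The first and third surviving
resonances are F1 and F3.

Short-time energy of frame n is  E_n = sum_k x^2(k) * w(n - k),  the
window-weighted sum of squared samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz

from .config import RunConfig
from .errors import (DegenerateInputError, InsufficientDataError,
                     MissingFormantError, ParameterError)
from .pitch import PitchTrack, perturbation
from .signal_io import AudioSignal, FrameSequence, SegmentList, frame_signal


@dataclass(frozen=True)
class FormantTrack:
    """Per-frame first and third formant frequencies (Hz).

    Only frames with a full set of qualifying resonances are retained, so
    the arrays may be shorter than the pitch track.
    """

    frame_times: np.ndarray
    f1: np.ndarray
    f3: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.frame_times,
                             "f1_hz": self.f1, "f3_hz": self.f3})


@dataclass(frozen=True)
class EnergyTrack:
    """Per-frame short-time energy (window-weighted sum of squares)."""

    frame_times: np.ndarray
    energy: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.frame_times, "energy": self.energy})


def ar_coefficients(frame: np.ndarray, order: int) -> np.ndarray:
    """Fit an order-p AR model by the autocorrelation (Yule-Walker) method.

    Returns predictor coefficients a_1..a_p in the convention

        x[n] = a_1 x[n-1] + ... + a_p x[n-p] + e[n],

    i.e. the all-pole filter is 1 / (1 - sum a_k z^-k).  The
    autocorrelation method guarantees a stable model.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if order < 2:
        raise ParameterError("order must be >= 2")
    if frame.size <= order:
        raise ParameterError(
            f"frame length {frame.size} must exceed order {order}")
    if not np.any(frame):
        raise DegenerateInputError("all-zero frame: AR model undefined")
    r = np.correlate(frame, frame, mode="full")[frame.size - 1:frame.size + order]
    r = r / frame.size
    # tiny diagonal loading guards against a numerically singular Toeplitz
    # system on near-degenerate frames (e.g. pure sinusoids)
    r0 = r[0] * (1.0 + 1e-9)
    a = solve_toeplitz((np.r_[r0, r[1:order]], np.r_[r0, r[1:order]]), r[1:order + 1])
    return np.asarray(a, dtype=np.float64)


def prediction_error(frame: np.ndarray, coeffs: np.ndarray) -> float:
    """Prediction-error power of an AR fit in the autocorrelation domain,
    E_p = r(0) - sum_k a_k r(k); non-increasing in model order."""
    frame = np.asarray(frame, dtype=np.float64)
    p = coeffs.size
    r = np.correlate(frame, frame, mode="full")[frame.size - 1:frame.size + p]
    r = r / frame.size
    return float(r[0] - np.dot(coeffs, r[1:p + 1]))


def formant_peaks(ar_coeffs: np.ndarray, sample_rate: int,
                  f_low: float = 90.0, f_high_margin: float = 50.0,
                  max_bandwidth: float = 700.0) -> np.ndarray:
    """Resonance frequencies (Hz, ascending) of a stable AR model.

    Keeps one frequency per complex-conjugate pole pair with frequency in
    (f_low, nyquist - f_high_margin) and bandwidth below ``max_bandwidth``.
    Raises :class:`MissingFormantError` when fewer than three qualify.
    """
    ar_coeffs = np.asarray(ar_coeffs, dtype=np.float64)
    poly = np.concatenate([[1.0], -ar_coeffs])
    roots = np.roots(poly)
    roots = roots[np.imag(roots) > 0]  # one per conjugate pair
    freqs = np.angle(roots) * sample_rate / (2.0 * np.pi)
    radii = np.abs(roots)
    with np.errstate(divide="ignore"):
        bandwidths = -sample_rate / np.pi * np.log(radii)
    nyquist = sample_rate / 2.0
    keep = ((freqs > f_low) & (freqs < nyquist - f_high_margin)
            & (bandwidths < max_bandwidth))
    candidates = np.sort(freqs[keep])
    if candidates.size < 3:
        raise MissingFormantError(
            f"only {candidates.size} qualifying resonances (need >= 3)")
    return candidates


def preemphasize(samples: np.ndarray, coefficient: float = 0.97) -> np.ndarray:
    """First-order high-pass y[n] = x[n] - c*x[n-1], flattening the glottal
    spectral tilt before AR fitting."""
    samples = np.asarray(samples, dtype=np.float64)
    out = samples.copy()
    out[1:] -= coefficient * samples[:-1]
    return out


def extract_formant_track(signal: AudioSignal, pitch: PitchTrack,
                          config: RunConfig | None = None) -> FormantTrack:
    """Estimate F1 and F3 on every voiced frame of ``pitch``.

    The signal is downsampled to the formant analysis rate (so the AR
    poles concentrate on the formant band rather than the empty top
    octave), pre-emphasized, framed on the same time grid as the pitch
    track, and each voiced frame is Hamming-windowed and fit with an AR
    model.  Frames without three qualifying resonances are dropped.
    """
    from .signal_io import resample  # local import avoids cycle at module load

    if config is None:
        config = RunConfig(sample_rate=signal.sample_rate)
    if not np.any(pitch.voiced):
        raise InsufficientDataError("no voiced frames: cannot extract formants")
    fs = config.formant_sample_rate
    analysed = resample(signal, fs) if fs != signal.sample_rate else signal
    emphasized = AudioSignal(
        samples=preemphasize(analysed.samples, config.preemphasis)
        if config.preemphasis else analysed.samples.copy(),
        sample_rate=fs)
    frame_length = max(2, round(config.frame_ms * 1e-3 * fs))
    hop = max(1, round(config.hop_ms * 1e-3 * fs))
    frames = frame_signal(emphasized, frame_length, hop, "hamming")
    order = config.resolved_lpc_order()
    times, f1s, f3s = [], [], []
    n = min(frames.n_frames, pitch.n_frames)
    centers = frames.frame_centers()
    for i in range(n):
        if not pitch.voiced[i]:
            continue
        frame = frames.frames[i]
        if not np.any(frame):
            continue
        try:
            coeffs = ar_coefficients(frame, order)
            peaks = formant_peaks(coeffs, fs)
        except (DegenerateInputError, MissingFormantError):
            continue
        times.append(centers[i])
        f1s.append(peaks[0])
        f3s.append(peaks[2])
    if not times:
        raise InsufficientDataError("no frame yielded a full formant set")
    return FormantTrack(frame_times=np.asarray(times),
                        f1=np.asarray(f1s), f3=np.asarray(f3s))


def formant_perturbation(values: np.ndarray) -> float:
    """Mean absolute successive difference of reciprocal formant
    frequencies (units 1/Hz), exactly parallel to jitter."""
    return perturbation(values)


def short_time_energy(frames: FrameSequence) -> EnergyTrack:
    """Short-time energy per frame: sum of sample^2 * window weight."""
    if frames.n_frames == 0:
        raise InsufficientDataError("no frames")
    energy = np.sum(frames.raw_frames ** 2 * frames.window[None, :], axis=1)
    return EnergyTrack(frame_times=frames.frame_centers(), energy=energy)


def mean_energy(track: EnergyTrack, segments: SegmentList,
                sample_rate: int) -> float:
    """Mean frame energy over frames whose centers fall inside voiced
    segments."""
    centers = track.frame_times * sample_rate
    mask = np.array([segments.contains(c) for c in centers])
    if not mask.any():
        raise InsufficientDataError("no frame centers inside voiced segments")
    return float(track.energy[mask].mean())
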