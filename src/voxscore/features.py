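"""Semitone pitch-range statistics and assembly of the 8-parameter
feature vector.

Pitch is mapped to a logarithmic semitone scale,

    D = 12 * log2(F / F_ref)        ["degrees"],

and the sound range (domain width) of a performance is four population
standard deviations of its D values, S = 4*sigma.  Since S depends only on
the spread of D, the reference frequency F_ref (default A4 = 440 Hz) does
not affect it.

The evaluation feature vector, in fixed order:
    F1 (Hz), F3 (Hz), F0 (Hz), range width S (degrees), jitter (s),
    F1 perturbation (1/Hz), F3 perturbation (1/Hz), mean energy.
Min-max normalization to [0, 1] makes the features commensurate before
they enter the scorer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .errors import InsufficientDataError, ParameterError
from .pitch import PitchTrack, extract_pitch_track, jitter
from .signal_io import AudioSignal, SegmentList, extract_voiced_segments, frame_signal, remove_dc
from .spectral import (EnergyTrack, FormantTrack, extract_formant_track,
                       formant_perturbation, mean_energy, short_time_energy)

FEATURE_NAMES = ("f1_hz", "f3_hz", "f0_hz", "range_S", "jitter_s",
                 "f1_pert", "f3_pert", "mean_energy")
N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class FeatureVector:
    """The eight evaluation parameters of one recording."""

    f1_hz: float
    f3_hz: float
    f0_hz: float
    range_S: float
    jitter_s: float
    f1_pert: float
    f3_pert: float
    mean_energy: float

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ParameterError("all features must be finite")
        if not self.f1_hz < self.f3_hz:
            raise ParameterError("F1 must be below F3")
        if self.range_S < 0 or self.jitter_s < 0:
            raise ParameterError("range width and jitter must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    @classmethod
    def from_array(cls, values) -> "FeatureVector":
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (N_FEATURES,):
            raise ParameterError(f"expected {N_FEATURES} features, got {values.shape}")
        return cls(**dict(zip(FEATURE_NAMES, values)))


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature training-set minima and maxima for min-max scaling.

    Features whose range collapses (max == min) are flagged degenerate and
    map to 0.5.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maximum < self.minimum):
            raise ParameterError("maximum must be >= minimum per feature")

    @property
    def degenerate(self) -> np.ndarray:
        return self.maximum == self.minimum

    def to_dict(self) -> dict:
        return {"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()}

    @classmethod
    def from_dict(cls, data: dict) -> "NormalizationParams":
        return cls(minimum=np.asarray(data["minimum"], dtype=np.float64),
                   maximum=np.asarray(data["maximum"], dtype=np.float64))


def pitch_to_D(f: float, f_ref: float = 440.0):
    """Semitone (D-value) scale: D = 12 * log2(f / f_ref)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f <= 0) or f_ref <= 0:
        raise ParameterError("frequencies must be positive")
    out = 12.0 * np.log2(f / f_ref)
    return float(out) if out.ndim == 0 else out


def range_statistics(d_values) -> tuple[float, float, float]:
    """Mean, population standard deviation, and domain width S = 4*sigma
    of a sequence of D values."""
    d = np.asarray(d_values, dtype=np.float64)
    if d.size == 0:
        raise InsufficientDataError("range statistics need at least 1 value")
    mean = float(d.mean())
    sigma = float(d.std(ddof=0))  # population SD, per the E[(D - mean)^2] form
    return mean, sigma, 4.0 * sigma


def assemble_features(pitch: PitchTrack, formants: FormantTrack,
                      energy: EnergyTrack, segments: SegmentList,
                      sample_rate: int, f_ref: float = 440.0) -> FeatureVector:
    """Summarize the per-frame tracks of one recording into the fixed
    8-parameter vector.

    F0, F1 and F3 are medians over their tracks (robust to occasional
    octave or peak-picking outliers); the range width comes from the D
    values of all voiced F0 estimates; jitter and the formant
    perturbations are successive-difference statistics on their tracks.
    """
    voiced_f0 = pitch.voiced_f0()
    if voiced_f0.size < 2:
        raise InsufficientDataError(
            "need >= 2 voiced frames for f0/range features")
    if formants.n_frames < 2:
        raise InsufficientDataError(
            "need >= 2 formant frames for formant features")
    _, _, range_s = range_statistics(pitch_to_D(voiced_f0, f_ref))
    return FeatureVector(
        f1_hz=float(np.median(formants.f1)),
        f3_hz=float(np.median(formants.f3)),
        f0_hz=float(np.median(voiced_f0)),
        range_S=range_s,
        jitter_s=jitter(pitch),
        f1_pert=formant_perturbation(formants.f1),
        f3_pert=formant_perturbation(formants.f3),
        mean_energy=mean_energy(energy, segments, sample_rate),
    )


def extract_features(signal: AudioSignal, config: RunConfig | None = None) -> FeatureVector:
    """End-to-end feature extraction for one recording.

    DC removal -> voiced-segment gating -> wavelet low-band pitch tracking
    -> AR formant tracking -> short-time energy -> 8-parameter vector.
    """
    if config is None:
        config = RunConfig(sample_rate=signal.sample_rate)
    clean = remove_dc(signal)
    segments = extract_voiced_segments(
        clean, config.energy_threshold_fraction, config.min_segment_ms,
        config.frame_length, config.hop)
    if len(segments) == 0:
        raise InsufficientDataError("no voiced segments found (silent input?)")
    pitch = extract_pitch_track(clean, config)
    formants = extract_formant_track(clean, pitch, config)
    frames = frame_signal(clean, config.frame_length, config.hop, config.window)
    energy = short_time_energy(frames)
    return assemble_features(pitch, formants, energy, segments,
                             signal.sample_rate, config.f_ref)


def fit_normalization(vectors: list[FeatureVector]) -> NormalizationParams:
    """Capture per-feature min/max over a training set (>= 2 vectors)."""
    if len(vectors) < 2:
        raise InsufficientDataError("normalization needs >= 2 vectors")
    mat = np.stack([v.to_array() for v in vectors])
    return NormalizationParams(minimum=mat.min(axis=0), maximum=mat.max(axis=0))


def apply_normalization(vector: FeatureVector, params: NormalizationParams) -> np.ndarray:
    """Min-max scale a feature vector into [0, 1]^8.

    Out-of-range inputs clamp to [0, 1]; degenerate features map to 0.5.
    """
    x = vector.to_array()
    span = params.maximum - params.minimum
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (x - params.minimum) / span
    scaled = np.where(params.degenerate, 0.5, scaled)
    return np.clip(scaled, 0.0, 1.0)


def invert_normalization(scaled: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map a [0, 1]^8 vector back to feature units (degenerate features
    return their common min=max value)."""
    scaled = np.asarray(scaled, dtype=np.float64)
    return np.where(params.degenerate, params.minimum,
                    params.minimum + scaled * (params.maximum - params.minimum))
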