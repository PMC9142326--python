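# Methods

This note documents the models and procedures voxscore implements, the
defaults it ships with, and the choices made where the method itself is
open-ended.

## The evaluation pipeline

A monophonic recording of sustained singing is reduced to eight acoustic
parameters and mapped to a 10-point quality score:

1. **Preprocessing** — the signal is downmixed to mono, resampled to the
   analysis rate, and its arithmetic mean is subtracted (DC removal).
   Useful (voiced) segments are found by short-time energy gating.
2. **Pitch tracking** — a wavelet low-band reconstruction suppresses
   content above ~1 kHz; each frame is center-clipped and its normalized
   autocorrelation searched for the pitch period.
3. **Formant tracking** — each voiced frame is fit with an all-pole (LPC)
   model; resonance frequencies are read off the pole angles. F1 and F3
   summarize vocal-tract configuration.
4. **Feature assembly** — medians of F0/F1/F3, the semitone range width,
   jitter, the two formant perturbations and mean short-time energy form
   the feature vector, min-max normalized to [0, 1].
5. **Scoring** — an 8–25–1 multilayer perceptron (tansig hidden layer,
   logsig output) trained by full-batch backpropagation against
   reference scores on a 10-point scale; a score above 6 counts as
   "good", otherwise "poor".

## Definitions

- Semitone (D-value) scale: `D = 12·log2(F / F_ref)`, `F_ref = 440 Hz`
  (A4). The range width is `S = 4σ`, with σ the **population** standard
  deviation of the D values of all voiced frames — the expectation form
  of the definition, not the sample estimator. Because S depends only on
  spread, the choice of `F_ref` does not affect it.
- Jitter (fundamental-frequency perturbation):
  `(1/(N−1)) · Σ |1/F0_i − 1/F0_{i−1}|`, in seconds, over the longest
  voiced run of per-frame F0 estimates. The same statistic applied to the
  F1 and F3 tracks gives the formant perturbations (units 1/Hz). The
  statistic is absolute, not normalized by the mean period.
- Short-time energy: `E_n = Σ x²(k)·w(n−k)` — the window weights multiply
  the *squared* samples. Mean energy averages frames whose centers fall in
  voiced segments.

## Signal-analysis parameters

| parameter | default | rationale |
|---|---|---|
| sample rate | 16 kHz | covers F0 to 1 kHz and F3 to ~4 kHz |
| frame / hop | 40 ms / 10 ms | ≥ 3 pitch periods at 80 Hz |
| F0 search band | 80–1000 Hz | bass through soprano |
| wavelet / level | db4, `floor(log2(fs/2/1000))` | narrowest approximation band containing 0–1 kHz (level 3 at 16 kHz) |
| center-clip ratio | 0.68 | classic clipping level |
| voicing threshold | 0.30 | on the normalized autocorrelation peak |
| formant analysis rate | 8 kHz | see below |
| LPC order | 2 + fs/1000 at the analysis rate (10 at 8 kHz) | standard rule |
| pre-emphasis | 1 − 0.97 z⁻¹ | flattens glottal tilt before LPC (switchable) |
| formant acceptance | f ∈ (90 Hz, Nyquist − 50 Hz), bandwidth < 700 Hz | rejects DC/tilt and noise poles |
| VAD | energy > 0.05 × max frame energy, runs ≥ 50 ms | simple energy gate |

### Why pitch refinement uses the full-band frame

Reconstructing from approximation coefficients alone zeroes the detail
channels of the wavelet filter bank, which also removes the terms that
cancel decimation aliasing. Harmonics near the band edge therefore leave
inharmonic alias residues (e.g. an 880 Hz harmonic under a 1 kHz edge
aliases to 1120 Hz) that flatten the true-period autocorrelation peak,
bias the peak position by up to ~1%, and can make the double-period peak
the global maximum. The detector therefore picks the coarse peak on the
clipped low-band autocorrelation (robust to formant structure and noise)
but refines it on the unfiltered frame: band-limited sinc interpolation
gives sub-sample period resolution (integer lags alone quantize 800 Hz at
16 kHz to ±2.5%), and a sub-multiple search (lag/d for d = 1…6, smallest
lag within 0.02 of the best normalized peak) resolves octave and deeper
sub-harmonic errors.

### Why formant analysis runs at 8 kHz

With an order-18 model at 16 kHz, half the poles model the energy-poor
3–8 kHz band and the rest lock onto individual harmonics; median F3 error
on synthetic vowels was ~7%. Downsampling to 8 kHz concentrates an
order-10 model on the formant band, giving errors below 2%. Formant
accuracy is ultimately limited by harmonic spacing: a spectral envelope is
only observable at multiples of F0, so F1 estimates at high F0 (above
~200 Hz) are pulled toward the nearest harmonic. This is a property of
all envelope estimators, not of the implementation.

## The scorer

Forward pass: `S_j = Σ w_ij a_i − θ_j`, `b_j = tansig(S_j)`;
`L = Σ v_j b_j − γ`, `C = logsig(L)`; score `= 10·C`. Training is plain
full-batch gradient descent on the MSE between C and score/10 (targets
clamped to [0.05, 0.95] to stay in logsig's open range); no momentum, no
adaptive rates, no regularization. Defaults: 25 hidden units (14 is a
documented alternative), learning rate 0.5 (sensible range 0.01–0.8),
stop at MSE ≤ 0.001 or 2000 epochs.

Weights and thresholds initialize uniformly in **(−1, 1)**. An
all-positive [0, 1] init (available via `init_low`/`init_high`) drives the
initial hidden weighted sums deep into tansig saturation, where the
gradient nearly vanishes; empirically it stalls a sizeable fraction of
runs at a large training error, which is precisely the failure mode the
near-zero-initial-output argument for symmetric init predicts. The
symmetric default converged on every seed tested.

Evaluation protocol: 6 good + 6 poor samples (subjective label: score
> 6 is good) are drawn at random for training; normalization is fitted on
the training set only; the remaining samples are scored and accuracy is
the fraction of test samples whose objective label matches the subjective
one.

## The synthetic-voice generator

No public corpus accompanies the method, so all validation runs on a
source-filter generator with exact ground truth:

- **Source** — a band-limited sawtooth-like pulse train (harmonics to
  Nyquist, 1/h rolloff) with per-cycle period
  `(1/f0(t))·(1 + jitter_fraction·ε)`, ε ~ N(0, 1).
- **Filter** — cascaded unity-peak-gain second-order resonators at the
  specified formant frequencies/bandwidths (defaults 700/1220/2600 Hz —
  an /a/-like configuration).
- **Mixing** — peak-normalized to the target amplitude, plus optional DC
  offset and white Gaussian noise rescaled so the realized SNR is exact.

The scored-corpus builder emulates a 22-recording panel-scored set:
11 "good" voices (cycle jitter 0.05–0.4%, vibrato-like modulation of
0.3–1 semitone at 4.5–6 Hz, amplitude 0.7–1.0) and 11 "poor" voices
(jitter 1.2–3%, pitch wander of 3–7 semitones at 0.8–2 Hz, amplitude
0.25–0.5), all 1.2 s at 30 dB SNR, base F0 drawn from 180–350 Hz. The
subjective score is `10·logsig(0.8·(−z_jitter − z_wander + z_amplitude))`
on fixed standardization constants — a smooth monotone map yielding good
scores ≥ ~8 and poor scores ≤ ~3.5 — plus Gaussian judge noise
(sd 0.5 points), clamped to [0, 10].

What the generator does **not** emulate: real glottal pulse shapes,
breathiness/aspiration noise, formant movement, consonants, room
acoustics, or inter-judge disagreement structure. Passing tests therefore
demonstrate that the pipeline recovers the parameters of this signal
class and that the protocol machinery is correct — not performance on
real singing.

A known measurement interaction: frame-level jitter integrates the F0
*contour* slope between frame centers in addition to cycle-level jitter,
so a fast vibrato contributes to measured jitter. The monotonicity checks
therefore inject jitter at fixed F0, and corpus classes are designed to
separate on range width and energy as well as jitter.

## Numerical choices and degenerate inputs

- DWT uses periodization mode, making the transform orthogonal and the
  low-band reconstruction an exact projection (hence exactly idempotent).
- Yule–Walker systems get 1e-9 diagonal loading to keep near-degenerate
  frames (pure sinusoids) solvable; the autocorrelation method guarantees
  pole stability. `prediction_error` reports the autocorrelation-domain
  residual `r0 − a·r`, the quantity the fit minimizes, which is exactly
  non-increasing in model order.
- Autocorrelation tie-breaks prefer the smallest lag (highest F0) within
  a 0.02 tolerance on the normalized peak.
- Silent signals: VAD returns an empty segment list; pitch tracking marks
  all frames unvoiced; feature assembly raises an insufficient-data error
  rather than emitting NaNs. All-zero frames are rejected by the AR fit.
- Features with zero training-set range normalize to 0.5; out-of-range
  test features clamp to [0, 1].

## Problem sizes used in the shipped checks

Validation uses 1–1.2 s signals at 16 kHz, 22-sample corpora, and
medians over 10 seeds for the stochastic checks (protocol accuracy,
jitter monotonicity) — small enough to run routinely while leaving the
statistics stable.

## Known limitations

- Jitter is frame-based, not glottal-cycle-based; absolute values are
  diluted relative to cycle-level jitter (ranking is preserved).
- F1 estimates degrade above ~200 Hz F0 (harmonic sampling limit).
- The comparison of sung pitch against a musical score, and the
  competitive-layer network variant, are out of scope; the range is
  computed from the detected pitch track only.
- Training is plain gradient descent and can be slow near saturation;
  divergence raises an explicit error suggesting a smaller learning rate.
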