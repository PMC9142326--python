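"""Shared fixtures: synthetic voices and corpora with known ground truth.

Everything is generated programmatically and cached per session; no audio
files ship with the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from voxscore import extract_features
from voxscore.config import RunConfig
from voxscore.synth import ScoredCorpusSpec, VoiceSpec, build_scored_corpus, synth_voice

SAMPLE_RATE = 16000


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def voice_220():
    """Clean sustained 220 Hz voice with default formants at 30 dB SNR."""
    return synth_voice(VoiceSpec(duration_s=1.0, f0_contour=220.0,
                                 snr_db=30.0, seed=1), SAMPLE_RATE)


@pytest.fixture(scope="session")
def steady_tone():
    """Pure 200 Hz sine, 1 s, unit-ish amplitude, no noise."""
    t = np.arange(SAMPLE_RATE) / SAMPLE_RATE
    return 0.7 * np.sin(2 * np.pi * 200.0 * t)


@pytest.fixture(scope="session")
def scored_corpus_features():
    """Seed-0 scored corpus with features extracted for every sample."""
    corpus = build_scored_corpus(ScoredCorpusSpec(seed=0), SAMPLE_RATE)
    features = {s.sample_id: extract_features(s.signal) for s in corpus}
    scores = {s.sample_id: s.score for s in corpus}
    return corpus, features, scores
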