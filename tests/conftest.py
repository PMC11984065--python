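from __future__ import annotations

import numpy as np
import pytest

from protoconv.annotation import SessionAnnotation, Speaker, Utterance

INFANT_ANALYSIS = ("protophone", "syllable", "protoword")
CAREGIVER_ANALYSIS = ("speech", "vocalization", "singing")


def random_stream(rng, speaker, n_max=30, grid=None, length=90.0):
    """A random sorted, non-overlapping single-speaker utterance stream.

    With ``grid`` set, all times are exact multiples of it (0.25 is exactly
    representable in binary, producing genuine floating-point ties for
    tie-break testing).
    """
    n = int(rng.integers(0, n_max + 1))
    cats = INFANT_ANALYSIS if speaker is Speaker.INFANT else CAREGIVER_ANALYSIS
    utts = []
    t = 0.0
    for _ in range(n):
        if grid:
            gap = grid * int(rng.integers(0, 8))
            dur = grid * int(rng.integers(1, 8))
        else:
            gap = float(rng.exponential(1.2))
            dur = 0.05 + float(rng.exponential(0.8))
        onset = t + gap
        offset = onset + dur
        if offset > length:
            break
        utts.append(
            Utterance(onset, offset, speaker, cats[int(rng.integers(len(cats)))])
        )
        t = offset
    return utts


def random_session(rng, n_max=30, grid=None, duration=90.0, dyad_id="dx"):
    infant = random_stream(rng, Speaker.INFANT, n_max=n_max, grid=grid, length=duration)
    caregiver = random_stream(
        rng, Speaker.CAREGIVER, n_max=n_max, grid=grid, length=duration
    )
    return SessionAnnotation(
        dyad_id=dyad_id,
        timepoint="T1",
        task="book_sharing",
        duration=duration,
        utterances=tuple(infant + caregiver),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def three_utterance_session():
    """Hand-worked timeline: caregiver [0,1], infant [1.5,2], caregiver [2.3,3]."""
    return SessionAnnotation(
        dyad_id="d1",
        timepoint="T1",
        task="book_sharing",
        duration=300.0,
        utterances=(
            Utterance(0.0, 1.0, Speaker.CAREGIVER, "speech"),
            Utterance(1.5, 2.0, Speaker.INFANT, "syllable"),
            Utterance(2.3, 3.0, Speaker.CAREGIVER, "speech"),
        ),
    )
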