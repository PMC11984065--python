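"""Conversational-turn detection with signed transition times.

A turn pairs the *offset* of an initiator (Speaker 1) utterance with the
onset of the nearest responder (Speaker 2) utterance inside a response
window (3 s by default).  The transition time is ``responder onset −
initiator offset``: negative values are overlaps (the responder starts
while the initiator is still vocalizing), positive values are gaps.

The candidate set for an initiator utterance ``v`` is every responder
utterance whose onset lies in ``(v.onset, v.offset + window]``: a response
may begin during the initiator's utterance (overlap), but never before the
vocalization it answers begins.  "Nearest" means minimal ``|onset −
offset|``; an exact overlap/gap tie resolves to the gap, matching the
forward-search description of the procedure.

Both directions (infant initiating and caregiver initiating) are computed
independently; by default one responder utterance may answer several
initiator utterances, with an optional one-to-one assignment mode for
sensitivity analyses.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

from .annotation import SessionAnnotation, Speaker, Utterance, _check_stream

__all__ = [
    "TurnEvent",
    "TurnSummary",
    "CAREGIVER_INITIATED",
    "INFANT_INITIATED",
    "DIRECTIONS",
    "match_turns",
    "summarize_turns",
    "bidirectional_turns",
]

#: caregiver is Speaker 1, the infant responds
CAREGIVER_INITIATED = "caregiver_initiated"
#: infant is Speaker 1, the caregiver responds
INFANT_INITIATED = "infant_initiated"
DIRECTIONS = (CAREGIVER_INITIATED, INFANT_INITIATED)

DEFAULT_WINDOW = 3.0


@dataclass(frozen=True)
class TurnEvent:
    """A matched initiator-offset / responder-onset pair."""

    direction: str
    s1_index: int
    s2_index: int
    s1_onset: float
    s1_offset: float
    s2_onset: float
    transition: float

    @property
    def is_overlap(self) -> bool:
        return self.transition < 0


@dataclass(frozen=True)
class TurnSummary:
    """Per-session turn counts and timing for one direction."""

    n_turns: int
    turn_rate: float
    mean_transition: float | None
    n_gaps: int
    n_overlaps: int


def _candidate_key(transition: float, onset: float) -> tuple:
    # nearest by |transition|; overlap/gap magnitude tie -> the gap;
    # any residual tie -> earlier responder onset
    return (abs(transition), transition < 0, onset)


def match_turns(
    speaker1: Sequence[Utterance],
    speaker2: Sequence[Utterance],
    window: float = DEFAULT_WINDOW,
    unique_responses: bool = False,
    gaps_only: bool = False,
    direction: str = "",
) -> list[TurnEvent]:
    """Match each Speaker 1 utterance to its nearest Speaker 2 response.

    Parameters
    ----------
    speaker1, speaker2:
        Sorted, within-speaker non-overlapping utterance streams, already
        filtered to the analysis set.
    window:
        Response window in seconds after the initiator's offset (must be
        positive).
    unique_responses:
        When true, each Speaker 2 utterance answers at most one Speaker 1
        utterance; pairs are assigned greedily by ascending ``|transition|``
        with earlier initiators winning remaining ties.
    gaps_only:
        Restrict candidates to onsets strictly after the initiator's offset
        (no overlaps) — the variant matched by the homogeneous-Poisson
        baseline ``1 − exp(−λ·window)``.

    Returns events sorted by initiator offset.
    """
    if not window > 0:
        raise ValueError(f"window must be positive, got {window}")
    s1 = list(speaker1)
    s2 = list(speaker2)
    _check_stream(s1, context=" (speaker 1)")
    _check_stream(s2, context=" (speaker 2)")
    onsets2 = [u.onset for u in s2]

    def candidates(i: int, v: Utterance) -> list[tuple[int, float]]:
        lower = v.offset if gaps_only else v.onset
        lo = bisect_right(onsets2, lower)
        hi = bisect_right(onsets2, v.offset + window)
        return [(j, onsets2[j] - v.offset) for j in range(lo, hi)]

    events: list[TurnEvent] = []
    if not unique_responses:
        for i, v in enumerate(s1):
            cands = candidates(i, v)
            if not cands:
                continue
            j, t = min(cands, key=lambda c: _candidate_key(c[1], onsets2[c[0]]))
            events.append(
                TurnEvent(direction, i, j, v.onset, v.offset, onsets2[j], t)
            )
    else:
        pairs = [
            (i, j, t) for i, v in enumerate(s1) for j, t in candidates(i, v)
        ]
        pairs.sort(
            key=lambda p: (abs(p[2]), s1[p[0]].onset, p[2] < 0, onsets2[p[1]])
        )
        used1: set[int] = set()
        used2: set[int] = set()
        for i, j, t in pairs:
            if i in used1 or j in used2:
                continue
            used1.add(i)
            used2.add(j)
            events.append(
                TurnEvent(direction, i, j, s1[i].onset, s1[i].offset, onsets2[j], t)
            )
    events.sort(key=lambda e: (e.s1_offset, e.s1_index))
    return events


def summarize_turns(events: Sequence[TurnEvent], duration: float) -> TurnSummary:
    """Counts, rate per minute and mean signed transition time.

    The rate denominator is the full task duration.  With zero events the
    mean transition is missing (``None``), never imputed as zero.
    """
    if not duration > 0:
        raise ValueError(f"duration must be positive, got {duration}")
    n = len(events)
    n_overlaps = sum(1 for e in events if e.transition < 0)
    mean_t = sum(e.transition for e in events) / n if n else None
    return TurnSummary(
        n_turns=n,
        turn_rate=n / (duration / 60.0),
        mean_transition=mean_t,
        n_gaps=n - n_overlaps,
        n_overlaps=n_overlaps,
    )


def bidirectional_turns(
    session: SessionAnnotation,
    window: float = DEFAULT_WINDOW,
    unique_responses: bool = False,
) -> dict[str, tuple[list[TurnEvent], TurnSummary]]:
    """Run the turn analysis in both directions on a filtered session.

    The two directions are independent: the same utterance may appear as a
    responder in one direction and an initiator in the other.
    """
    infant = session.speaker_utterances(Speaker.INFANT)
    caregiver = session.speaker_utterances(Speaker.CAREGIVER)
    out: dict[str, tuple[list[TurnEvent], TurnSummary]] = {}
    for direction, s1, s2 in (
        (CAREGIVER_INITIATED, caregiver, infant),
        (INFANT_INITIATED, infant, caregiver),
    ):
        events = match_turns(
            s1, s2, window=window, unique_responses=unique_responses,
            direction=direction,
        )
        out[direction] = (events, summarize_turns(events, session.duration))
    return out
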