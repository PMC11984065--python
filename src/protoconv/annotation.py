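"""Utterance-level annotation model for dyadic vocal interaction sessions.

The unit of observation is the *utterance*: for infants, a vocalization
produced on a single expiration cycle (protophones, syllables, proto-words,
plus the reflexive laugh/cry categories); for caregivers, a vocal sound
bounded by silent pauses longer than a segmentation threshold (200 ms by
default), coded as speech, vocalization, singing or laughter.

A :class:`SessionAnnotation` holds every utterance of one dyad in one task
at one longitudinal timepoint, together with the task duration.  Reading
and writing go through Praat TextGrid files, the de-facto standard exchange
format for this kind of manual coding.

Conventions: all times are real seconds from session start; intervals are
half-open ``[onset, offset)`` for tiling purposes, so an onset equal to the
preceding offset is contiguity, not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from . import textgrid

logger = logging.getLogger(__name__)

__all__ = [
    "Speaker",
    "Utterance",
    "SessionAnnotation",
    "AnnotationError",
    "TIMEPOINTS",
    "TASKS",
    "INFANT_CATEGORIES",
    "CAREGIVER_CATEGORIES",
    "REFLEXIVE_INFANT_CATEGORIES",
    "EXCLUDED_CAREGIVER_CATEGORIES",
    "read_textgrid",
    "read_session",
    "write_textgrid",
    "merge_close_sounds",
    "filter_analysis_set",
]

TIMEPOINTS = ("T1", "T2", "T3", "T4")
TASKS = ("book_sharing", "manipulative_toys", "rattle_shaking")

#: numerical slack for float comparisons on annotation boundaries
EPS = 1e-9


class AnnotationError(ValueError):
    """Raised for invalid annotation content (overlaps, bad labels, ...)."""


class Speaker(str, Enum):
    INFANT = "infant"
    CAREGIVER = "caregiver"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


INFANT_CATEGORIES = frozenset(
    {"protophone", "syllable", "protoword", "laugh", "cry"}
)
CAREGIVER_CATEGORIES = frozenset({"speech", "vocalization", "singing", "laughter"})

#: reflexive infant sounds excluded from the analysis set
REFLEXIVE_INFANT_CATEGORIES = frozenset({"laugh", "cry"})
#: caregiver categories excluded from "vocal production"
EXCLUDED_CAREGIVER_CATEGORIES = frozenset({"laughter"})

_CATEGORIES = {
    Speaker.INFANT: INFANT_CATEGORIES,
    Speaker.CAREGIVER: CAREGIVER_CATEGORIES,
}


@dataclass(frozen=True)
class Utterance:
    """One labelled time interval produced by one speaker."""

    onset: float
    offset: float
    speaker: Speaker
    category: str

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise AnnotationError(
                f"utterance must have positive duration, got "
                f"[{self.onset}, {self.offset}]"
            )
        if self.onset < 0:
            raise AnnotationError(f"utterance onset must be >= 0, got {self.onset}")
        speaker = Speaker(self.speaker)
        object.__setattr__(self, "speaker", speaker)
        if self.category not in _CATEGORIES[speaker]:
            raise AnnotationError(
                f"category {self.category!r} is not legal for speaker "
                f"{speaker.value!r} (legal: {sorted(_CATEGORIES[speaker])})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _check_stream(utterances: Sequence[Utterance], context: str = "") -> None:
    """Validate that a single-speaker stream is sorted and non-overlapping."""
    for prev, cur in zip(utterances, utterances[1:]):
        if cur.onset < prev.onset - EPS:
            raise AnnotationError(f"utterances not sorted by onset{context}")
        if cur.onset < prev.offset - EPS:
            raise AnnotationError(
                f"overlapping same-speaker utterances "
                f"[{prev.onset}, {prev.offset}] and [{cur.onset}, {cur.offset}]"
                f"{context}"
            )


@dataclass
class SessionAnnotation:
    """All utterances of one dyad in one task at one timepoint.

    The constructor normalizes (sorts by onset) and validates: utterances
    must lie inside ``[0, duration]`` (up to ``spillover_tol``) and must not
    overlap within a speaker.
    """

    dyad_id: str
    timepoint: str
    task: str
    duration: float
    utterances: tuple[Utterance, ...] = ()
    spillover_tol: float = field(default=0.0, compare=False)
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise AnnotationError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        if self.task not in TASKS:
            raise AnnotationError(
                f"unknown task {self.task!r}; expected one of {TASKS}"
            )
        if not self.duration > 0:
            raise AnnotationError(f"duration must be positive, got {self.duration}")
        utts = tuple(sorted(self.utterances, key=lambda u: (u.onset, u.offset)))
        object.__setattr__(self, "utterances", utts)
        for u in utts:
            if u.offset > self.duration + self.spillover_tol + EPS:
                raise AnnotationError(
                    f"utterance [{u.onset}, {u.offset}] extends past the "
                    f"session duration {self.duration} (dyad {self.dyad_id}, "
                    f"{self.timepoint}, {self.task})"
                )
        for speaker in Speaker:
            self_utts = [u for u in utts if u.speaker is speaker]
            _check_stream(
                self_utts,
                context=f" for speaker {speaker.value!r} (dyad {self.dyad_id})",
            )

    def speaker_utterances(self, speaker: Speaker) -> tuple[Utterance, ...]:
        speaker = Speaker(speaker)
        return tuple(u for u in self.utterances if u.speaker is speaker)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.dyad_id, self.timepoint, self.task)


# ---------------------------------------------------------------------------
# TextGrid I/O

DEFAULT_TIER_MAP: Mapping[str, Speaker] = {
    "infant": Speaker.INFANT,
    "caregiver": Speaker.CAREGIVER,
}


def _repair_overlaps(
    utts: list[Utterance], repair: str
) -> tuple[list[Utterance], int]:
    """Resolve same-speaker interval overlaps from annotation slips.

    ``repair='clip'`` truncates the earlier interval at the later one's
    onset (dropping it when that leaves nothing); anything else is a hard
    error, the default contract.
    """
    if repair != "clip":
        _check_stream(utts, context=" in input file (use repair='clip' to fix)")
        return utts, 0
    out: list[Utterance] = []
    n_repaired = 0
    for u in sorted(utts, key=lambda x: (x.onset, x.offset)):
        if out and u.onset < out[-1].offset - EPS:
            prev = out.pop()
            n_repaired += 1
            logger.warning(
                "clipping overlapping interval [%s, %s] at %s", prev.onset,
                prev.offset, u.onset,
            )
            if u.onset > prev.onset + EPS:
                out.append(replace(prev, offset=u.onset))
        out.append(u)
    return out, n_repaired


def read_textgrid(
    path: str | Path,
    tier_map: Mapping[str, Speaker] | None = None,
    label_map: Mapping[str, str] | None = None,
    repair: str = "error",
) -> list[Utterance]:
    """Read the utterances of one session from a Praat TextGrid.

    Parameters
    ----------
    path:
        TextGrid file (long or short text format, UTF-8 or UTF-16).
    tier_map:
        Mapping from interval-tier name to the speaker it annotates.
        Defaults to ``{"infant": INFANT, "caregiver": CAREGIVER}``.
    label_map:
        Mapping from raw interval label to coding category.  By default
        labels must already be category names.  Unknown labels are an
        error, never silently dropped; empty labels are silence.
    repair:
        ``"error"`` (default) rejects overlapping same-speaker intervals;
        ``"clip"`` truncates the earlier interval and logs the repair.
    """
    tier_map = dict(tier_map or DEFAULT_TIER_MAP)
    grid = textgrid.read(path)
    utterances: list[Utterance] = []
    for tier_name, speaker in tier_map.items():
        tier = grid.get_tier(tier_name)  # raises naming the tier
        if not isinstance(tier, textgrid.IntervalTier):
            raise AnnotationError(
                f"tier {tier_name!r} in {path} is not an interval tier"
            )
        speaker = Speaker(speaker)
        utts: list[Utterance] = []
        for iv in tier.intervals:
            label = iv.text.strip()
            if not label:
                continue
            if label_map is not None:
                if label not in label_map:
                    raise AnnotationError(
                        f"unknown label {label!r} on interval "
                        f"[{iv.xmin}, {iv.xmax}] of tier {tier_name!r} in {path}"
                    )
                category = label_map[label]
            else:
                category = label
            try:
                utts.append(Utterance(iv.xmin, iv.xmax, speaker, category))
            except AnnotationError as exc:
                raise AnnotationError(f"{path}: {exc}") from exc
        utts, _ = _repair_overlaps(utts, repair)
        utterances.extend(utts)
    utterances.sort(key=lambda u: (u.onset, u.offset))
    return utterances


def read_session(
    path: str | Path,
    dyad_id: str,
    timepoint: str,
    task: str,
    duration: float | None = None,
    tier_map: Mapping[str, Speaker] | None = None,
    label_map: Mapping[str, str] | None = None,
    repair: str = "error",
    spillover_tol: float = 0.0,
) -> SessionAnnotation:
    """Read a TextGrid and assemble a full :class:`SessionAnnotation`.

    ``duration`` normally comes from the session manifest; if omitted, the
    grid's global ``xmax`` is used.
    """
    utts = read_textgrid(path, tier_map=tier_map, label_map=label_map, repair=repair)
    if duration is None:
        duration = textgrid.read(path).xmax
    return SessionAnnotation(
        dyad_id=dyad_id,
        timepoint=timepoint,
        task=task,
        duration=float(duration),
        utterances=tuple(utts),
        spillover_tol=spillover_tol,
    )


def write_textgrid(session: SessionAnnotation, path: str | Path) -> None:
    """Write a session as a long-format TextGrid, one tier per speaker.

    Silence intervals are inserted so each tier tiles ``[0, duration]``;
    :func:`read_textgrid` inverts the file exactly.
    """
    grid = textgrid.TextGrid(xmin=0.0, xmax=float(session.duration))
    for speaker in Speaker:
        tier = textgrid.IntervalTier(speaker.value, 0.0, float(session.duration))
        cursor = 0.0
        for u in session.speaker_utterances(speaker):
            if u.onset > cursor:
                tier.intervals.append(textgrid.Interval(cursor, u.onset, ""))
            tier.intervals.append(textgrid.Interval(u.onset, u.offset, u.category))
            cursor = u.offset
        if cursor < session.duration:
            tier.intervals.append(
                textgrid.Interval(cursor, float(session.duration), "")
            )
        grid.tiers.append(tier)
    textgrid.write(grid, path)


# ---------------------------------------------------------------------------
# segmentation and filtering


def merge_close_sounds(
    utterances: Sequence[Utterance],
    max_pause: float = 0.200,
    merge_across_categories: bool = False,
) -> list[Utterance]:
    """Fuse successive sounds separated by pauses of at most ``max_pause``.

    Implements the inter-pausal segmentation rule used in caregiver coding:
    two successive sounds are separate utterances only when the silent pause
    between them exceeds the threshold (a pause of exactly ``max_pause``
    fuses).  Fusion is transitive and, by default, restricted to
    same-category neighbours — category is an annotation-level judgement
    that fusion must not erase.

    The input must be one speaker's stream, sorted and non-overlapping.
    """
    if max_pause < 0:
        raise ValueError(f"max_pause must be >= 0, got {max_pause}")
    utts = list(utterances)
    if not utts:
        return []
    speakers = {u.speaker for u in utts}
    if len(speakers) > 1:
        raise AnnotationError("merge_close_sounds expects a single-speaker stream")
    _check_stream(utts, context=" in merge_close_sounds input")
    merged = [utts[0]]
    for u in utts[1:]:
        prev = merged[-1]
        gap = u.onset - prev.offset
        same_cat = merge_across_categories or (u.category == prev.category)
        if gap <= max_pause + EPS and same_cat:
            merged[-1] = replace(prev, offset=max(prev.offset, u.offset))
        else:
            merged.append(u)
    return merged


def filter_analysis_set(session: SessionAnnotation) -> SessionAnnotation:
    """Restrict a session to the utterances entering the analyses.

    Reflexive infant sounds (laugh, cry) and caregiver laughter are removed;
    speech, vocalization and singing remain as caregiver vocal production,
    and all speech-like infant categories remain.  Removal counts are logged
    and recorded in ``session.meta['filtered']``.
    """
    kept: list[Utterance] = []
    removed: dict[str, int] = {}
    for u in session.utterances:
        excluded = (
            u.speaker is Speaker.INFANT and u.category in REFLEXIVE_INFANT_CATEGORIES
        ) or (
            u.speaker is Speaker.CAREGIVER
            and u.category in EXCLUDED_CAREGIVER_CATEGORIES
        )
        if excluded:
            key = f"{u.speaker.value}:{u.category}"
            removed[key] = removed.get(key, 0) + 1
        else:
            kept.append(u)
    if removed:
        logger.info(
            "filter_analysis_set dropped %d utterances (%s) from dyad %s %s %s",
            sum(removed.values()), removed, session.dyad_id, session.timepoint,
            session.task,
        )
    meta = dict(session.meta)
    meta["filtered"] = removed
    return SessionAnnotation(
        dyad_id=session.dyad_id,
        timepoint=session.timepoint,
        task=session.task,
        duration=session.duration,
        utterances=tuple(kept),
        spillover_tol=session.spillover_tol,
        meta=meta,
    )


def apply_segmentation(
    session: SessionAnnotation,
    max_pause: float = 0.200,
    merge_across_categories: bool = False,
    merge_infant: bool = False,
) -> SessionAnnotation:
    """Apply the pause-merge rule to a whole session.

    The rule is part of the caregiver coding scheme; infant utterances are
    defined by expiration cycles and are left untouched unless
    ``merge_infant`` is set (sensitivity analyses).
    """
    out: list[Utterance] = []
    for speaker in Speaker:
        stream = list(session.speaker_utterances(speaker))
        if speaker is Speaker.CAREGIVER or merge_infant:
            stream = merge_close_sounds(
                stream, max_pause=max_pause,
                merge_across_categories=merge_across_categories,
            )
        out.extend(stream)
    return SessionAnnotation(
        dyad_id=session.dyad_id,
        timepoint=session.timepoint,
        task=session.task,
        duration=session.duration,
        utterances=tuple(out),
        spillover_tol=session.spillover_tol,
        meta=dict(session.meta),
    )
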