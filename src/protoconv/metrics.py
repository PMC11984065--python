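"""Per-session outcome rows and the long table consumed by the models.

Each analysed session contributes one row: vocalization rates per minute
for both partners, conversational-turn rates for both directions, mean
signed transition times, and mean utterance durations.  Rates always use
the full task duration (an ``effective_duration`` override is available
for sensitivity analyses).  Zero-turn sessions yield *missing* mean
transition times, which the marginal models later drop per-outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import pandas as pd

from .annotation import SessionAnnotation, Speaker, Utterance, TASKS, TIMEPOINTS
from .turns import (
    CAREGIVER_INITIATED,
    INFANT_INITIATED,
    DEFAULT_WINDOW,
    bidirectional_turns,
)

__all__ = [
    "SessionMetrics",
    "vocal_rate",
    "summarize_session",
    "build_long_table",
    "missing_cells",
    "OUTCOME_COLUMNS",
]

#: outcome columns of the long table, in reporting order
OUTCOME_COLUMNS = (
    "infant_voc_rate",
    "caregiver_voc_rate",
    "turns_cg_initiated_rate",
    "turns_inf_initiated_rate",
    "mean_tt_infant_responding",
    "mean_tt_caregiver_responding",
    "mean_infant_voc_duration",
    "mean_caregiver_utt_duration",
)


@dataclass(frozen=True)
class SessionMetrics:
    """The per-session row of all derived outcomes.

    ``turns_cg_initiated_rate`` counts turns with the caregiver as Speaker 1
    (the infant responding), so it pairs with ``mean_tt_infant_responding``;
    symmetrically for the infant-initiated direction.
    """

    dyad_id: str
    timepoint: str
    task: str
    duration: float
    infant_voc_rate: float
    caregiver_voc_rate: float
    turns_cg_initiated_rate: float
    turns_inf_initiated_rate: float
    mean_tt_infant_responding: float | None
    mean_tt_caregiver_responding: float | None
    mean_infant_voc_duration: float | None
    mean_caregiver_utt_duration: float | None

    def to_row(self) -> dict:
        row = asdict(self)
        for k, v in row.items():
            if v is None:
                row[k] = math.nan
        return row


def vocal_rate(utterances: Sequence[Utterance] | int, duration: float) -> float:
    """Events per minute over the full task duration."""
    if not duration > 0:
        raise ValueError(f"duration must be positive, got {duration}")
    n = utterances if isinstance(utterances, int) else len(utterances)
    return n / (duration / 60.0)


def _mean_duration(utterances: Sequence[Utterance]) -> float | None:
    if not utterances:
        return None
    return sum(u.duration for u in utterances) / len(utterances)


def summarize_session(
    session: SessionAnnotation,
    window: float = DEFAULT_WINDOW,
    unique_responses: bool = False,
    effective_duration: float | None = None,
) -> SessionMetrics:
    """Compute the full outcome row for one (already filtered) session."""
    duration = effective_duration if effective_duration is not None else session.duration
    infant = session.speaker_utterances(Speaker.INFANT)
    caregiver = session.speaker_utterances(Speaker.CAREGIVER)
    turns = bidirectional_turns(
        session, window=window, unique_responses=unique_responses
    )
    # recompute rates on the chosen denominator (bidirectional_turns uses
    # the session duration internally)
    _, cg_init = turns[CAREGIVER_INITIATED]
    _, inf_init = turns[INFANT_INITIATED]
    return SessionMetrics(
        dyad_id=session.dyad_id,
        timepoint=session.timepoint,
        task=session.task,
        duration=float(duration),
        infant_voc_rate=vocal_rate(infant, duration),
        caregiver_voc_rate=vocal_rate(caregiver, duration),
        turns_cg_initiated_rate=vocal_rate(cg_init.n_turns, duration),
        turns_inf_initiated_rate=vocal_rate(inf_init.n_turns, duration),
        mean_tt_infant_responding=cg_init.mean_transition,
        mean_tt_caregiver_responding=inf_init.mean_transition,
        mean_infant_voc_duration=_mean_duration(infant),
        mean_caregiver_utt_duration=_mean_duration(caregiver),
    )


def build_long_table(rows: Iterable[SessionMetrics | dict]) -> pd.DataFrame:
    """Stack per-session rows into the dyad x timepoint x task long table.

    Factor columns get ordered categorical dtypes; duplicate
    (dyad, timepoint, task) keys are an error naming the offending key.
    Missing sessions are simply absent — unbalanced panels are expected.
    """
    records = [
        r.to_row() if isinstance(r, SessionMetrics) else dict(r) for r in rows
    ]
    df = pd.DataFrame.from_records(records)
    if df.empty:
        raise ValueError("no session rows provided")
    dup = df.duplicated(subset=["dyad_id", "timepoint", "task"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["dyad_id", "timepoint", "task"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ValueError(f"duplicate session keys: {sorted(keys)}")
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=TIMEPOINTS, ordered=True)
    df["task"] = pd.Categorical(df["task"], categories=TASKS, ordered=True)
    return df.sort_values(["dyad_id", "timepoint", "task"]).reset_index(drop=True)


def missing_cells(table: pd.DataFrame, dyads: Sequence[str] | None = None) -> pd.DataFrame:
    """List absent dyad x timepoint x task cells of the full factorial design."""
    dyads = list(dyads) if dyads is not None else sorted(table["dyad_id"].unique())
    full = pd.MultiIndex.from_product(
        [dyads, list(TIMEPOINTS), list(TASKS)],
        names=["dyad_id", "timepoint", "task"],
    )
    present = pd.MultiIndex.from_frame(
        table[["dyad_id", "timepoint", "task"]].astype(str)
    )
    absent = full.difference(present)
    return absent.to_frame(index=False)
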