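"""Synthetic dyadic vocalization sessions with coupled response structure.

The generative model is a marked Poisson process with a post-offset
response kernel — the simplest mechanism that produces every quantity the
analysis measures (vocalization rates, turn rates, signed transition
times):

* each speaker produces *spontaneous* utterance onsets as a homogeneous
  Poisson process whose per-minute rate depends on task and timepoint and
  is multiplied by a dyad-level random effect (mean-one lognormal on the
  rate scale, shared across that dyad's sessions);
* after each spontaneous utterance of one partner, the other partner
  *responds* with a task/timepoint-dependent probability at a latency
  drawn from a Normal distribution; with probability ``overlap_prob`` the
  response begins *inside* the initiator's utterance (but never before its
  onset), yielding a negative turn transition;
* utterance durations are lognormal per speaker; reflexive sounds (infant
  laugh/cry, caregiver laughter) form separate low-rate streams so that
  the base rates describe the post-filtering analysis set;
* a scheduled utterance that would overlap an existing same-speaker
  utterance is dropped (the later-scheduled one loses); drop counts are
  reported in the session's ``meta`` so rate distortion is never silent;
* whole sessions go missing independently with ``missing_prob``,
  emulating missed visits in an unbalanced longitudinal panel.

Default parameters place the caregiver's highest rates in book-sharing at
every timepoint, keep the infant's expected vocalization rate
task-balanced at T1–T3, and introduce a book/rattle-versus-toys infant
effect (about two session-level standard deviations) only at T4 — the
qualitative pattern the downstream models are expected to detect.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import (
    SessionAnnotation,
    Speaker,
    TASKS,
    TIMEPOINTS,
    Utterance,
    write_textgrid,
)

__all__ = [
    "DyadSimParams",
    "StudyDesign",
    "StudyResult",
    "default_params",
    "null_params",
    "simulate_session",
    "simulate_study",
]

RateTable = Mapping[tuple[str, str], float]

_COLLISION_EPS = 1e-12
#: minimum head start of an initiator over an overlapping response (s)
_MIN_LEAD = 1e-3


def _lookup(value: float | RateTable, task: str, timepoint: str) -> float:
    if isinstance(value, Mapping):
        return float(value[(task, timepoint)])
    return float(value)


@dataclass
class DyadSimParams:
    """Study-condition parameters of the dyad simulator.

    Rates are utterances per minute; tables are keyed ``(task, timepoint)``
    and scalars apply uniformly.  ``dyad_sd`` is the standard deviation of
    the dyad random effect on log rates; ``missing_prob`` is the
    probability that any given session is absent.
    """

    caregiver_base_rate: float | RateTable = 10.0
    infant_base_rate: float | RateTable = 2.5
    p_infant_response: float | RateTable = 0.1
    p_caregiver_response: float | RateTable = 0.35
    latency_mean: float = 0.6
    latency_sd: float = 0.4
    overlap_prob: float = 0.2
    infant_duration_logmean: float = math.log(0.6)
    infant_duration_logsd: float = 0.5
    caregiver_duration_logmean: float = 0.0
    caregiver_duration_logsd: float = 0.6
    infant_reflexive_rate: float = 0.5
    caregiver_laughter_rate: float = 0.3
    session_length: float = 300.0
    dyad_sd: float = 0.2
    missing_prob: float = 0.3

    def validate(self) -> None:
        def rates(v: float | RateTable) -> list[float]:
            return list(v.values()) if isinstance(v, Mapping) else [float(v)]

        for name in ("caregiver_base_rate", "infant_base_rate",
                     "infant_reflexive_rate", "caregiver_laughter_rate"):
            if any(r < 0 for r in rates(getattr(self, name))):
                raise ValueError(f"{name} must be non-negative")
        for name in ("p_infant_response", "p_caregiver_response",
                     "overlap_prob", "missing_prob"):
            if any(not 0 <= p <= 1 for p in rates(getattr(self, name))):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.session_length > 0:
            raise ValueError("session_length must be positive")
        if self.latency_sd < 0 or self.dyad_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def default_params() -> DyadSimParams:
    """Defaults emulating the study's qualitative result pattern.

    Caregiver rates are highest during book-sharing at every timepoint and
    rise gently with infant age.  The infant's spontaneous rate and the
    coupled response load (response probability x caregiver rate) are both
    task-balanced at T1–T3; at T4 book-sharing and rattle-shaking exceed
    manipulative-toys play by about 2 utterances/min in expectation.
    """
    cg = {}
    inf = {}
    p_inf = {}
    cg_by_task = {
        "book_sharing": (12.0, 12.5, 13.0, 13.5),
        "manipulative_toys": (8.0, 8.5, 9.0, 9.0),
        "rattle_shaking": (8.0, 8.5, 9.0, 9.0),
    }
    inf_by_task = {
        "book_sharing": (1.8, 2.2, 2.6, 4.2),
        "manipulative_toys": (1.8, 2.2, 2.6, 2.6),
        "rattle_shaking": (1.8, 2.2, 2.6, 4.2),
    }
    # infant responses per minute the coupling should contribute
    load_by_task = {
        "book_sharing": (0.6, 0.8, 1.0, 1.6),
        "manipulative_toys": (0.6, 0.8, 1.0, 1.0),
        "rattle_shaking": (0.6, 0.8, 1.0, 1.6),
    }
    for task in TASKS:
        for i, tp in enumerate(TIMEPOINTS):
            cg[(task, tp)] = cg_by_task[task][i]
            inf[(task, tp)] = inf_by_task[task][i]
            p_inf[(task, tp)] = load_by_task[task][i] / cg_by_task[task][i]
    return DyadSimParams(
        caregiver_base_rate=cg,
        infant_base_rate=inf,
        p_infant_response=p_inf,
    )


def null_params() -> DyadSimParams:
    """Task-balanced variant of the defaults (age trends kept).

    Used for type-I-error calibration: no task main effect and no
    task x timepoint interaction in either partner's expected rates or in
    the coupling.
    """
    params = default_params()
    cg = {}
    inf = {}
    p_inf = {}
    for i, tp in enumerate(TIMEPOINTS):
        for task in TASKS:
            cg[(task, tp)] = (9.0, 9.5, 10.0, 10.5)[i]
            inf[(task, tp)] = (1.8, 2.2, 2.6, 3.0)[i]
            p_inf[(task, tp)] = (0.6, 0.8, 1.0, 1.2)[i] / cg[(task, tp)]
    params.caregiver_base_rate = cg
    params.infant_base_rate = inf
    params.p_infant_response = p_inf
    return params


# ---------------------------------------------------------------------------
# core stream generation


def _keep_scan(
    onsets: np.ndarray, durations: np.ndarray, groups: list[str], length: float
) -> tuple[list[float], list[float], list[str], dict[str, int]]:
    """Drop utterances overlapping an earlier-onset kept one; clip at length."""
    order = np.argsort(onsets, kind="stable")
    kept_on: list[float] = []
    kept_off: list[float] = []
    kept_grp: list[str] = []
    dropped: dict[str, int] = {}
    for idx in order:
        on = float(onsets[idx])
        off = min(on + float(durations[idx]), length)
        if off <= on:
            continue
        if kept_off and on < kept_off[-1] - _COLLISION_EPS:
            g = groups[idx]
            dropped[g] = dropped.get(g, 0) + 1
            continue
        kept_on.append(on)
        kept_off.append(off)
        kept_grp.append(groups[idx])
    return kept_on, kept_off, kept_grp, dropped


class _Stream:
    """A sorted, non-overlapping single-speaker stream with group labels."""

    def __init__(self, onsets: list[float], offsets: list[float], groups: list[str]):
        self.onsets = onsets
        self.offsets = offsets
        self.groups = groups

    def try_insert(self, onset: float, offset: float, group: str) -> bool:
        idx = bisect_right(self.onsets, onset)
        if idx > 0 and self.offsets[idx - 1] > onset + _COLLISION_EPS:
            return False
        if idx < len(self.onsets) and self.onsets[idx] < offset - _COLLISION_EPS:
            return False
        self.onsets.insert(idx, onset)
        self.offsets.insert(idx, offset)
        self.groups.insert(idx, group)
        return True


def simulate_streams(
    rng: np.random.Generator,
    params: DyadSimParams,
    task: str,
    timepoint: str,
    dyad_effect: float = 1.0,
) -> tuple[dict[Speaker, _Stream], dict]:
    """Generate both partners' onset/offset streams (no Utterance objects).

    This is the fast path shared by :func:`simulate_session` and the
    calibration simulations; counts are identical between the two.
    """
    params.validate()
    L = params.session_length
    rates = {
        Speaker.CAREGIVER: _lookup(params.caregiver_base_rate, task, timepoint),
        Speaker.INFANT: _lookup(params.infant_base_rate, task, timepoint),
    }
    reflexive = {
        Speaker.CAREGIVER: params.caregiver_laughter_rate,
        Speaker.INFANT: params.infant_reflexive_rate,
    }
    dur_params = {
        Speaker.CAREGIVER: (params.caregiver_duration_logmean,
                            params.caregiver_duration_logsd),
        Speaker.INFANT: (params.infant_duration_logmean,
                         params.infant_duration_logsd),
    }
    streams: dict[Speaker, _Stream] = {}
    stats: dict = {}
    spontaneous: dict[Speaker, list[tuple[float, float]]] = {}
    for speaker in (Speaker.CAREGIVER, Speaker.INFANT):
        n_main = rng.poisson(rates[speaker] / 60.0 * L * dyad_effect)
        n_refl = rng.poisson(reflexive[speaker] / 60.0 * L * dyad_effect)
        onsets = rng.uniform(0.0, L, n_main + n_refl)
        lm, ls = dur_params[speaker]
        durations = rng.lognormal(lm, ls, n_main + n_refl)
        groups = ["analysis"] * n_main + ["reflexive"] * n_refl
        kept_on, kept_off, kept_grp, dropped = _keep_scan(onsets, durations, groups, L)
        streams[speaker] = _Stream(kept_on, kept_off, kept_grp)
        spontaneous[speaker] = [
            (o, f) for o, f, g in zip(kept_on, kept_off, kept_grp) if g == "analysis"
        ]
        stats[speaker.value] = {
            "n_spont_scheduled": n_main,
            "n_spont_dropped": dropped.get("analysis", 0),
            "n_reflexive_scheduled": n_refl,
            "n_reflexive_dropped": dropped.get("reflexive", 0),
            "n_resp_scheduled": 0,
            "n_resp_dropped": 0,
            "n_resp_truncated": 0,
        }
    p_resp = {
        Speaker.INFANT: _lookup(params.p_infant_response, task, timepoint),
        Speaker.CAREGIVER: _lookup(params.p_caregiver_response, task, timepoint),
    }
    # responses are triggered by the partner's kept spontaneous utterances
    for initiator, responder in (
        (Speaker.CAREGIVER, Speaker.INFANT),
        (Speaker.INFANT, Speaker.CAREGIVER),
    ):
        p = p_resp[responder]
        lm, ls = dur_params[responder]
        st = stats[responder.value]
        for on, off in spontaneous[initiator]:
            if rng.random() >= p:
                continue
            st["n_resp_scheduled"] += 1
            magnitude = abs(rng.normal(params.latency_mean, params.latency_sd))
            if rng.random() < params.overlap_prob:
                r_on = max(on + _MIN_LEAD, off - magnitude)
            else:
                r_on = off + magnitude
            r_off = min(r_on + rng.lognormal(lm, ls), L)
            if r_on >= L or r_off <= r_on:
                st["n_resp_truncated"] += 1
                continue
            if not streams[responder].try_insert(r_on, r_off, "response"):
                st["n_resp_dropped"] += 1
    for speaker in (Speaker.CAREGIVER, Speaker.INFANT):
        grp = streams[speaker].groups
        stats[speaker.value]["n_kept_analysis"] = sum(
            1 for g in grp if g in ("analysis", "response")
        )
        stats[speaker.value]["n_kept_reflexive"] = grp.count("reflexive")
    return streams, stats


_ANALYSIS_CATEGORIES = {
    Speaker.INFANT: (("protophone", "syllable", "protoword"), (0.65, 0.28, 0.07)),
    Speaker.CAREGIVER: (("speech", "vocalization", "singing"), (0.80, 0.10, 0.10)),
}
_REFLEXIVE_CATEGORIES = {
    Speaker.INFANT: (("laugh", "cry"), (0.5, 0.5)),
    Speaker.CAREGIVER: (("laughter",), (1.0,)),
}


def simulate_session(
    params: DyadSimParams,
    task: str,
    timepoint: str,
    dyad_effect: float = 1.0,
    seed: int | np.random.Generator | None = None,
    dyad_id: str = "sim",
) -> SessionAnnotation:
    """Simulate one fully annotated session.

    Reproducible from ``seed``; simulation bookkeeping (scheduled, dropped
    and truncated counts per speaker) lands in the session's ``meta``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    streams, stats = simulate_streams(rng, params, task, timepoint, dyad_effect)
    utterances: list[Utterance] = []
    for speaker, stream in streams.items():
        for on, off, grp in zip(stream.onsets, stream.offsets, stream.groups):
            table = (
                _REFLEXIVE_CATEGORIES if grp == "reflexive" else _ANALYSIS_CATEGORIES
            )[speaker]
            category = table[0][int(rng.choice(len(table[0]), p=table[1]))]
            utterances.append(Utterance(on, off, speaker, category))
    return SessionAnnotation(
        dyad_id=dyad_id,
        timepoint=timepoint,
        task=task,
        duration=params.session_length,
        utterances=tuple(utterances),
        meta={"sim": stats, "dyad_effect": dyad_effect},
    )


# ---------------------------------------------------------------------------
# whole studies


@dataclass
class StudyDesign:
    """Longitudinal factorial design: dyads x timepoints x tasks."""

    n_dyads: int = 104
    timepoints: tuple[str, ...] = TIMEPOINTS
    tasks: tuple[str, ...] = TASKS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be >= 1")


@dataclass
class StudyResult:
    manifest: pd.DataFrame
    sessions: dict[tuple[str, str, str], SessionAnnotation]
    dyad_effects: dict[str, float] = field(default_factory=dict)


def session_rng(seed: int, dyad_index: int, tp_index: int, task_index: int
                ) -> np.random.Generator:
    """Per-session generator derived deterministically from the root seed."""
    return np.random.default_rng([seed, 3, dyad_index, tp_index, task_index])


def simulate_study(
    design: StudyDesign,
    params: DyadSimParams,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Simulate a full study; optionally write TextGrids plus a manifest.

    Dyad effects are drawn once per dyad and shared across that dyad's
    sessions; sessions are masked missing independently with
    ``params.missing_prob``.  With ``out_dir`` set, one TextGrid per
    session and a ``manifest.csv`` (columns ``dyad_id, timepoint, task,
    duration_s, textgrid_path``) are written.
    """
    params.validate()
    effect_rng = np.random.default_rng([design.seed, 1])
    effects = np.exp(
        effect_rng.normal(-params.dyad_sd**2 / 2.0, params.dyad_sd, design.n_dyads)
    )
    missing_rng = np.random.default_rng([design.seed, 2])
    missing = missing_rng.random(
        (design.n_dyads, len(design.timepoints), len(design.tasks))
    ) < params.missing_prob

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows = []
    sessions: dict[tuple[str, str, str], SessionAnnotation] = {}
    dyad_effects: dict[str, float] = {}
    for d in range(design.n_dyads):
        dyad_id = f"d{d + 1:03d}"
        dyad_effects[dyad_id] = float(effects[d])
        for ti, tp in enumerate(design.timepoints):
            for ki, task in enumerate(design.tasks):
                if missing[d, ti, ki]:
                    continue
                rng = session_rng(design.seed, d, ti, ki)
                session = simulate_session(
                    params, task, tp, dyad_effect=float(effects[d]),
                    seed=rng, dyad_id=dyad_id,
                )
                sessions[(dyad_id, tp, task)] = session
                tg_path = ""
                if out_path is not None:
                    tg_path = f"{dyad_id}_{tp}_{task}.TextGrid"
                    write_textgrid(session, out_path / tg_path)
                rows.append(
                    {
                        "dyad_id": dyad_id,
                        "timepoint": tp,
                        "task": task,
                        "duration_s": params.session_length,
                        "textgrid_path": tg_path,
                    }
                )
    manifest = pd.DataFrame(
        rows, columns=["dyad_id", "timepoint", "task", "duration_s", "textgrid_path"]
    )
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return StudyResult(manifest=manifest, sessions=sessions, dyad_effects=dyad_effects)
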