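"""Simulation-based validation of the pipeline and the inference stage.

These routines quantify, under the simulator's known generative model:

* the chance-level turn-matching baseline — with no coupling, the fraction
  of initiator utterances matched in the gap-only variant should follow
  the homogeneous-Poisson prediction ``1 − exp(−λ·W)``;
* rate recovery through the full annotation pipeline (TextGrid round trip,
  filtering, rate arithmetic), with the simulator's collision-drop
  distortion reported explicitly;
* the type-I error of the omnibus GEE interaction test on task-balanced
  (null) studies;
* the power to detect the T4-only book-versus-toys infant effect via
  Bonferroni-corrected within-timepoint contrasts, together with the
  false-flag rate at T1.

Replicate sizes are parameters; defaults are the sizes the package's own
validation suite uses.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    Speaker,
    TASKS,
    TIMEPOINTS,
    filter_analysis_set,
    read_session,
    write_textgrid,
)
from .gee import ModelSpec, fit_marginal_model, omnibus_wald, pairwise_task_contrasts
from .metrics import summarize_session, vocal_rate
from .simulate import (
    DyadSimParams,
    default_params,
    null_params,
    session_rng,
    simulate_session,
    simulate_streams,
)
from .turns import match_turns

__all__ = [
    "independence_matched_fraction",
    "caregiver_rate_recovery",
    "simulate_outcome_table",
    "interaction_type_one_error",
    "t4_contrast_power",
]


def _uncoupled_params(caregiver_rate: float, infant_rate: float) -> DyadSimParams:
    return DyadSimParams(
        caregiver_base_rate=caregiver_rate,
        infant_base_rate=infant_rate,
        p_infant_response=0.0,
        p_caregiver_response=0.0,
        dyad_sd=0.0,
        missing_prob=0.0,
    )


def independence_matched_fraction(
    n_sessions: int = 200,
    seed: int = 0,
    window: float = 3.0,
    infant_rate: float = 4.0,
    caregiver_rate: float = 12.0,
) -> dict:
    """Chance-level matching under independence, versus the Poisson law.

    Simulates uncoupled sessions, runs gap-only turn matching with the
    caregiver initiating, and returns the fraction of caregiver utterances
    matched (restricted to initiators whose window fits inside the
    session) together with the analytic value ``1 − exp(−λ·W)`` at the
    nominal infant onset rate and the Monte-Carlo standard error.
    """
    params = _uncoupled_params(caregiver_rate, infant_rate)
    fractions = []
    n_matched_total = 0
    n_initiators_total = 0
    for i in range(n_sessions):
        session = simulate_session(
            params, "book_sharing", "T1", seed=np.random.default_rng([seed, 10, i])
        )
        session = filter_analysis_set(session)
        caregiver = session.speaker_utterances(Speaker.CAREGIVER)
        infant = session.speaker_utterances(Speaker.INFANT)
        events = match_turns(caregiver, infant, window=window, gaps_only=True)
        matched = {e.s1_index for e in events}
        limit = session.duration - window
        eligible = [j for j, u in enumerate(caregiver) if u.offset <= limit]
        if not eligible:
            continue
        n_hit = sum(1 for j in eligible if j in matched)
        fractions.append(n_hit / len(eligible))
        n_matched_total += n_hit
        n_initiators_total += len(eligible)
    fractions = np.asarray(fractions)
    analytic = 1.0 - math.exp(-window * infant_rate / 60.0)
    return {
        "fraction": float(fractions.mean()),
        "analytic": analytic,
        "mc_se": float(fractions.std(ddof=1) / math.sqrt(len(fractions))),
        "n_sessions": len(fractions),
        "n_initiators": n_initiators_total,
    }


def caregiver_rate_recovery(
    n_sessions: int = 200,
    seed: int = 0,
    rate: float = 12.0,
    via_files: bool = True,
    work_dir: str | Path | None = None,
) -> dict:
    """Recover the caregiver's nominal rate through the full pipeline.

    Each uncoupled session is (optionally) written to a TextGrid, read
    back, filtered and summarized; the extracted ``caregiver_voc_rate`` is
    compared against the nominal rate and against the nominal rate after
    the simulator-reported collision-drop correction.
    """
    params = _uncoupled_params(rate, 2.5)
    extracted = []
    n_scheduled = 0
    n_dropped = 0
    tmp = None
    if via_files and work_dir is None:
        tmp = tempfile.TemporaryDirectory()
        work_dir = tmp.name
    try:
        for i in range(n_sessions):
            session = simulate_session(
                params, "book_sharing", "T1",
                seed=np.random.default_rng([seed, 11, i]),
            )
            st = session.meta["sim"]["caregiver"]
            n_scheduled += st["n_spont_scheduled"]
            n_dropped += st["n_spont_dropped"]
            if via_files:
                path = Path(work_dir) / f"session_{i}.TextGrid"
                write_textgrid(session, path)
                session = read_session(
                    path, session.dyad_id, session.timepoint, session.task,
                    duration=session.duration,
                )
            metrics = summarize_session(filter_analysis_set(session))
            extracted.append(metrics.caregiver_voc_rate)
    finally:
        if tmp is not None:
            tmp.cleanup()
    extracted = np.asarray(extracted)
    kept_fraction = 1.0 - n_dropped / n_scheduled if n_scheduled else float("nan")
    minutes_per_session = params.session_length / 60.0
    scheduled_rate = n_scheduled / (n_sessions * minutes_per_session)
    # per-session scheduled counts are Poisson(rate * minutes)
    scheduled_se = math.sqrt(rate / minutes_per_session / n_sessions)
    return {
        "extracted_mean_rate": float(extracted.mean()),
        "nominal_rate": rate,
        "kept_fraction": kept_fraction,
        "expected_rate": rate * kept_fraction,
        "scheduled_mean_rate": scheduled_rate,
        "scheduled_mc_se": scheduled_se,
        "mc_se": float(extracted.std(ddof=1) / math.sqrt(len(extracted))),
        "n_sessions": n_sessions,
    }


def simulate_outcome_table(
    params: DyadSimParams,
    n_dyads: int,
    seed: int,
    outcome: str = "infant_voc_rate",
) -> pd.DataFrame:
    """Fast per-session outcome table using the array stream path.

    Mirrors :func:`protoconv.simulate.simulate_study` (same dyad effects,
    missingness masks and per-session seed derivation, hence identical
    counts) without building ``Utterance`` objects.
    """
    if outcome not in ("infant_voc_rate", "caregiver_voc_rate"):
        raise ValueError(f"fast path does not produce outcome {outcome!r}")
    speaker = "infant" if outcome == "infant_voc_rate" else "caregiver"
    effect_rng = np.random.default_rng([seed, 1])
    effects = np.exp(
        effect_rng.normal(-params.dyad_sd**2 / 2.0, params.dyad_sd, n_dyads)
    )
    missing_rng = np.random.default_rng([seed, 2])
    missing = missing_rng.random((n_dyads, len(TIMEPOINTS), len(TASKS))) < params.missing_prob
    rows = []
    for d in range(n_dyads):
        for ti, tp in enumerate(TIMEPOINTS):
            for ki, task in enumerate(TASKS):
                if missing[d, ti, ki]:
                    continue
                rng = session_rng(seed, d, ti, ki)
                _, stats = simulate_streams(rng, params, task, tp, float(effects[d]))
                rows.append(
                    {
                        "dyad_id": f"d{d + 1:03d}",
                        "timepoint": tp,
                        "task": task,
                        "duration": params.session_length,
                        outcome: vocal_rate(
                            stats[speaker]["n_kept_analysis"], params.session_length
                        ),
                    }
                )
    return pd.DataFrame(rows)


def interaction_type_one_error(
    n_reps: int = 500,
    n_dyads: int = 60,
    seed: int = 0,
    alpha: float = 0.05,
    params: DyadSimParams | None = None,
) -> dict:
    """Rejection rate of the omnibus interaction Wald test on null studies."""
    params = params if params is not None else null_params()
    spec = ModelSpec(outcome="infant_voc_rate")
    rejections = 0
    for rep in range(n_reps):
        rep_seed = (seed * 1000003 + rep) % (2**31 - 1)
        table = simulate_outcome_table(params, n_dyads, rep_seed)
        fit = fit_marginal_model(table, spec)
        if omnibus_wald(fit, "interaction").p_value < alpha:
            rejections += 1
    rate = rejections / n_reps
    return {
        "rejection_rate": rate,
        "n_reps": n_reps,
        "mc_se": math.sqrt(rate * (1 - rate) / n_reps),
    }


def t4_contrast_power(
    n_reps: int = 200,
    n_dyads: int = 80,
    seed: int = 0,
    alpha: float = 0.05,
    params: DyadSimParams | None = None,
) -> dict:
    """Detection of the T4-only book-versus-toys infant effect.

    Returns the fraction of replicates whose Bonferroni-adjusted
    within-timepoint book-versus-toys contrast is significant at T4
    (power) and at T1 (false-flag rate).
    """
    params = params if params is not None else default_params()
    spec = ModelSpec(outcome="infant_voc_rate")
    hits_t4 = 0
    hits_t1 = 0
    for rep in range(n_reps):
        rep_seed = (seed * 999983 + rep) % (2**31 - 1)
        table = simulate_outcome_table(params, n_dyads, rep_seed)
        fit = fit_marginal_model(table, spec)
        contrasts = pairwise_task_contrasts(fit, family="within_timepoint")
        pair = (
            (contrasts["task_a"] == "book_sharing")
            & (contrasts["task_b"] == "manipulative_toys")
        )
        p_t4 = contrasts.loc[pair & (contrasts["timepoint"] == "T4"), "p_adjusted"]
        p_t1 = contrasts.loc[pair & (contrasts["timepoint"] == "T1"), "p_adjusted"]
        hits_t4 += int(float(p_t4.iloc[0]) < alpha)
        hits_t1 += int(float(p_t1.iloc[0]) < alpha)
    return {
        "power_t4": hits_t4 / n_reps,
        "false_flag_t1": hits_t1 / n_reps,
        "n_reps": n_reps,
    }
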