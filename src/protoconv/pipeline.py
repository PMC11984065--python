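"""Four-stage pipeline: simulate -> extract -> analyze -> report.

Extraction walks a session manifest, reads each TextGrid, applies the
pause-merge segmentation and the analysis-set filter, computes the
per-session outcome row, and assembles the long table.  Every
data-dropping decision (category filters, overlap repairs, zero-turn
sessions, missing outcomes) is counted in a QC report — data loss is
never silent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    Speaker,
    apply_segmentation,
    filter_analysis_set,
    read_session,
)
from .gee import (
    ModelSpec,
    fit_marginal_model,
    format_wald,
    omnibus_wald,
    pairwise_task_contrasts,
    TERMS,
)
from .metrics import OUTCOME_COLUMNS, build_long_table, missing_cells, summarize_session
from .simulate import DyadSimParams, StudyDesign, default_params, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_extract", "run_analyze", "run_report", "run_simulate"]

MANIFEST_COLUMNS = ("dyad_id", "timepoint", "task", "duration_s", "textgrid_path")


@dataclass
class PipelineConfig:
    """Structured configuration shared by the CLI subcommands."""

    manifest: str = "manifest.csv"
    annotation_dir: str = "."
    out_dir: str = "out"
    window: float = 3.0
    merge_threshold: float = 0.200
    merge_across_categories: bool = False
    merge_infant: bool = False
    unique_responses: bool = False
    repair: str = "error"
    tier_map: Mapping[str, str] | None = None
    label_map: Mapping[str, str] | None = None
    outcome: str = "infant_voc_rate"
    family: str = "gaussian"
    working_correlation: str = "independence"
    seed: int = 0
    simulator: DyadSimParams = field(default_factory=default_params)
    n_dyads: int = 104

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = data.pop("simulator", None)
        config = cls(**data)
        if sim is not None:
            config.simulator = DyadSimParams(**sim)
        if config.window <= 0:
            raise ValueError("window must be positive")
        if config.merge_threshold < 0:
            raise ValueError("merge_threshold must be non-negative")
        return config

    def provenance(self) -> dict:
        def keyed(obj):
            if isinstance(obj, dict):
                return {str(k): keyed(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [keyed(v) for v in obj]
            return obj

        blob = json.dumps(
            keyed(dataclasses.asdict(self)), sort_keys=True, default=str
        ).encode()
        return {
            "version": __version__,
            "seed": self.seed,
            "config_sha1": hashlib.sha1(blob).hexdigest(),
        }


def run_simulate(config: PipelineConfig) -> pd.DataFrame:
    """Simulate a study to disk (TextGrids + manifest); returns the manifest."""
    design = StudyDesign(n_dyads=config.n_dyads, seed=config.seed)
    result = simulate_study(design, config.simulator, out_dir=config.out_dir)
    logger.info("simulated %d sessions into %s", len(result.manifest), config.out_dir)
    return result.manifest


def run_extract(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Extract the long table from a manifest of TextGrid annotations.

    Returns the table and a QC report (counts of removed categories,
    repairs, zero-turn sessions, missing design cells).  Deterministic
    given the inputs; any per-session failure aborts naming the session.
    """
    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    missing_cols = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest is missing columns: {sorted(missing_cols)}")
    tier_map = (
        {k: Speaker(v) for k, v in config.tier_map.items()}
        if config.tier_map
        else None
    )
    rows = []
    qc: dict = {
        "n_sessions": 0,
        "removed_by_category": {},
        "zero_turn_sessions": [],
        "sessions_failed": [],
    }
    for rec in manifest.itertuples(index=False):
        tg_path = Path(config.annotation_dir) / str(rec.textgrid_path)
        if not tg_path.exists():
            raise FileNotFoundError(
                f"TextGrid not found for session ({rec.dyad_id}, {rec.timepoint}, "
                f"{rec.task}): {tg_path}"
            )
        try:
            session = read_session(
                tg_path,
                dyad_id=str(rec.dyad_id),
                timepoint=str(rec.timepoint),
                task=str(rec.task),
                duration=float(rec.duration_s),
                tier_map=tier_map,
                label_map=config.label_map,
                repair=config.repair,
            )
            session = apply_segmentation(
                session,
                max_pause=config.merge_threshold,
                merge_across_categories=config.merge_across_categories,
                merge_infant=config.merge_infant,
            )
            session = filter_analysis_set(session)
            effective = getattr(rec, "effective_duration_s", None)
            effective = None if effective is None or pd.isna(effective) else float(effective)
            metrics = summarize_session(
                session,
                window=config.window,
                unique_responses=config.unique_responses,
                effective_duration=effective,
            )
        except Exception as exc:
            raise RuntimeError(
                f"extraction failed for session ({rec.dyad_id}, {rec.timepoint}, "
                f"{rec.task}): {exc}"
            ) from exc
        qc["n_sessions"] += 1
        for key, count in session.meta.get("filtered", {}).items():
            qc["removed_by_category"][key] = (
                qc["removed_by_category"].get(key, 0) + count
            )
        if (
            metrics.turns_cg_initiated_rate == 0
            and metrics.turns_inf_initiated_rate == 0
        ):
            qc["zero_turn_sessions"].append(list(session.key))
        rows.append(metrics)
    table = build_long_table(rows)
    qc["missing_cells"] = missing_cells(table).to_dict(orient="records")
    qc["n_missing_cells"] = len(qc["missing_cells"])
    return table, qc


def run_analyze(
    table: pd.DataFrame,
    outcome: str,
    family: str = "gaussian",
    working_correlation: str = "independence",
    contrast_family: str = "within_timepoint",
) -> dict:
    """Fit the marginal model for one outcome; return results + report text."""
    spec = ModelSpec(
        outcome=outcome, family=family, working_correlation=working_correlation
    )
    fit = fit_marginal_model(table, spec)
    wald = {term: omnibus_wald(fit, term) for term in TERMS}
    contrasts = pairwise_task_contrasts(fit, family=contrast_family)
    lines = [
        f"Outcome: {outcome} "
        f"(family={family}, corr={working_correlation}, "
        f"n={fit.n_used}, dropped={fit.n_dropped})",
        "",
        "Omnibus tests (robust covariance):",
    ]
    for term in TERMS:
        lines.append(f"  {term:<12} {format_wald(wald[term])}")
    lines.append("")
    lines.append(
        f"Pairwise task contrasts (Bonferroni, family size "
        f"{int(contrasts['family_size'].iloc[0])}):"
    )
    for rec in contrasts.itertuples(index=False):
        flag = "*" if rec.p_adjusted < 0.05 else " "
        lines.append(
            f"  {rec.timepoint} {rec.task_a} vs {rec.task_b}: "
            f"estimate = {rec.estimate:+.3f} (SE {rec.se:.3f}), "
            f"adj. p = {rec.p_adjusted:.3g} {flag}"
        )
    return {
        "fit": fit,
        "wald": wald,
        "contrasts": contrasts,
        "report": "\n".join(lines),
    }


def run_report(table: pd.DataFrame, outcomes: tuple[str, ...] = OUTCOME_COLUMNS
               ) -> pd.DataFrame:
    """Descriptive summaries per outcome x task x timepoint.

    Quartiles use linear interpolation (the default definition in numpy and
    in standard boxplot conventions).
    """
    if table.empty:
        raise ValueError("empty long table")
    records = []
    for outcome in outcomes:
        if outcome not in table.columns:
            continue
        grouped = table.groupby(["task", "timepoint"], observed=True)[outcome]
        for (task, tp), values in grouped:
            values = values.dropna()
            if values.empty:
                continue
            records.append(
                {
                    "outcome": outcome,
                    "task": task,
                    "timepoint": tp,
                    "n": len(values),
                    "mean": values.mean(),
                    "median": values.median(),
                    "q1": values.quantile(0.25),
                    "q3": values.quantile(0.75),
                }
            )
    return pd.DataFrame(records)


def make_boxplots(table: pd.DataFrame, outcome: str, path: str | Path) -> None:
    """Generic boxplot figure of one outcome by timepoint and task."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    positions = []
    data = []
    labels = []
    for i, tp in enumerate(sorted(table["timepoint"].astype(str).unique())):
        for j, task in enumerate(sorted(table["task"].astype(str).unique())):
            vals = table.loc[
                (table["timepoint"].astype(str) == tp)
                & (table["task"].astype(str) == task),
                outcome,
            ].dropna()
            positions.append(i * 4 + j)
            data.append(vals)
            labels.append(f"{tp}\n{task[:4]}")
    ax.boxplot(data, positions=positions)
    ax.set_xticks(positions)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel(outcome)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
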