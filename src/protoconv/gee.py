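"""Marginal (GEE) repeated-measures models of the session outcomes.

Each outcome is modelled as ``outcome ~ task * timepoint`` with the dyad as
the clustering unit and robust (sandwich) standard errors — the standard
marginal approach for longitudinal designs where visits from the same dyad
are correlated and the panel is unbalanced.  The default working
correlation is independence: GEE point estimates are consistent under any
working structure, and at study-typical cluster counts (tens of dyads) the
extra noise from *estimating* an exchangeable correlation measurably
inflates the size of the 6-df interaction Wald test, whereas the
independence estimating equations with sandwich covariance stay calibrated
(exchangeable and AR(1) remain available).  Available-case analysis per
outcome: rows with a missing outcome (e.g., the mean transition time of a
zero-turn session) are dropped and counted, never imputed.

Omnibus Wald tests of the task (df 2), timepoint (df 3) and interaction
(df 6) terms use the quadratic form ``beta' V^-1 beta`` on the robust
covariance.  Post-hoc task contrasts are formed from estimated marginal
means per task x timepoint cell, with a Bonferroni family of the 3 task
pairs within each timepoint by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations


import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .annotation import TASKS, TIMEPOINTS

__all__ = [
    "ModelSpec",
    "GEEFit",
    "WaldResult",
    "fit_marginal_model",
    "omnibus_wald",
    "pairwise_task_contrasts",
    "estimated_marginal_means",
    "format_wald",
    "mixed_model_comparison",
]

TERMS = ("task", "timepoint", "interaction")
_EXPECTED_DF = {"task": 2, "timepoint": 3, "interaction": 6}


@dataclass
class ModelSpec:
    """What to fit: outcome column, distribution family, working correlation.

    ``cluster_adjust`` applies the conventional ``G/(G−1)`` finite-sample
    scaling to the sandwich covariance (the default behaviour of the
    standard cluster-robust implementations in R and Stata); set it to
    False for the raw sandwich.
    """

    outcome: str
    family: str = "gaussian"  # or "poisson" (log link, log-duration offset)
    working_correlation: str = "independence"  # or "exchangeable", "ar1"
    cluster: str = "dyad_id"
    cluster_adjust: bool = True


@dataclass
class GEEFit:
    """A fitted marginal model plus bookkeeping."""

    result: object  # statsmodels GEEResults
    spec: ModelSpec
    n_used: int
    n_dropped: int
    n_clusters: int = 0

    @property
    def params(self) -> pd.Series:
        return self.result.params

    def robust_cov(self) -> np.ndarray:
        """Sandwich covariance, with the G/(G−1) scaling when requested."""
        V = np.asarray(self.result.cov_params())
        if self.spec.cluster_adjust and self.n_clusters > 1:
            V = V * (self.n_clusters / (self.n_clusters - 1))
        return V


@dataclass(frozen=True)
class WaldResult:
    term: str
    statistic: float
    df: int
    p_value: float


def _cov_struct(name: str) -> sm.cov_struct.CovStruct:
    table = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
        "ar1": sm.cov_struct.Autoregressive,
    }
    if name not in table:
        raise ValueError(
            f"unknown working correlation {name!r}; choose from {sorted(table)}"
        )
    if name == "ar1":
        return table[name](grid=False)
    return table[name]()


def fit_marginal_model(table: pd.DataFrame, spec: ModelSpec) -> GEEFit:
    """Fit ``outcome ~ task * timepoint`` by GEE with robust covariance.

    Requires at least two clusters and at most one row per dyad x
    timepoint x task.  For the Poisson family the outcome must be a count
    column; ``log(duration / 60)`` enters as the exposure offset so
    coefficients stay on the per-minute rate scale.
    """
    if spec.outcome not in table.columns:
        raise ValueError(f"outcome column {spec.outcome!r} not in table")
    df = table.copy()
    dup = df.duplicated(subset=[spec.cluster, "timepoint", "task"], keep=False)
    if dup.any():
        keys = df.loc[dup, [spec.cluster, "timepoint", "task"]].drop_duplicates()
        raise ValueError(
            f"duplicate rows per cluster/timepoint/task: "
            f"{list(keys.itertuples(index=False, name=None))}"
        )
    n_total = len(df)
    df = df.dropna(subset=[spec.outcome])
    n_dropped = n_total - len(df)
    if df[spec.cluster].nunique() < 2:
        raise ValueError("need at least 2 clusters (dyads) to fit a GEE")
    df = df.copy()
    df["task"] = df["task"].astype(
        pd.CategoricalDtype(categories=TASKS, ordered=True)
    )
    df["timepoint"] = df["timepoint"].astype(
        pd.CategoricalDtype(categories=TIMEPOINTS, ordered=True)
    )

    formula = f"{spec.outcome} ~ C(task) * C(timepoint)"
    kwargs: dict = {}
    if spec.family == "gaussian":
        family = sm.families.Gaussian()
    elif spec.family == "poisson":
        family = sm.families.Poisson()
        kwargs["offset"] = np.log(df["duration"] / 60.0)
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    time = None
    if spec.working_correlation == "ar1":
        time = df["timepoint"].cat.codes.to_numpy()
    if spec.family == "gaussian" and df[spec.outcome].nunique() == 1:
        # a constant outcome degenerates the GEE scale estimate; ordinary
        # least squares gives the exact (intercept-only) solution here
        result = smf.ols(formula, data=df).fit()
        return GEEFit(result=result, spec=spec, n_used=len(df),
                      n_dropped=n_dropped, n_clusters=df[spec.cluster].nunique())
    model = smf.gee(
        formula,
        groups=spec.cluster,
        data=df,
        family=family,
        cov_struct=_cov_struct(spec.working_correlation),
        time=time,
        **kwargs,
    )
    result = model.fit(maxiter=100)
    converged = getattr(result, "converged", True)
    if converged is False:
        raise RuntimeError(
            f"GEE did not converge for outcome {spec.outcome!r} "
            f"(fit history: {getattr(result, 'fit_history', None)})"
        )
    if not np.all(np.isfinite(np.asarray(result.params))):
        raise RuntimeError(
            f"GEE produced non-finite coefficients for outcome {spec.outcome!r}"
        )
    return GEEFit(result=result, spec=spec, n_used=len(df),
                  n_dropped=n_dropped, n_clusters=df[spec.cluster].nunique())


def _term_indices(fit: GEEFit, term: str) -> list[int]:
    names = list(fit.result.model.exog_names)
    if term == "task":
        return [i for i, n in enumerate(names) if "C(task)" in n and ":" not in n]
    if term == "timepoint":
        return [
            i for i, n in enumerate(names) if "C(timepoint)" in n and ":" not in n
        ]
    if term == "interaction":
        return [i for i, n in enumerate(names) if ":" in n]
    raise ValueError(f"unknown term {term!r}; choose from {TERMS}")


def omnibus_wald(fit: GEEFit, term: str) -> WaldResult:
    """Joint Wald chi-square test of one model term against zero.

    Computed as ``beta_s' V_ss^-1 beta_s`` on the robust covariance
    submatrix of the term's coefficients.
    """
    idx = _term_indices(fit, term)
    beta = np.asarray(fit.result.params)[idx]
    V = fit.robust_cov()[np.ix_(idx, idx)]
    try:
        solved = np.linalg.solve(V, beta)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            f"singular covariance submatrix for term {term!r}"
        ) from exc
    stat = float(beta @ solved)
    if not np.isfinite(stat) or stat < -1e-8:
        raise RuntimeError(f"invalid Wald statistic for term {term!r}: {stat}")
    stat = max(stat, 0.0)
    df = len(idx)
    return WaldResult(
        term=term, statistic=stat, df=df,
        p_value=float(scipy.stats.chi2.sf(stat, df)),
    )


def _cell_design_row(fit: GEEFit, task: str, timepoint: str) -> np.ndarray:
    design_info = fit.result.model.data.design_info
    (mat,) = patsy.build_design_matrices(
        [design_info], pd.DataFrame({"task": [task], "timepoint": [timepoint]})
    )
    return np.asarray(mat)[0]


def estimated_marginal_means(fit: GEEFit) -> pd.DataFrame:
    """Model-based mean of the outcome in every task x timepoint cell."""
    beta = np.asarray(fit.result.params)
    V = fit.robust_cov()
    rows = []
    for tp in TIMEPOINTS:
        for task in TASKS:
            x = _cell_design_row(fit, task, tp)
            est = float(x @ beta)
            se = float(np.sqrt(x @ V @ x))
            rows.append(
                {"timepoint": tp, "task": task, "emmean": est, "se": se}
            )
    return pd.DataFrame(rows)


def pairwise_task_contrasts(
    fit: GEEFit,
    family: str = "within_timepoint",
    global_family: bool = False,
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise task comparisons.

    ``family="within_timepoint"`` (default): all 3 task pairs within each
    timepoint, adjusted within a family of 3 per timepoint (or a global
    family of 12 with ``global_family=True``).  ``family="marginal"``:
    task effects averaged over timepoints, family of 3.

    P-values are two-sided normal (z) tests on the robust covariance.
    """
    beta = np.asarray(fit.result.params)
    V = fit.robust_cov()
    rows = []
    if family == "within_timepoint":
        fam_size = 12 if global_family else 3
        cells = {
            (tp, task): _cell_design_row(fit, task, tp)
            for tp in TIMEPOINTS
            for task in TASKS
        }
        for tp in TIMEPOINTS:
            for a, b in combinations(TASKS, 2):
                L = cells[(tp, a)] - cells[(tp, b)]
                rows.append((tp, a, b, L, fam_size))
    elif family == "marginal":
        avg = {
            task: np.mean(
                [_cell_design_row(fit, task, tp) for tp in TIMEPOINTS], axis=0
            )
            for task in TASKS
        }
        for a, b in combinations(TASKS, 2):
            rows.append(("all", a, b, avg[a] - avg[b], 3))
    else:
        raise ValueError(f"unknown contrast family {family!r}")

    records = []
    for tp, a, b, L, fam_size in rows:
        est = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        if se == 0:
            raise RuntimeError(f"degenerate contrast {a} vs {b} at {tp}")
        z = est / se
        p_raw = float(2.0 * scipy.stats.norm.sf(abs(z)))
        records.append(
            {
                "timepoint": tp,
                "task_a": a,
                "task_b": b,
                "estimate": est,
                "se": se,
                "z": z,
                "p_raw": p_raw,
                "family_size": fam_size,
                "p_adjusted": min(1.0, p_raw * fam_size),
            }
        )
    return pd.DataFrame(records)


def format_wald(result: WaldResult) -> str:
    """Render a Wald test in the conventional reporting shape."""
    if result.p_value < 0.001:
        p = "p < 0.001"
    else:
        p = f"p = {result.p_value:.3f}"
    return f"Wald χ²({result.df}) = {result.statistic:.4g}, {p}"


def mixed_model_comparison(table: pd.DataFrame, outcome: str) -> str:
    """Optional ML linear mixed-model cross-check (random dyad intercept).

    Provided for comparison output only; the marginal GEE is the validated
    estimator in this package.
    """
    df = table.dropna(subset=[outcome]).copy()
    df["task"] = df["task"].astype(str)
    df["timepoint"] = df["timepoint"].astype(str)
    model = smf.mixedlm(
        f"{outcome} ~ C(task) * C(timepoint)", data=df, groups=df["dyad_id"]
    )
    result = model.fit(reml=False)
    return str(result.summary())
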