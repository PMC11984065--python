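import re

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from protoconv.annotation import TASKS, TIMEPOINTS
from protoconv.calibration import simulate_outcome_table
from protoconv.gee import (
    ModelSpec,
    estimated_marginal_means,
    fit_marginal_model,
    format_wald,
    mixed_model_comparison,
    omnibus_wald,
    pairwise_task_contrasts,
)
from protoconv.simulate import default_params, null_params


def factorial_table(dyads, outcome_fn, duration=300.0):
    rows = []
    for d in dyads:
        for tp in TIMEPOINTS:
            for task in TASKS:
                rows.append(
                    {
                        "dyad_id": d, "timepoint": tp, "task": task,
                        "duration": duration,
                        "infant_voc_rate": outcome_fn(d, tp, task),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def simulated_table():
    return simulate_outcome_table(default_params(), 40, seed=123)


@pytest.fixture(scope="module")
def simulated_fit(simulated_table):
    return fit_marginal_model(simulated_table, ModelSpec("infant_voc_rate"))


class TestFitting:
    def test_constant_outcome_gives_pure_intercept(self):
        table = factorial_table(["d1", "d2", "d3", "d4"], lambda *_: 1.0)
        fit = fit_marginal_model(
            table, ModelSpec("infant_voc_rate", working_correlation="independence")
        )
        params = np.asarray(fit.result.params)
        assert params[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(params[1:], 0.0, atol=1e-10)

    def test_outcome_identical_across_tasks_zeroes_task_terms(self):
        tp_effect = {"T1": 1.0, "T2": 2.0, "T3": 4.0, "T4": 5.0}
        table = factorial_table(
            ["d1", "d2", "d3", "d4", "d5"], lambda d, tp, task: tp_effect[tp]
        )
        fit = fit_marginal_model(
            table, ModelSpec("infant_voc_rate", working_correlation="independence")
        )
        names = fit.result.model.exog_names
        for name, value in zip(names, np.asarray(fit.result.params)):
            if "task" in name:
                assert value == pytest.approx(0.0, abs=1e-9)

    def test_independence_one_row_per_cluster_equals_ols(self, rng):
        rows = []
        cells = [(tp, task) for tp in TIMEPOINTS for task in TASKS]
        for i in range(60):
            tp, task = cells[i % 12]
            rows.append(
                {
                    "dyad_id": f"solo{i}", "timepoint": tp, "task": task,
                    "duration": 300.0,
                    "infant_voc_rate": float(rng.normal(3.0, 1.0)),
                }
            )
        table = pd.DataFrame(rows)
        fit = fit_marginal_model(
            table, ModelSpec("infant_voc_rate", working_correlation="independence")
        )
        df = table.copy()
        df["task"] = pd.Categorical(df["task"], categories=TASKS, ordered=True)
        df["timepoint"] = pd.Categorical(
            df["timepoint"], categories=TIMEPOINTS, ordered=True
        )
        ols = smf.ols("infant_voc_rate ~ C(task) * C(timepoint)", data=df).fit()
        assert np.allclose(
            np.asarray(fit.result.params), np.asarray(ols.params), atol=1e-8
        )

    def test_missing_outcomes_dropped_and_counted(self):
        table = factorial_table(["d1", "d2", "d3"], lambda *_: 2.0)
        table.loc[[0, 5], "infant_voc_rate"] = np.nan
        fit = fit_marginal_model(
            table, ModelSpec("infant_voc_rate", working_correlation="independence")
        )
        assert fit.n_dropped == 2
        assert fit.n_used == len(table) - 2

    def test_single_cluster_rejected(self):
        table = factorial_table(["d1"], lambda *_: 1.0)
        with pytest.raises(ValueError, match="2 clusters"):
            fit_marginal_model(table, ModelSpec("infant_voc_rate"))

    def test_duplicate_rows_rejected(self):
        table = factorial_table(["d1", "d2"], lambda *_: 1.0)
        table = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            fit_marginal_model(table, ModelSpec("infant_voc_rate"))

    def test_poisson_family_with_offset_recovers_log_rate(self):
        # constant 20 counts over 5 minutes in every cell: the log-offset
        # parameterization must give exp(intercept) = 4/min exactly
        rows = []
        for i in range(8):
            for tp in TIMEPOINTS:
                for task in TASKS:
                    rows.append(
                        {
                            "dyad_id": f"d{i}", "timepoint": tp, "task": task,
                            "duration": 300.0,
                            "n_voc": 20,
                        }
                    )
        table = pd.DataFrame(rows)
        fit = fit_marginal_model(
            table,
            ModelSpec("n_voc", family="poisson",
                      working_correlation="independence"),
        )
        assert np.exp(fit.result.params.iloc[0]) == pytest.approx(4.0, rel=1e-6)


class TestWald:
    def test_term_degrees_of_freedom(self, simulated_fit):
        assert omnibus_wald(simulated_fit, "task").df == 2
        assert omnibus_wald(simulated_fit, "timepoint").df == 3
        assert omnibus_wald(simulated_fit, "interaction").df == 6

    @pytest.mark.parametrize("term", ["task", "timepoint", "interaction"])
    def test_quadratic_form_matches_statsmodels(self, simulated_table, term):
        # raw sandwich (no cluster-count scaling) must equal the
        # statsmodels wald_test quadratic form exactly
        simulated_fit = fit_marginal_model(
            simulated_table, ModelSpec("infant_voc_rate", cluster_adjust=False)
        )
        result = simulated_fit.result
        names = result.model.exog_names
        if term == "task":
            idx = [i for i, n in enumerate(names) if "C(task)" in n and ":" not in n]
        elif term == "timepoint":
            idx = [
                i for i, n in enumerate(names)
                if "C(timepoint)" in n and ":" not in n
            ]
        else:
            idx = [i for i, n in enumerate(names) if ":" in n]
        R = np.zeros((len(idx), len(names)))
        for row, i in enumerate(idx):
            R[row, i] = 1.0
        oracle = result.wald_test(R, scalar=True)
        ours = omnibus_wald(simulated_fit, term)
        assert ours.statistic == pytest.approx(float(oracle.statistic), rel=1e-8)
        assert ours.p_value == pytest.approx(float(oracle.pvalue), rel=1e-6)

    def test_cluster_adjustment_scales_statistic(self, simulated_table, simulated_fit):
        plain = fit_marginal_model(
            simulated_table, ModelSpec("infant_voc_rate", cluster_adjust=False)
        )
        G = simulated_fit.n_clusters
        for term in ("task", "timepoint", "interaction"):
            adjusted = omnibus_wald(simulated_fit, term).statistic
            raw = omnibus_wald(plain, term).statistic
            assert adjusted == pytest.approx(raw * (G - 1) / G, rel=1e-10)

    def test_row_order_invariance(self):
        table = simulate_outcome_table(default_params(), 25, seed=9)
        fit_a = fit_marginal_model(table, ModelSpec("infant_voc_rate"))
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit_b = fit_marginal_model(shuffled, ModelSpec("infant_voc_rate"))
        for term in ("task", "timepoint", "interaction"):
            assert omnibus_wald(fit_a, term).statistic == pytest.approx(
                omnibus_wald(fit_b, term).statistic, abs=1e-8, rel=1e-8
            )

    def test_unknown_term_rejected(self, simulated_fit):
        with pytest.raises(ValueError):
            omnibus_wald(simulated_fit, "age")


class TestContrasts:
    def test_estimates_are_emm_differences_and_antisymmetric(self, simulated_fit):
        emm = estimated_marginal_means(simulated_fit).set_index(
            ["timepoint", "task"]
        )["emmean"]
        contrasts = pairwise_task_contrasts(simulated_fit)
        for rec in contrasts.itertuples(index=False):
            diff = emm[(rec.timepoint, rec.task_a)] - emm[(rec.timepoint, rec.task_b)]
            assert rec.estimate == pytest.approx(diff, abs=1e-10)
        # antisymmetry: A-B equals -(B-A) by construction of the linear form
        assert contrasts.loc[0, "estimate"] == pytest.approx(
            -(emm[("T1", "manipulative_toys")] - emm[("T1", "book_sharing")]),
            abs=1e-10,
        )

    def test_bonferroni_arithmetic_and_bounds(self, simulated_fit):
        contrasts = pairwise_task_contrasts(simulated_fit)
        assert (contrasts["family_size"] == 3).all()
        assert len(contrasts) == 12
        for rec in contrasts.itertuples(index=False):
            assert rec.p_adjusted == pytest.approx(min(1.0, rec.p_raw * 3))
            assert rec.p_adjusted >= rec.p_raw
            assert rec.p_adjusted <= 1.0

    def test_global_family_size(self, simulated_fit):
        contrasts = pairwise_task_contrasts(simulated_fit, global_family=True)
        assert (contrasts["family_size"] == 12).all()

    def test_marginal_family(self, simulated_fit):
        contrasts = pairwise_task_contrasts(simulated_fit, family="marginal")
        assert len(contrasts) == 3
        assert (contrasts["family_size"] == 3).all()

    def test_unknown_family_rejected(self, simulated_fit):
        with pytest.raises(ValueError):
            pairwise_task_contrasts(simulated_fit, family="per_task")


class TestReporting:
    def test_wald_report_shape(self, simulated_fit):
        pattern = re.compile(
            r"^Wald χ²\((\d+)\) = \d+(\.\d+)?([eE][+-]?\d+)?, p (< 0\.001|= \d?\.\d+)$"
        )
        for term, df in (("task", 2), ("timepoint", 3), ("interaction", 6)):
            text = format_wald(omnibus_wald(simulated_fit, term))
            m = pattern.match(text)
            assert m, text
            assert int(m.group(1)) == df

    def test_mixed_model_comparison_runs(self):
        table = simulate_outcome_table(null_params(), 20, seed=2)
        text = mixed_model_comparison(table, "infant_voc_rate")
        assert "Coef." in text
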