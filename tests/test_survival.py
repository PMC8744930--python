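import numpy as np
import pandas as pd
import pytest

from tregsig import (
    ClinicalTable,
    ConvergenceError,
    SimConfig,
    cox_fit,
    cox_fit_arrays,
    gene_screen,
    kaplan_meier,
    logrank_test,
    simulate_bulk_cohort,
)
from .conftest import grid_search_cox_beta


class TestKaplanMeier:
    def test_hand_product_limit_three_subjects(self):
        km = kaplan_meier([2.0, 4.0, 5.0], [1, 1, 0])
        np.testing.assert_allclose(km.times, [2.0, 4.0])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3])
        assert km.survival_at(5.0) == pytest.approx(1 / 3)  # flat through the censoring
        assert km.survival_at(0.0) == 1.0

    def test_all_censored_curve_stays_at_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_no_censoring_equals_ecdf_complement(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        km = kaplan_meier(t, np.ones(40, dtype=int))
        for et in km.times:
            assert km.survival_at(et) == pytest.approx(np.mean(t > et))

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        t = np.round(rng.exponential(10, 60), 0) + 1  # heavy ties
        e = (rng.random(60) < 0.6).astype(int)
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(km.times).to_numpy()
        np.testing.assert_allclose(km.survival, ref, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 30)
        e = (rng.random(30) < 0.7).astype(int)
        g = (rng.random(30) < 0.5).astype(int)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a == pytest.approx(b)

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [1, 1])

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(3)
        t = np.round(rng.exponential(5, 80), 1)
        e = (rng.random(80) < 0.7).astype(int)
        g = (rng.random(80) < 0.4).astype(int)
        chi2, p = logrank_test(t, e, g)
        ref = ll_logrank(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


class TestCoxFit:
    def test_grid_search_oracle_on_spec_example(self):
        t, e, x = [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [1.0, 0.0, 1.0, 0.0]
        fit = cox_fit_arrays(t, e, np.array(x)[:, None], ["x"], ties="breslow")
        beta_grid = grid_search_cox_beta(t, e, x)
        assert fit.coefficients[0].coef == pytest.approx(beta_grid, abs=1e-4)

    def test_identical_groups_give_hr_one(self):
        t = [1.0, 2.0, 3.0, 4.0] * 2
        e = [1, 1, 0, 1] * 2
        x = [0.0] * 4 + [1.0] * 4
        fit = cox_fit_arrays(t, e, np.array(x)[:, None], ["g"])
        assert fit.coefficients[0].coef == pytest.approx(0.0, abs=1e-8)
        assert fit.coefficients[0].hr == pytest.approx(1.0, abs=1e-8)
        assert fit.logrank_p == pytest.approx(1.0)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 50)  # continuous: no ties a.s.
        e = (rng.random(50) < 0.7).astype(int)
        x = rng.normal(size=(50, 2))
        fe = cox_fit_arrays(t, e, x, ["a", "b"], ties="efron")
        fb = cox_fit_arrays(t, e, x, ["a", "b"], ties="breslow")
        for ce, cb in zip(fe.coefficients, fb.coefficients):
            assert ce.coef == pytest.approx(cb.coef, abs=1e-10)

    def test_matches_lifelines_with_ties_efron(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 150
        x = rng.normal(size=(n, 2))
        t = np.round(rng.exponential(1 / np.exp(0.5 * x[:, 0] - 0.3 * x[:, 1])), 1) + 0.1
        e = (rng.random(n) < 0.7).astype(int)
        fit = cox_fit_arrays(t, e, x, ["a", "b"], ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "a": x[:, 0], "b": x[:, 1]})
        ref = CoxPHFitter().fit(df, "t", "e")
        # lifelines iterates to a looser gradient tolerance, hence 1e-4
        np.testing.assert_allclose(
            [c.coef for c in fit.coefficients], ref.params_.to_numpy(), atol=1e-4
        )
        np.testing.assert_allclose(
            [c.se for c in fit.coefficients], ref.standard_errors_.to_numpy(), atol=1e-4
        )
        assert fit.log_likelihood == pytest.approx(ref.log_likelihood_, abs=1e-4)

    def test_time_rescaling_and_covariate_shift_leave_beta_unchanged(self):
        rng = np.random.default_rng(6)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.4 * x))
        e = (rng.random(n) < 0.8).astype(int)
        base = cox_fit_arrays(t, e, x[:, None], ["x"]).coefficients[0].coef
        scaled = cox_fit_arrays(t * 7.3, e, x[:, None], ["x"]).coefficients[0].coef
        shifted = cox_fit_arrays(t, e, (x + 100.0)[:, None], ["x"]).coefficients[0].coef
        assert scaled == pytest.approx(base, abs=1e-7)
        assert shifted == pytest.approx(base, abs=1e-6)

    def test_negating_binary_covariate_negates_beta(self):
        rng = np.random.default_rng(7)
        n = 60
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / np.exp(0.8 * x))
        e = np.ones(n, dtype=int)
        a = cox_fit_arrays(t, e, x[:, None], ["x"]).coefficients[0].coef
        b = cox_fit_arrays(t, e, (1 - x)[:, None], ["x"]).coefficients[0].coef
        assert a == pytest.approx(-b, abs=1e-7)

    def test_no_events_and_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit_arrays([1.0, 2.0], [0, 0], np.array([[1.0], [0.0]]), ["x"])
        with pytest.raises(ValueError, match="constant"):
            cox_fit_arrays([1.0, 2.0, 3.0], [1, 1, 0], np.ones((3, 1)), ["x"])

    def test_perfect_separation_raises_naming_covariate(self):
        # group 1 always dies first: monotone likelihood
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, dtype=int)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.raises(ConvergenceError, match="sep"):
            cox_fit_arrays(t, e, x[:, None], ["sep_cov"])

    def test_wald_and_logrank_agree_on_rejection_mostly(self):
        agree = 0
        n_data = 200
        for seed in range(n_data):
            rng = np.random.default_rng(10_000 + seed)
            n = 200
            x = (rng.random(n) < 0.5).astype(float)
            t = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
            c = rng.exponential(1 / 0.05, n)
            e = (t <= c).astype(int)
            obs = np.minimum(t, c)
            fit = cox_fit_arrays(obs, e, x[:, None], ["x"])
            wald_rej = fit.coefficients[0].p < 0.05
            lr_rej = fit.logrank_p < 0.05
            agree += wald_rej == lr_rej
        assert agree / n_data >= 0.95


class TestCoxClinical:
    def _clinical(self):
        rng = np.random.default_rng(8)
        n = 120
        stage = rng.choice(["I", "II", "III"], n, p=[0.4, 0.4, 0.2])
        lp = 0.8 * (stage == "II")
        t = rng.exponential(1 / (0.05 * np.exp(lp)))
        return ClinicalTable(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(n)],
                    "os_time": t,
                    "event": 1,
                    "age": rng.normal(65, 8, n).round(1),
                    "sex": rng.choice(["female", "male"], n),
                    "stage": stage,
                }
            )
        )

    def test_complete_case_drops_out_of_contrast_stages(self):
        clin = self._clinical()
        fit = cox_fit(clin, covariates=["stage", "age", "sex"])
        n_outside = int((clin.data["stage"] == "III").sum())
        assert fit.n_dropped_missing == n_outside
        assert fit.n == len(clin) - n_outside
        assert fit.coefficient("stage").coef > 0  # planted stage II excess hazard

    def test_horizon_is_administrative_censoring(self):
        clin = self._clinical()
        full = cox_fit(clin, covariates=["stage"])
        horizon_huge = cox_fit(clin, covariates=["stage"], horizon_months=1e9)
        assert horizon_huge.coefficient("stage").coef == pytest.approx(
            full.coefficient("stage").coef, abs=1e-10
        )
        truncated = cox_fit(clin, covariates=["stage"], horizon_months=10.0)
        assert truncated.n_events < full.n_events


class TestGeneScreen:
    def test_planted_prognostic_gene_ranks_first_in_most_seeds(self):
        wins = 0
        n_seeds = 50
        genes = ["GENE0001"] + [f"GENE{i:04d}" for i in range(2, 26)]
        for seed in range(n_seeds):
            config = SimConfig(seed=20_000 + seed, n_samples=400, planted_beta=np.log(2))
            matrix, clinical, _ = simulate_bulk_cohort(config, ["GENE0001"])
            table = gene_screen(matrix, genes, clinical, dichotomize="median")
            wins += table.iloc[0]["gene"] == "GENE0001"
        assert wins / n_seeds >= 0.9

    def test_horizon_beyond_all_times_equals_no_horizon(self):
        config = SimConfig(seed=30, n_samples=150)
        matrix, clinical, _ = simulate_bulk_cohort(config, ["GENE0001"])
        a = gene_screen(matrix, ["GENE0001", "GENE0002"], clinical, horizon_months=None)
        b = gene_screen(matrix, ["GENE0001", "GENE0002"], clinical, horizon_months=1e9)
        np.testing.assert_allclose(a["coef"].to_numpy(), b["coef"].to_numpy(), atol=1e-10)

    def test_constant_gene_skipped_not_crashed(self):
        config = SimConfig(seed=31, n_samples=100)
        matrix, clinical, _ = simulate_bulk_cohort(config, ["GENE0001"])
        flat = matrix.values.copy()
        flat[matrix.gene_ids.index("GENE0002"), :] = 3.0
        from tregsig import ExpressionMatrix

        m2 = ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, flat, scale=matrix.scale)
        table = gene_screen(m2, ["GENE0001", "GENE0002"], clinical)
        assert "GENE0002" not in set(table["gene"])
        assert "GENE0001" in set(table["gene"])

    def test_bh_q_column_appended_and_sorted_by_p(self):
        config = SimConfig(seed=32, n_samples=200)
        matrix, clinical, _ = simulate_bulk_cohort(config, ["GENE0001"])
        table = gene_screen(matrix, [f"GENE{i:04d}" for i in range(1, 11)], clinical)
        assert table["p_value"].is_monotonic_increasing
        assert "q_value" in table.columns
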