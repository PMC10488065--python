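"""Propensity model, caliper matching and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest

from twamatch import SimConfig, generate_cohort
from twamatch.errors import (
    MissingDataError,
    PerfectSeparationError,
    RankDeficientError,
)
from twamatch.io import cohort_to_dataframe
from twamatch.pipeline import match_cohort
from twamatch.psm import (
    MATCHING_COVARIATES,
    PropensityModel,
    balance_table,
    build_design_matrix,
    fit_propensity,
    match_caliper,
    smd_binary,
    smd_continuous,
)


class TestFitPropensity:
    def test_intercept_only_recovers_group_proportion(self):
        y = np.r_[np.ones(30), np.zeros(70)].astype(bool)
        X = pd.DataFrame(index=range(100))
        model = fit_propensity(X, y)
        assert model.converged
        assert np.allclose(model.fitted_scores, 0.30, atol=1e-8)

    def test_grid_search_oracle_small_instance(self):
        """Newton fit agrees with brute-force likelihood maximization."""
        x = np.array([0.2, 0.5, 1.1, 1.4, 2.0, 2.3, 3.1, 3.4])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=bool)
        model = fit_propensity(pd.DataFrame({"x": x}), y)

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(y @ eta - np.logaddexp(0, eta).sum())

        b0s = np.linspace(-8, 4, 241)
        b1s = np.linspace(-2, 6, 241)
        grid = [(loglik(b0, b1), b0, b1) for b0 in b0s for b1 in b1s]
        best_ll, best_b0, best_b1 = max(grid)
        assert model.log_likelihood >= best_ll - 1e-6
        assert model.coefficients["intercept"] == pytest.approx(best_b0, abs=0.1)
        assert model.coefficients["x"] == pytest.approx(best_b1, abs=0.1)

    def test_agrees_with_reference_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        eta = 0.3 + 0.8 * X["a"] - 0.5 * X["b"]
        y = rng.random(300) < 1 / (1 + np.exp(-eta))
        model = fit_propensity(X, y)
        ref = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
        ours = [model.coefficients[k] for k in ("intercept", "a", "b", "c")]
        assert np.allclose(ours, np.asarray(ref.params), atol=1e-6)

    def test_null_covariate_coefficient_near_zero(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(23)
        x = rng.normal(size=200)
        y = rng.random(200) < 0.4  # independent of x
        model = fit_propensity(pd.DataFrame({"x": x}), y)
        ref = sm.Logit(y.astype(float), sm.add_constant(x)).fit(disp=0)
        lo, hi = np.asarray(ref.conf_int())[1]
        assert lo <= 0.0 <= hi
        assert model.coefficients["x"] == pytest.approx(
            np.asarray(ref.params)[1], abs=1e-6
        )

    def test_perfect_separation_names_the_covariate(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.astype(bool)
        with pytest.raises(PerfectSeparationError) as exc:
            fit_propensity(pd.DataFrame({"sep": x, "noise": np.tile([0.1, 0.9], 10)}), y)
        assert "sep" in exc.value.covariates

    def test_rank_deficiency_lists_collinear_columns(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=50)
        y = rng.random(50) < 0.5
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(RankDeficientError) as exc:
            fit_propensity(X, y)
        assert exc.value.covariates

    def test_missing_values_are_a_hard_error(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0, 0.5]})
        with pytest.raises(MissingDataError):
            fit_propensity(X, [True, False, True, False])


def _model_from_scores(scores, ids=None):
    scores = np.asarray(scores, dtype=float)
    return PropensityModel(
        coefficients={},
        fitted_scores=scores,
        converged=True,
        n_iterations=1,
        log_likelihood=0.0,
        ids=None if ids is None else np.asarray(ids).astype(str),
    )


class TestMatchCaliper:
    def test_identical_scores_match_every_treated_unit(self):
        scores = np.full(10, 0.4)
        treated = np.r_[np.ones(4), np.zeros(6)].astype(bool)
        res = match_caliper(_model_from_scores(scores), treated, caliper_sd=0.1)
        assert res.n_pairs == 4
        assert res.unmatched_treated == []
        assert len(res.unmatched_control) == 2

    def test_caliper_excludes_isolated_treated_unit(self):
        scores = np.array([0.95, 0.30, 0.32, 0.31, 0.29, 0.28])
        treated = np.array([True, True, False, False, False, False])
        res = match_caliper(_model_from_scores(scores), treated, caliper_sd=0.1)
        assert "0" in res.unmatched_treated
        assert res.n_pairs == 1

    def test_hand_executed_greedy_walk(self):
        """5 treated / 7 controls with listed scores: the pair list equals
        the by-hand execution of the descending-greedy nearest rule."""
        t_scores = [0.9, 0.8, 0.6, 0.5, 0.3]
        c_scores = [0.85, 0.7, 0.55, 0.45, 0.35, 0.2, 0.1]
        scores = np.array(t_scores + c_scores)
        treated = np.array([True] * 5 + [False] * 7)
        ids = [f"t{i}" for i in range(5)] + [f"c{i}" for i in range(7)]
        res = match_caliper(
            _model_from_scores(scores, ids), treated, caliper_sd=10.0
        )
        assert res.pairs == [
            ("t0", "c0"),  # 0.9 -> 0.85
            ("t1", "c1"),  # 0.8 -> 0.70
            ("t2", "c2"),  # 0.6 -> 0.55
            ("t3", "c3"),  # 0.5 -> 0.45
            ("t4", "c4"),  # 0.3 -> 0.35
        ]

    def test_every_pair_respects_the_caliper_bound(self, small_cohort_df):
        res = match_cohort(small_cohort_df, caliper_sd=0.1)
        logit = lambda p: np.log(p / (1 - p))
        for t, c in res.pairs:
            d = abs(logit(res.scores[t]) - logit(res.scores[c]))
            assert d <= res.caliper_width + 1e-12

    def test_input_order_permutation_gives_identical_pairs(self, small_cohort_df):
        df = small_cohort_df
        res1 = match_cohort(df, caliper_sd=0.1)
        rng = np.random.default_rng(1)
        perm = df.iloc[rng.permutation(len(df))]
        res2 = match_cohort(perm, caliper_sd=0.1)
        assert sorted(res1.pairs) == sorted(res2.pairs)

    def test_pair_count_monotone_in_caliper(self, small_cohort_df):
        counts = [
            match_cohort(small_cohort_df, caliper_sd=c).n_pairs
            for c in (0.1, 0.2, 0.3, 0.4, 0.5)
        ]
        assert counts == sorted(counts)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            match_caliper(_model_from_scores([0.5, 0.5]), [True, True])


class TestSmd:
    def test_continuous_identical_samples(self):
        assert smd_continuous([1, 2, 3, 4], [1, 2, 3, 4]) == 0.0

    def test_continuous_one_pooled_sd_shift(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        sd = np.sqrt((x.var(ddof=1) + x.var(ddof=1)) / 2)
        assert smd_continuous(x + sd, x) == pytest.approx(1.0, rel=1e-9)

    def test_continuous_hand_listed_vectors(self):
        a = [3.1, 2.9, 3.5, 3.0, 2.7, 3.3, 3.8, 2.5, 3.2, 3.4]
        b = [2.4, 2.8, 2.2, 2.9, 2.6, 2.3, 2.7, 2.1, 2.5, 3.0]
        num = np.mean(a) - np.mean(b)
        den = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2)
        assert smd_continuous(a, b) == pytest.approx(num / den, rel=1e-12)

    def test_continuous_degenerate_variance(self):
        with pytest.warns(UserWarning):
            assert smd_continuous([1, 1, 1], [2, 2, 2]) == -np.inf

    @pytest.mark.parametrize(
        "k_t,n_t,k_c,n_c,expected",
        [
            (131, 565, 2, 204, 0.725),
            (123, 565, 27, 204, 0.226),
            (53, 565, 8, 204, 0.220),
        ],
    )
    def test_binary_reproduces_published_cohort_values(self, k_t, n_t, k_c, n_c, expected):
        assert round(smd_binary(k_t / n_t, k_c / n_c), 3) == expected

    def test_binary_sign_flips_under_group_relabel(self):
        assert smd_binary(0.3, 0.1) == pytest.approx(-smd_binary(0.1, 0.3))

    def test_binary_degenerate_proportions(self):
        assert smd_binary(1.0, 1.0) == 0.0
        with pytest.warns(UserWarning):
            assert smd_binary(1.0, 0.0) == np.inf


class TestBalanceTable:
    def test_unconfounded_cohort_is_balanced(self):
        cfg = SimConfig(
            n_patients=1000, seed=6, assignment_coefficients={"intercept": 0.0}
        )
        records, _ = generate_cohort(cfg)
        df = cohort_to_dataframe(records)
        bal = balance_table(
            df[list(MATCHING_COVARIATES)], (df["group"] == "HPI").to_numpy()
        )
        assert bal.max_abs_smd < 0.2

    def test_matching_restores_balance(self, small_cohort_df):
        res = match_cohort(small_cohort_df, caliper_sd=0.1)
        assert res.balance_before.max_abs_smd > 0.2
        assert res.balance_after.max_abs_smd < res.balance_before.max_abs_smd

    def test_balance_improves_on_average_over_seeds(self):
        before, after = [], []
        for seed in range(20):
            cfg = SimConfig(n_patients=300, seed=100 + seed)
            records, _ = generate_cohort(cfg)
            df = cohort_to_dataframe(records)
            res = match_cohort(df, caliper_sd=0.1)
            before.append(res.balance_before.max_abs_smd)
            after.append(res.balance_after.max_abs_smd)
        assert np.mean(after) < np.mean(before)

    def test_categorical_levels_expanded_with_level_maximum(self, small_cohort_df):
        df = small_cohort_df
        treated = (df["group"] == "HPI").to_numpy()
        bal = balance_table(df[["surgical_approach"]], treated)
        level_rows = [i for i in bal.table.index if i.startswith("surgical_approach=")]
        assert len(level_rows) == 4
        assert bal.table.loc["surgical_approach", "abs_smd"] == pytest.approx(
            bal.table.loc[level_rows, "abs_smd"].max()
        )

    def test_design_matrix_drops_reference_levels(self, small_cohort_df):
        X = build_design_matrix(small_cohort_df)
        assert "surgical_approach[combined]" not in X.columns  # reference level
        assert "surgical_approach[laparotomy]" in X.columns
        assert X.notna().all().all()
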