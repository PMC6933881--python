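"""Statistics chain: breakage formula, screen, OLS, stepwise, path analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

import kernelct as kc
from kernelct import stats as st
from kernelct.datasets import load_path_coefficients


class TestBreakageAndMoisture:
    @pytest.mark.parametrize(
        "pan, s5, s2, expected",
        [(0.0, 12.0, 7.0, 0.0), (10.0, 10.0, 10.0, 1 / 3), (15.0, 10.0, 5.0, 0.5)],
    )
    def test_sieve_mass_fraction(self, pan, s5, s2, expected):
        assert st.breakage_rate(pan, s5, s2) == pytest.approx(expected)

    def test_zero_total_mass_rejected(self):
        with pytest.raises(ValueError):
            st.breakage_rate(0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "wa, wb, expected", [(100.0, 100.0, 0.0), (100.0, 88.5, 0.115), (200.0, 150.0, 0.25)]
    )
    def test_gravimetric_moisture(self, wa, wb, expected):
        assert st.moisture_content(wa, wb) == pytest.approx(expected)

    def test_dry_heavier_than_wet_rejected(self):
        with pytest.raises(ValueError):
            st.moisture_content(90.0, 100.0)

    @given(st_h.floats(0.01, 1000), st_h.floats(0.01, 1000), st_h.floats(0.01, 1000))
    @settings(max_examples=50, deadline=None)
    def test_breakage_rate_always_a_fraction(self, a, b, c):
        assert 0.0 <= st.breakage_rate(a, b, c) <= 1.0


class TestSpearmanScreen:
    def _table(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        return pd.DataFrame({"x": x, "neg": -x, "noise": rng.normal(size=12),
                             "const": 1.0, "y": x})

    def test_identical_predictor_gives_plus_one(self):
        out = st.spearman_screen(self._table(), "y")
        assert out.loc["x", "rho"] == pytest.approx(1.0)
        assert out.loc["x", "stars"] == "**"

    def test_reversed_predictor_gives_minus_one(self):
        out = st.spearman_screen(self._table(), "y")
        assert out.loc["neg", "rho"] == pytest.approx(-1.0)

    def test_constant_column_flagged_not_silent(self):
        out = st.spearman_screen(self._table(), "y")
        assert bool(out.loc["const", "undefined"])

    def test_single_swap_matches_rank_formula(self):
        # brute-force d^2 over ranks: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([6, 5, 4, 3, 1, 2], dtype=float)
        d2 = ((np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))) ** 2).sum()
        expected = 1 - 6 * d2 / (6 * 35)
        table = pd.DataFrame({"x": x, "y": y})
        out = st.spearman_screen(table, "y")
        assert out.loc["x", "rho"] == pytest.approx(expected)

    @given(st_h.integers(1, 6))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transforms(self, power):
        rng = np.random.default_rng(42)
        x = rng.uniform(0.1, 5.0, size=15)
        y = rng.uniform(0.1, 5.0, size=15)
        base = st.spearman_screen(pd.DataFrame({"x": x, "y": y}), "y").loc["x", "rho"]
        trans = st.spearman_screen(
            pd.DataFrame({"x": x**power, "y": np.exp(y)}), "y").loc["x", "rho"]
        assert trans == pytest.approx(base, abs=1e-12)


class TestOLS:
    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = 2.0 + 3.0 * X["a"] - 0.5 * X["b"]
        fit = st.fit_ols(y, X)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.coef["a"] == pytest.approx(3.0)
        assert fit.coef["b"] == pytest.approx(-0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_published_six_variety_regression(self, variety_table):
        y = variety_table["BR_pct"] / 100.0
        fit = st.fit_ols(y, variety_table[["Vsc", "DE"]])
        assert fit.intercept == pytest.approx(1.381, rel=0.02)
        assert fit.coef["DE"] == pytest.approx(-0.724, rel=0.02)
        assert fit.r_squared == pytest.approx(0.991, rel=0.02)

    def test_duplicated_column_raises_naming_it(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a", "b"])
        X["dup"] = X["a"]
        with pytest.raises(np.linalg.LinAlgError, match="a|dup"):
            st.fit_ols(rng.normal(size=15), X)

    def test_simulated_cohort_coefficients_unbiased(self):
        # Monte Carlo: average estimate within 2 SE of truth
        ests = []
        for seed in range(200):
            design = kc.CohortDesign(n_varieties=20, replicates_per_variety=3,
                                     rng_seed=seed)
            t = kc.simulate_cohort_table(design)
            fit = st.fit_ols(t["BR"], t[["Vsc", "DE"]])
            ests.append([fit.coef["Vsc"], fit.coef["DE"]])
        ests = np.asarray(ests)
        mean = ests.mean(axis=0)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        assert abs(mean[0] - 0.010) < 2 * se[0]
        assert abs(mean[1] + 0.724) < 2 * se[1]


class TestStepwise:
    def test_dominant_predictor_selected_among_noise(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = X["c"].to_numpy()  # exactly collinear with one candidate
        res = st.stepwise_select(y, X)
        assert res.selected == ["c"]

    def test_true_two_predictor_model_recovered_reliably(self):
        hits = 0
        for seed in range(100):
            design = kc.CohortDesign(n_varieties=20, replicates_per_variety=3,
                                     rng_seed=seed)
            t = kc.simulate_cohort_table(design)
            res = st.stepwise_select(t["BR"], t[["Vsc", "DE", "SSAg", "SP"]])
            if set(res.selected) == {"Vsc", "DE"}:
                hits += 1
        assert hits >= 90

    def test_no_signal_gives_flagged_empty_model(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        with pytest.warns(UserWarning, match="empty"):
            res = st.stepwise_select(y, X, alpha_in=1e-6)
        assert res.empty and res.fit is None

    def test_trace_never_revisits_a_state(self):
        design = kc.CohortDesign(n_varieties=20, replicates_per_variety=3, rng_seed=0)
        t = kc.simulate_cohort_table(design)
        res = st.stepwise_select(t["BR"], t[["Vsc", "DE", "SSAg", "SP"]])
        states = [frozenset()]
        current: set = set()
        for action, name, _p in res.trace:
            current = set(current)
            current.add(name) if action == "add" else current.remove(name)
            assert frozenset(current) not in states
            states.append(frozenset(current))

    def test_estimator_api_round_trip(self):
        design = kc.CohortDesign(n_varieties=20, replicates_per_variety=3, rng_seed=1)
        t = kc.simulate_cohort_table(design)
        X = t[["Vsc", "DE", "SSAg", "SP"]]
        model = kc.StepwiseRegressor().fit(X, t["BR"])
        assert set(model.selected_) == {"Vsc", "DE"}
        assert model.get_params() == {"alpha_in": 0.05, "alpha_out": 0.05}
        pred = model.predict(X)
        resid = t["BR"].to_numpy() - pred
        assert np.sqrt((resid**2).mean()) < 0.01


class TestPathAnalysis:
    def test_total_effects_reproduce_correlations(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("wxyz"))
        X["x"] += 0.7 * X["w"]  # correlated predictors
        y = X @ np.array([0.5, -1.0, 0.2, 0.0]) + rng.normal(scale=0.3, size=50)
        res = st.path_analysis(y, X)
        assert np.allclose(res.total, res.correlations_with_response, atol=1e-6)

    def test_orthonormal_predictors_have_zero_indirect_effects(self):
        n = 64
        X = pd.DataFrame({
            "a": np.tile([1.0, -1.0], n // 2),
            "b": np.repeat([1.0, -1.0], n // 2),
        })
        rng = np.random.default_rng(6)
        y = 0.8 * X["a"] - 0.3 * X["b"] + rng.normal(scale=0.2, size=n)
        res = st.path_analysis(y, X)
        off_diag = res.indirect.to_numpy()[~np.eye(2, dtype=bool)]
        assert np.allclose(off_diag, 0.0, atol=1e-12)
        assert np.allclose(res.direct, res.correlations_with_response, atol=1e-9)

    def test_published_decomposition_row_sums(self):
        table = load_path_coefficients()
        direct = table["direct"]
        indirect = table["indirect"]
        x4 = direct["X4"] + sum(indirect["X4"].values())
        x3 = direct["X3"] + sum(indirect["X3"].values())
        assert x4 == pytest.approx(-0.934, abs=0.001)  # density-breakage r
        assert x3 == pytest.approx(-0.714, abs=0.001)  # sphericity-breakage r

    def test_estimator_exposes_fitted_decomposition(self, variety_table):
        y = variety_table["BR_pct"] / 100.0
        model = kc.PathAnalysis().fit(variety_table[["Vsc", "DE"]], y)
        assert np.allclose(model.total_, model.correlations_, atol=1e-6)
        assert np.isnan(model.indirect_.loc["Vsc", "Vsc"])


class TestAnovaLetters:
    def test_identical_groups_share_one_letter(self):
        g = {k: np.array([5.0, 5.1, 4.9]) for k in "ABC"}
        out = st.anova_letters(g)
        assert set(out["letters"]) == {"a"}

    def test_two_far_groups_get_distinct_letters(self):
        rng = np.random.default_rng(7)
        g = {"lo": rng.normal(0, 0.01, 3), "hi": rng.normal(100, 0.01, 3)}
        out = st.anova_letters(g)
        assert out.loc["hi", "letters"] != out.loc["lo", "letters"]

    def test_close_pair_shares_letter_far_group_does_not(self):
        rng = np.random.default_rng(12)
        g = {"a1": rng.normal(0.0, 0.05, 5), "a2": rng.normal(0.1, 0.05, 5),
             "far": rng.normal(10.0, 0.05, 5)}
        out = st.anova_letters(g)
        # oracle: direct pairwise t-tests
        from scipy.stats import ttest_ind
        assert ttest_ind(g["a1"], g["a2"]).pvalue > 0.05
        assert ttest_ind(g["a1"], g["far"]).pvalue < 0.05
        assert set(out.loc["a1", "letters"]) & set(out.loc["a2", "letters"])
        assert not set(out.loc["far", "letters"]) & set(out.loc["a1", "letters"])

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            st.anova_letters({"a": [1.0], "b": [2.0]})
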