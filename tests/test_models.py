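"""Design construction, OLS/REML fits, descriptive tests, harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wmhcontrast import (
    ModelSpec,
    build_design,
    chi_square,
    fit_ols,
    fit_random_intercept,
    harmonize_vascular_columns,
    welch_t,
)
from wmhcontrast.models import DesignError, RankDeficientError



class TestModelSpec:
    def test_interaction_requires_longitudinal(self):
        with pytest.raises(ValueError, match="longitudinal"):
            ModelSpec("severity", ("B", "A"), interaction=True)

    def test_formula_echoes_model_structure(self):
        spec = ModelSpec("log_total", ("B", "A"), "vascular",
                         longitudinal=True, interaction=True)
        f = spec.formula
        assert "Diabetes" in f and "Group:TimeFromBaseline" in f and "(1|ID)" in f


class TestBuildDesign:
    def test_column_count_base(self, tiny_cohort):
        spec = ModelSpec("severity", ("B", "A"))
        y, X, ids, dropped = build_design(tiny_cohort, spec)
        # intercept + group + age + sex + education + 2 diagnosis dummies
        assert X.shape[1] == 7
        assert dropped == 0

    def test_vascular_adds_three_columns(self, tiny_cohort):
        base = build_design(tiny_cohort, ModelSpec("severity", ("B", "A")))[1]
        vasc = build_design(
            tiny_cohort, ModelSpec("severity", ("B", "A"), "vascular")
        )[1]
        assert vasc.shape[1] == base.shape[1] + 3

    def test_zero_volume_maps_to_zero_log(self, tiny_cohort):
        tab = tiny_cohort.copy()
        tab.loc[tab.index[0], "wmh_occipital_mm3"] = 0.0
        y, X, _, _ = build_design(tab, ModelSpec("log_occipital", ("B", "A")))
        assert y[0] == 0.0

    def test_reference_coding(self, tiny_cohort):
        _, X, _, _ = build_design(tiny_cohort, ModelSpec("severity", ("B", "A")))
        grp = X["group"].to_numpy()
        assert set(grp) == {0.0, 1.0}
        assert grp.sum() == 3  # three B rows coded 1

    def test_missing_group_rejected(self, tiny_cohort):
        with pytest.raises(DesignError, match="absent"):
            build_design(tiny_cohort, ModelSpec("severity", ("C", "A")))

    def test_incomplete_cases_dropped_and_counted(self, tiny_cohort):
        tab = tiny_cohort.copy()
        tab.loc[tab.index[0], "education"] = np.nan
        y, X, _, dropped = build_design(tab, ModelSpec("severity", ("B", "A")))
        assert dropped == 1 and len(y) == 5

    def test_all_missing_rejected(self, tiny_cohort):
        tab = tiny_cohort.copy()
        tab["age"] = np.nan
        with pytest.raises(DesignError, match="zero complete cases"):
            build_design(tab, ModelSpec("severity", ("B", "A")))

    def test_constant_column_rejected(self, tiny_cohort):
        tab = tiny_cohort.copy()
        tab["sex"] = 1
        with pytest.raises(DesignError, match="sex"):
            build_design(tab, ModelSpec("severity", ("B", "A")))

    def test_interaction_uses_baseline_age(self, small_cohort):
        spec = ModelSpec("log_total", ("B", "A"),
                         longitudinal=True, interaction=True)
        _, X, ids, _ = build_design(small_cohort, spec)
        ages = pd.DataFrame({"id": ids, "age": X["age"]})
        assert (ages.groupby("id")["age"].nunique() == 1).all()
        assert "time_years" in X and "group_x_time" in X


class TestFitOLS:
    def test_matches_pseudoinverse_oracle(self):
        """Coefficients equal an independent pinv solve on random designs."""
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(10, 51))
            p = int(rng.integers(2, 9))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            fit = fit_ols(y, X)
            oracle = np.linalg.pinv(X) @ y
            worst = max(worst, float(np.max(np.abs(fit.estimates - oracle))))
        assert worst < 1e-8

    def test_six_point_hand_dataset(self):
        """Closed-form check on a dataset small enough to solve by hand."""
        X = np.array([[1, 0], [1, 1], [1, 2], [1, 3], [1, 4], [1, 5]], float)
        y = np.array([1.0, 2.9, 5.1, 7.0, 9.2, 10.8])
        fit = fit_ols(y, X, names=["const", "x"])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        assert np.allclose(fit.estimates, beta, atol=1e-10)
        resid = y - X @ beta
        s2 = resid @ resid / (6 - 2)
        assert np.allclose(fit.se, np.sqrt(np.diag(s2 * XtX_inv)), atol=1e-10)

    def test_t_equals_estimate_over_se(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        y = rng.normal(size=30)
        fit = fit_ols(y, X)
        assert np.max(np.abs(fit.tstats - fit.estimates / fit.se)) < 1e-10

    def test_exact_fit_flagged(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 2.0 + 3.0 * np.arange(10.0)
        fit = fit_ols(y, X)
        assert fit.exact_fit
        assert np.all(np.isinf(fit.tstats) | (fit.se == 0) | (np.abs(fit.tstats) > 1e6))

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame(
            {"const": 1.0, "a": np.arange(10.0), "b": 2 * np.arange(10.0)}
        )
        with pytest.raises(RankDeficientError, match="b"):
            fit_ols(np.zeros(10), X)


class TestFitRandomIntercept:
    def test_balanced_closed_form(self):
        """Balanced one-way layout: REML equals the mean-squares solution."""
        rng = np.random.default_rng(5)
        m, k = 60, 3
        u = rng.normal(0, 1.0, m)
        y = (u[:, None] + rng.normal(0, 0.5, (m, k))).ravel()
        ids = np.repeat(np.arange(m), k)
        fit = fit_random_intercept(y, np.ones((m * k, 1)), ids, names=["const"])
        ybar = y.reshape(m, k).mean(1)
        msb = k * np.var(ybar, ddof=1)
        msw = np.sum((y.reshape(m, k) - ybar[:, None]) ** 2) / (m * (k - 1))
        assert abs(fit.sigma2_resid - msw) < 1e-6
        assert abs(fit.sigma2_subject - max((msb - msw) / k, 0)) < 1e-6

    def test_boundary_reduces_to_ols(self):
        """Zero between-subject variance: GLS collapses to OLS exactly."""
        a = np.arange(1.0, 9.0)
        y = np.concatenate([a, -a])  # every subject mean is 0
        ids = np.tile(np.arange(8), 2)
        X = np.ones((16, 1))
        mixed = fit_random_intercept(y, X, ids, names=["const"])
        ols = fit_ols(y, X, names=["const"])
        assert mixed.boundary
        assert mixed.sigma2_subject == 0.0
        assert np.max(np.abs(mixed.estimates - ols.estimates)) < 1e-6
        assert np.max(np.abs(mixed.se - ols.se)) < 1e-6

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(11)
        m, k = 500, 3
        u = rng.normal(0, 1.0, m)
        ids = np.repeat(np.arange(m), k)
        x = rng.normal(size=m * k)
        y = 1.0 + 0.3 * x + u[ids] + rng.normal(0, 0.5, m * k)
        X = np.column_stack([np.ones(m * k), x])
        fit = fit_random_intercept(y, X, ids, names=["const", "x"])
        assert abs(fit.sigma2_subject - 1.0) < 0.1
        assert abs(fit.sigma2_resid - 0.25) < 0.025

    def test_agrees_with_statsmodels(self):
        """Independent cross-check against MixedLM REML."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        m = 80
        u = rng.normal(0, 0.9, m)
        ids = np.repeat(np.arange(m), 3)
        x = rng.normal(size=m * 3)
        y = 2.0 + 0.7 * x + u[ids] + rng.normal(0, 0.6, m * 3)
        X = np.column_stack([np.ones(m * 3), x])
        mine = fit_random_intercept(y, X, ids, names=["const", "x"])
        ref = sm.MixedLM(y, X, groups=ids).fit(reml=True)
        assert np.max(np.abs(mine.estimates - np.asarray(ref.fe_params))) < 1e-5
        assert np.max(np.abs(mine.se - np.asarray(ref.bse_fe))) < 1e-3
        assert abs(mine.sigma2_subject - float(np.asarray(ref.cov_re)[0, 0])) < 1e-3
        assert abs(mine.sigma2_resid - ref.scale) < 1e-3

    def test_requires_repeated_visits(self):
        y = np.arange(4.0)
        X = np.ones((4, 1))
        with pytest.raises(DesignError, match="repeated"):
            fit_random_intercept(y, X, np.arange(4), names=["const"])


class TestWelchT:
    # Printed cohort summaries (mean, sd, n) per group and the published
    # t-statistic each pair reproduces.
    CASES = [
        ("education_black_white", (15.08, 2.81, 892), (16.31, 2.67, 7132), -12.38),
        ("bmi_black_white", (29.13, 6.04, 892), (26.72, 5.00, 7132), 11.46),
        ("age_black_white", (72.26, 8.82, 892), (71.36, 9.23, 7132), 2.85),
        ("bmi_asian_white", (23.90, 3.73, 283), (26.72, 5.00, 7132), -12.30),
        ("education_hispanic", (13.61, 4.54, 661), (16.18, 2.73, 8307), -14.39),
        ("bmi_hispanic", (28.09, 5.04, 661), (26.89, 5.17, 8307), 5.86),
        ("education_black_white_mri", (14.53, 3.09, 260), (15.93, 2.85, 1876), -6.87),
    ]

    @pytest.mark.parametrize("name,g1,g2,expected", CASES, ids=[c[0] for c in CASES])
    def test_published_summary_statistics(self, name, g1, g2, expected):
        t, dof, p = welch_t(*g1, *g2)
        assert t == pytest.approx(expected, rel=0.01)
        assert p < 0.01

    def test_identical_groups(self):
        t, dof, p = welch_t(10.0, 2.0, 50, 10.0, 2.0, 50)
        assert t == 0.0 and p == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.floats(-5, 5), st.floats(0.5, 3), st.integers(5, 500),
        st.floats(-5, 5), st.floats(0.5, 3), st.integers(5, 500),
    )
    def test_antisymmetry(self, m1, s1, n1, m2, s2, n2):
        t_ab, _, p_ab = welch_t(m1, s1, n1, m2, s2, n2)
        t_ba, _, p_ba = welch_t(m2, s2, n2, m1, s1, n1)
        assert t_ab == pytest.approx(-t_ba, abs=1e-12)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            welch_t(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            welch_t(1, 1.0, 1, 2, 1.0, 10)


class TestChiSquare:
    def test_identical_proportions_zero(self):
        chi2, dof, p = chi_square([[10, 10], [10, 10]])
        assert chi2 == 0.0 and dof == 1

    def test_against_expected_count_oracle(self):
        """Pearson statistic equals the direct sum over cells."""
        table = np.array([[30.0, 10.0], [10.0, 30.0]])
        chi2, dof, p = chi_square(table)
        total = table.sum()
        oracle = 0.0
        for i in range(2):
            for j in range(2):
                e = table[i].sum() * table[:, j].sum() / total
                oracle += (table[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(oracle, abs=1e-12)
        assert dof == 1

    def test_row_swap_and_column_permutation_invariance(self):
        table = np.array([[25.0, 30.0, 45.0], [40.0, 20.0, 10.0]])
        chi2, dof, _ = chi_square(table)
        chi2_swapped = chi_square(table[::-1])[0]
        chi2_perm = chi_square(table[:, [2, 0, 1]])[0]
        assert chi2 == pytest.approx(chi2_swapped, abs=1e-10)
        assert chi2 == pytest.approx(chi2_perm, abs=1e-10)
        assert dof == 2

    def test_published_sex_contingency(self):
        """Male counts by race from the printed cohort table."""
        chi2, dof, p = chi_square([[244, 892 - 244], [3364, 7132 - 3364]])
        assert chi2 == pytest.approx(124.97, rel=0.01)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square([[0, 0], [5, 5]])


class TestHarmonizeVascular:
    def test_merge_rules(self):
        raw = pd.DataFrame(
            {
                "HYPERT": [0, 0, np.nan, np.nan, 1],
                "HXHYPER": [0, np.nan, np.nan, 0, 0],
                "HYPERTEN": [0, 1, np.nan, np.nan, 0],
                "DIABET": [0, 1, np.nan, 0, np.nan],
                "DIABETES": [0, np.nan, np.nan, 0, 1],
                "NACCBMI": [26.5, 31.0, 11.0, 72.0, 24.0],
            }
        )
        out = harmonize_vascular_columns(raw)
        assert out["hypertension"].tolist()[0] == 0  # (0,0,0) -> 0
        assert out["hypertension"].tolist()[1] == 1  # (0,missing,1) -> 1
        assert np.isnan(out["hypertension"].tolist()[2])  # all missing
        assert np.isnan(out["hypertension"].tolist()[3])  # (na,0,na): not all known 0
        assert out["diabetes"].tolist()[0] == 0
        assert out["diabetes"].tolist()[1] == 1
        assert np.isnan(out["bmi"].iloc[2]) and np.isnan(out["bmi"].iloc[3])
        assert out["bmi"].iloc[0] == 26.5

    def test_absent_sources_rejected(self):
        with pytest.raises(ValueError, match="source columns"):
            harmonize_vascular_columns(pd.DataFrame({"DIABET": [0, 1]}))
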