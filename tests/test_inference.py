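"""Contingency-table statistics and the IRLS logistic regression."""
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from actiqol import (
    ContingencyTable2x2,
    LogisticModelSpec,
    LogisticRegressionIRLS,
    chi_square_independence,
    fit_logistic,
    odds_ratio,
    two_sample_t,
)
from actiqol.inference import RankDeficiencyError, SeparationError


class TestOddsRatio:
    def test_identity_table(self):
        r = odds_ratio(ContingencyTable2x2(1, 1, 1, 1))
        assert r.odds_ratio == pytest.approx(1.0)
        # CI symmetric about 1 on the log scale
        assert math.log(r.ci_high) == pytest.approx(-math.log(r.ci_low))

    def test_zero_cell_gets_continuity_correction(self):
        r = odds_ratio(ContingencyTable2x2(0, 5, 10, 5))
        assert r.corrected
        assert np.isfinite([r.odds_ratio, r.ci_low, r.ci_high]).all()

    def test_from_labels_orientation(self):
        exposed = [0, 0, 1, 1, 1]
        high = [0, 1, 0, 1, 1]
        t = ContingencyTable2x2.from_labels(exposed, high)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 200, 4)
            r = odds_ratio(ContingencyTable2x2(a, b, c, d))
            assert r.odds_ratio == pytest.approx((a * d) / (b * c))


class TestChiSquare:
    def test_perfectly_proportional_table(self):
        stat, df, p = chi_square_independence([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 5]])

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            obs = rng.integers(1, 100, size=(rng.integers(2, 4), rng.integers(2, 4)))
            stat, df, p = chi_square_independence(obs)
            ref = scipy.stats.chi2_contingency(obs, correction=False)
            assert stat == pytest.approx(ref.statistic)
            assert df == ref.dof
            assert p == pytest.approx(ref.pvalue)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, _, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_textbook_fixture(self):
        # hand computation: means 5 and 3, pooled sd 1, n = 4 each
        x = [4.0, 5.0, 5.0, 6.0]
        y = [2.0, 3.0, 3.0, 4.0]
        t, df, p = two_sample_t(x, y)
        sp2 = (3 * (2 / 3) + 3 * (2 / 3)) / 6
        expected_t = 2.0 / math.sqrt(sp2 * 0.5)
        assert t == pytest.approx(expected_t)
        assert df == 6

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_scipy(self, rng, equal_var):
        for _ in range(25):
            x = rng.normal(0, 1, int(rng.integers(5, 40)))
            y = rng.normal(0.3, 1.4, int(rng.integers(5, 40)))
            t, _, p = two_sample_t(x, y, equal_var=equal_var)
            ref = scipy.stats.ttest_ind(x, y, equal_var=equal_var)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_age_contrast_at_study_moments(self, rng):
        """Groups synthesized to the study's age moments give p < .01."""

        def exact_moments(n, mean, sd):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        low = exact_moments(293, 45.43, 11.72)
        high = exact_moments(1005, 43.18, 12.34)
        _, _, p = two_sample_t(low, high)
        assert p < 0.01
        assert p == pytest.approx(0.006, abs=0.002)


class TestLogisticIRLS:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        est = LogisticRegressionIRLS().fit(np.empty((100, 0)), y)
        assert est.params_["intercept"] == pytest.approx(math.log(30 / 70))
        assert est.converged_

    def test_saturated_fit_equals_contingency_or(self):
        x = np.array([0] * 293 + [1] * 1005)
        y = np.array([0] * 243 + [1] * 50 + [0] * 762 + [1] * 243)
        # exposure x, outcome y: cross-product OR
        est = LogisticRegressionIRLS().fit(pd.DataFrame({"x": x}), y)
        table = ContingencyTable2x2.from_labels(exposed=x, outcome_high=y)
        assert math.exp(est.params_["x"]) == pytest.approx(
            odds_ratio(table).odds_ratio, rel=1e-10
        )

    def test_matches_statsmodels(self, rng):
        n = 400
        X = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.integers(0, 2, n).astype(float),
                "x3": rng.normal(size=n),
            }
        )
        lp = -0.3 + 0.8 * X.x1 - 0.5 * X.x2
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        est = LogisticRegressionIRLS().fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            est.params_.to_numpy(), ref.params.to_numpy(), rtol=1e-6
        )
        np.testing.assert_allclose(
            est.bse_.to_numpy(), ref.bse.to_numpy(), rtol=1e-5
        )

    def test_separation_detected_and_named(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = x.copy()
        with pytest.raises(SeparationError) as exc:
            LogisticRegressionIRLS().fit(pd.DataFrame({"sep_var": x}), y)
        assert exc.value.term == "sep_var"

    def test_rank_deficiency_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(RankDeficiencyError) as exc:
            LogisticRegressionIRLS().fit(X, y)
        assert set(exc.value.terms) & {"a", "b"}

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError):
            LogisticRegressionIRLS().fit(np.ones((5, 1)), np.array([0, 1, 2, 1, 0]))

    def test_predict_proba_bounds(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=80)})
        y = (rng.random(80) < 0.4).astype(float)
        est = LogisticRegressionIRLS().fit(X, y)
        p = est.predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_wald_ci_coverage_single_covariate(self):
        """~95% CI coverage for a true OR of 1.6 at n = 2000."""
        rng = np.random.default_rng(1234)
        true_beta = math.log(1.6)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = (rng.random(2000) < 0.3).astype(float)
            p = 1 / (1 + np.exp(-(-0.2 + true_beta * x)))
            y = (rng.random(2000) < p).astype(float)
            est = LogisticRegressionIRLS().fit(pd.DataFrame({"x": x}), y)
            lo, hi = est.conf_int().loc["x"]
            hits += int(lo <= true_beta <= hi)
        assert hits / reps >= 0.93


class TestModelSpec:
    def test_categorical_encoding_uses_reference_levels(self):
        df = pd.DataFrame(
            {
                "qol_label": ["high", "low", "high", "low"] * 10,
                "meets_ab": [1, 0, 0, 1] * 10,
                "sex": ["male", "female", "female", "male"] * 10,
                "age": np.linspace(20, 60, 40),
            }
        )
        from actiqol.inference import build_design

        X, y = build_design(
            df, LogisticModelSpec(covariates=["age", "sex"])
        )
        assert list(X.columns) == ["meets_ab", "age", "sex[female]"]
        assert y.sum() == 20

    def test_missing_reference_level_rejected(self):
        df = pd.DataFrame(
            {
                "qol_label": ["high", "low"] * 5,
                "meets_ab": [1, 0] * 5,
                "sex": ["female"] * 10,
            }
        )
        with pytest.raises(ValueError, match="reference level"):
            fit_logistic(LogisticModelSpec(covariates=["sex"]), df)

    def test_missing_values_fail_fast(self):
        df = pd.DataFrame(
            {
                "qol_label": ["high", "low"] * 5,
                "meets_ab": [1, 0] * 5,
                "age": [30.0, np.nan] * 5,
            }
        )
        with pytest.raises(ValueError, match="missing"):
            fit_logistic(LogisticModelSpec(covariates=["age"]), df)
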