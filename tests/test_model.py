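"""Logistic model: encoding, IRLS fitting, inference and concordance."""
import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from temporeg.errors import (CollinearityError, ConvergenceWarning, DataError)
from temporeg.model import (DesignSpec, LogisticModel, bivariate_table,
                            concordance, encode_design, fit_adjusted)


def _xy(x_cols: dict, y):
    X = pd.DataFrame({"intercept": np.ones(len(y)), **x_cols})
    return LogisticModel(X, np.asarray(y, float))


class TestFit:
    def test_intercept_only_equals_logit_of_prevalence(self):
        y = np.r_[np.ones(20), np.zeros(80)]
        res = _xy({}, y).fit()
        assert res.intercept == pytest.approx(np.log(0.20 / 0.80), abs=1e-8)

    def test_two_by_two_table_recovers_empirical_odds_ratio(self):
        # exposed 30/70, unexposed 10/90 -> OR = (30*90)/(70*10)
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        res = _xy({"exposed": x}, y).fit()
        assert np.exp(res.params["exposed"]) == pytest.approx(270 / 70, rel=1e-7)

    def test_perfect_separation_flags_nonconvergence(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        with pytest.warns(ConvergenceWarning):
            res = _xy({"x": x}, x.copy()).fit()
        assert not res.converged

    def test_deviance_is_nonincreasing_across_iterations(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = rng.random(500) < 1 / (1 + np.exp(-(0.5 + 0.8 * x)))
        res = _xy({"x": x}, y).fit()
        assert np.all(np.diff(res.deviance_trace) <= 1e-9)

    def test_sum_of_fitted_probabilities_equals_event_count(self, scored_cohort):
        res = fit_adjusted(scored_cohort)
        assert res.fittedvalues.sum() == pytest.approx(
            scored_cohort["flagged"].sum(), abs=1e-8)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(DataError):
            _xy({}, np.ones(10))

    def test_collinear_design_names_terms(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = np.r_[np.ones(10), np.zeros(10), np.ones(10), np.zeros(10)]
        with pytest.raises(CollinearityError, match="x_copy"):
            _xy({"x": x, "x_copy": x}, y).fit()

    def test_agrees_with_reference_mle(self, scored_cohort):
        """Coefficients and Wald SEs match an independent ML implementation.

        Restricted to well-populated predictors: rare conditions can be
        quasi-separated in a small cohort, where the MLE is unbounded and
        any two stopping rules disagree.
        """
        sm = pytest.importorskip("statsmodels.api")
        spec = DesignSpec(
            categoricals=DesignSpec.default().categoricals,
            binaries=("diabetes", "hypertension", "osteoporosis", "anxiety",
                      "depression", "current_smoker"))
        res = fit_adjusted(scored_cohort, spec)
        X = res.model.X
        ref = sm.Logit(res.model.y, X).fit(disp=0, method="newton")
        np.testing.assert_allclose(res.params.to_numpy(), ref.params,
                                   rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(res.bse.to_numpy(), ref.bse,
                                   rtol=1e-5, atol=1e-8)


class TestResults:
    def test_ci_and_or_consistency(self, scored_cohort):
        res = fit_adjusted(scored_cohort)
        tab = res.table()
        assert np.allclose(tab["or"], np.exp(tab["coefficient"]))
        assert np.allclose(tab["ci_low"],
                           np.exp(tab["coefficient"] - 1.96 * tab["se"]))
        assert ((tab["ci_low"] <= tab["or"]) & (tab["or"] <= tab["ci_high"])).all()
        assert set(tab.loc[tab["p_value"] < 0.001, "marker"]) <= {"†"}

    def test_summary_mentions_significance_convention(self, scored_cohort):
        text = fit_adjusted(scored_cohort).summary()
        assert "p < 0.05" in text and "p < 0.001" in text
        assert "c-statistic" in text

    def test_all_reference_patient_prediction_is_logistic_intercept(self):
        y = np.r_[np.ones(15), np.zeros(35), np.ones(10), np.zeros(40)]
        res = _xy({"x": np.r_[np.ones(50), np.zeros(50)]}, y).fit()
        row = pd.DataFrame({"intercept": [1.0], "x": [0.0]})
        assert res.predict(row)[0] == pytest.approx(
            1 / (1 + np.exp(-res.intercept)))

    def test_mean_prediction_equals_event_rate(self, scored_cohort):
        res = fit_adjusted(scored_cohort)
        assert res.fittedvalues.mean() == pytest.approx(
            scored_cohort["flagged"].mean(), abs=1e-10)

    def test_predict_requires_all_features(self, scored_cohort):
        res = fit_adjusted(scored_cohort)
        with pytest.raises(DataError, match="missing"):
            res.predict(pd.DataFrame({"intercept": [1.0]}))


class TestEncodeDesign:
    def test_reference_patient_encodes_to_zero_indicators(self, scored_cohort):
        ref = scored_cohort.iloc[[0]].copy()
        ref[["age_group", "sex", "ethnic_group", "region", "ses_group",
             "egfr_category"]] = ["40-49", "female", "general", "central",
                                  "highest", "60+"]
        for c in DesignSpec.default().binaries:
            ref[c] = False
        X, _ = encode_design(ref, drop_empty=False)
        assert X.drop(columns="intercept").to_numpy().sum() == 0

    def test_male_indicator(self, scored_cohort):
        X, y = encode_design(scored_cohort)
        assert np.array_equal(X["sex:male"].to_numpy(dtype=bool),
                              (scored_cohort["sex"] == "male").to_numpy())
        assert y.sum() == scored_cohort["flagged"].sum()

    def test_unseen_level_is_an_error(self, scored_cohort):
        bad = scored_cohort.copy()
        bad.loc[bad.index[0], "region"] = "atlantis"
        with pytest.raises(DataError, match="atlantis"):
            encode_design(bad)

    def test_all_zero_indicator_dropped_with_warning(self, scored_cohort):
        sub = scored_cohort[scored_cohort["ethnic_group"] != "ultra_orthodox"]
        with pytest.warns(UserWarning, match="ultra_orthodox"):
            X, _ = encode_design(sub)
        assert "ethnic_group:ultra_orthodox" not in X.columns


class TestConcordance:
    def test_perfect_and_constant_ranking(self):
        assert concordance([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert concordance([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_counted_example(self):
        assert concordance([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_degenerate_outcome(self):
        with pytest.raises(DataError):
            concordance([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        p = np.round(rng.random(n), 1)  # coarse grid forces ties
        y = rng.random(n) < 0.3
        if y.all() or not y.any():
            y[:2] = [True, False]
        num = sum(1.0 if pi > pj else 0.5 if pi == pj else 0.0
                  for pi, pj in itertools.product(p[y], p[~y]))
        assert concordance(p, y) == pytest.approx(num / (y.sum() * (~y).sum()))


class TestBivariate:
    def test_one_row_per_nonreference_level(self, scored_cohort):
        tab = bivariate_table(scored_cohort)
        spec = DesignSpec.default()
        expected_terms = set(spec.term_names())
        produced = set(tab["term"])
        # levels absent from the sample are dropped, never invented
        assert produced <= expected_terms
        assert len(produced) > 30
        assert (tab.groupby("predictor").size() >= 1).all()

    def test_failures_do_not_abort_other_predictors(self, scored_cohort):
        frozen = scored_cohort.copy()
        frozen["dementia"] = False  # no variation -> that model degenerates
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = bivariate_table(frozen)
        assert "sex:male" in set(tab["term"])
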