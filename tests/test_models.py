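"""Nested-CV forest evaluation, metrics, report layout, Shapley axioms."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from moodspeech.attribution import ShapleyExplainer, shapley_attribution
from moodspeech.models import (
    FeatureSetSpec,
    FoldMetrics,
    ModelEvaluation,
    NestedForestEvaluator,
    TunedForestRegressor,
    build_design,
    format_report,
    nested_cv_evaluate,
    regression_metrics,
    report_table,
    standard_feature_sets,
)
from moodspeech.synthdata import CohortSpec, generate_cohort

FAST_GRID = {"n_estimators": [50], "max_depth": [None, 4], "min_samples_leaf": [2]}


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(
        CohortSpec(n=80, effect_map={"s": ("madrs", 0.6), "n1": ("madrs", 0.0)},
                   seed=21)
    )


class TestMetrics:
    def test_zero_variance_truth_r2_missing(self):
        r2, mse, mae = regression_metrics([0, 0], [1, 1])
        assert np.isnan(r2)
        assert mse == 1.0 and mae == 1.0

    def test_perfect_prediction(self):
        assert regression_metrics([1, 2, 3], [1, 2, 3]) == (1.0, 0.0, 0.0)

    def test_constant_prediction_hand_value(self):
        r2, mse, mae = regression_metrics([1, 2, 3], [2, 2, 2])
        assert (r2, mse, mae) == pytest.approx((0.0, 2 / 3, 2 / 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([1, 2], [1])


class TestFeatureSets:
    def test_combined_is_union(self):
        sets = standard_feature_sets()
        assert set(sets["combined"].columns) == (
            set(sets["nlp_conversational"].columns) | set(sets["acoustic"].columns)
        )

    def test_empty_columns_rejected(self):
        with pytest.raises(ValueError):
            FeatureSetSpec("x", ())

    def test_sex_adjustment_appends_encoded_column(self, small_cohort):
        spec = FeatureSetSpec("s", ("s",), adjust_sex=True)
        X, y, dropped = build_design(small_cohort, spec, "madrs")
        assert "sex_code" in X.columns
        codes = X["sex_code"].to_numpy()
        female = (small_cohort["sex"] == "female").to_numpy()
        assert np.array_equal(codes.astype(bool), female)

    def test_missing_rows_dropped_and_counted(self, small_cohort):
        t = small_cohort.copy()
        t.loc[t.index[:5], "s"] = np.nan
        X, y, dropped = build_design(t, FeatureSetSpec("s", ("s",)), "madrs")
        assert dropped == 5
        assert len(X) == len(t) - 5


class TestNestedCV:
    def test_same_seed_reproduces_evaluation(self, small_cohort):
        spec = FeatureSetSpec("s", ("s", "n1"))
        kwargs = dict(grid=FAST_GRID, random_state=7)
        ev1 = NestedForestEvaluator(**kwargs).evaluate(small_cohort, spec, "madrs")
        ev2 = NestedForestEvaluator(**kwargs).evaluate(small_cohort, spec, "madrs")
        assert ev1.to_dict() == ev2.to_dict()

    def test_outer_folds_partition_rows(self, small_cohort):
        ev = NestedForestEvaluator(grid=FAST_GRID, random_state=0).evaluate(
            small_cohort, FeatureSetSpec("s", ("s",)), "madrs"
        )
        assert sum(f.n_test for f in ev.per_fold) == ev.n_rows_used
        assert len(ev.per_fold) == 5

    def test_mae_squared_bounded_by_mse_each_fold(self, small_cohort):
        ev = NestedForestEvaluator(grid=FAST_GRID, random_state=1).evaluate(
            small_cohort, FeatureSetSpec("s", ("s",)), "madrs"
        )
        for f in ev.per_fold:
            assert f.mae**2 <= f.mse + 1e-9

    def test_too_few_rows_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="10"):
            nested_cv_evaluate(small_cohort.head(6), FeatureSetSpec("s", ("s",)),
                               "madrs")

    def test_undersized_test_fold_aborts(self, small_cohort):
        with pytest.raises(ValueError, match="fold"):
            NestedForestEvaluator(
                grid=FAST_GRID, outer_folds=41, stratify_by_quartile=False,
                random_state=0,
            ).evaluate(small_cohort, FeatureSetSpec("s", ("s",)), "madrs")

    def test_violating_jensen_bound_is_rejected_at_construction(self):
        with pytest.raises(AssertionError):
            ModelEvaluation(
                per_fold=[FoldMetrics(0, 0.5, 1.0, 1.5, 10, 5)],
                target="madrs", spec=FeatureSetSpec("x", ("x",)), seed=0,
                n_rows_used=15, n_rows_dropped=0,
            )

    def test_tuned_forest_sklearn_protocol(self, small_cohort):
        model = TunedForestRegressor(grid=FAST_GRID, random_state=0)
        params = model.get_params()
        assert params["inner_folds"] == 3
        X = small_cohort[["s"]]
        model.fit(X, small_cohort["madrs_total"])
        assert model.predict(X).shape == (len(X),)
        assert set(model.best_params_) == {"n_estimators", "max_depth",
                                           "min_samples_leaf"}


class TestReportTable:
    @staticmethod
    def _evaluation(r2s, name="nlp_conversational", target="madrs", adjust=False):
        folds = [FoldMetrics(i, r2, 4.0, 1.5, 40, 10) for i, r2 in enumerate(r2s)]
        return ModelEvaluation(per_fold=folds, target=target,
                               spec=FeatureSetSpec(name, ("x",), adjust),
                               seed=0, n_rows_used=50, n_rows_dropped=0)

    def test_average_row_is_fold_mean(self):
        ev = self._evaluation([0.1, 0.2, 0.3, 0.4, 0.5])
        report = report_table([ev])
        col = ("madrs", "unadjusted")
        assert report.loc[("nlp_conversational", "R2 average"), col] == pytest.approx(0.3)

    def test_missing_fold_r2_marks_average_missing(self):
        ev = self._evaluation([0.1, float("nan"), 0.3, 0.2, 0.4])
        report = report_table([ev])
        assert np.isnan(report.loc[("nlp_conversational", "R2 average"),
                                   ("madrs", "unadjusted")])
        assert "—" in format_report(report)

    def test_single_spec_single_block(self):
        report = report_table([self._evaluation([0.1] * 5)])
        assert report.index.get_level_values("feature_set").unique().tolist() == [
            "nlp_conversational"
        ]

    def test_multiple_targets_and_adjustments_columns(self):
        evs = [self._evaluation([0.1] * 5, target=t, adjust=a)
               for t in ("madrs", "ymrs") for a in (False, True)]
        report = report_table(evs)
        assert report.shape[1] == 4


class TestShapley:
    @staticmethod
    def _fit(X, y):
        return RandomForestRegressor(60, random_state=0).fit(X, y)

    def test_single_feature_attribution_is_full_margin(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 1))
        model = self._fit(X, 3 * X[:, 0])
        att = shapley_attribution(model, X[:10], background=X[:20])
        expected = att.predictions - att.base_value
        assert np.allclose(att.values[:, 0], expected, atol=1e-9)

    def test_local_additivity_exact_mode(self):
        rng = np.random.default_rng(1)
        X = rng.random((80, 4))
        y = X @ [3, -2, 0, 1] + 0.1 * rng.standard_normal(80)
        att = shapley_attribution(self._fit(X, y), X[:15], background=X[:20])
        assert att.additivity_error() <= 1e-6

    def test_local_additivity_sampling_mode(self):
        rng = np.random.default_rng(2)
        X = rng.random((80, 4))
        y = X.sum(axis=1)
        model = self._fit(X, y)
        att = ShapleyExplainer(
            model, background=X[:10], exact_max_features=0,
            n_permutations=16, random_state=0,
        ).explain(X[:5])
        assert att.additivity_error() <= 1e-6

    def test_duplicated_feature_gets_symmetric_attribution(self):
        # the symmetry axiom needs a model that treats the twin columns
        # interchangeably: minimum-norm least squares on duplicated columns
        # splits the coefficient evenly, so attributions must match exactly
        from sklearn.linear_model import LinearRegression

        rng = np.random.default_rng(3)
        base = rng.random((100, 1))
        X = np.hstack([base, base])
        y = 4 * base[:, 0]
        model = LinearRegression().fit(X, y)
        assert model.coef_[0] == pytest.approx(model.coef_[1])
        att = shapley_attribution(model, X[:25], background=X[:20])
        mean_abs = att.mean_abs()
        assert mean_abs.iloc[0] == pytest.approx(mean_abs.iloc[1], rel=1e-9)

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.random((30, 3))
        model = self._fit(X, X.sum(axis=1))
        with pytest.raises(ValueError, match="columns"):
            ShapleyExplainer(model, background=X[:5, :2]).explain(X[:3])

    def test_signal_feature_ranks_first(self, small_cohort):
        evaluator = NestedForestEvaluator(grid=FAST_GRID, random_state=0)
        model, X, _ = evaluator.fit_full(
            small_cohort, FeatureSetSpec("sn", ("s", "n1")), "madrs"
        )
        att = shapley_attribution(model.model_, X, random_state=0)
        assert att.mean_abs().index[0] == "s"
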