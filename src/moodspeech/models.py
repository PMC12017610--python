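"""Random-forest severity regression under nested cross-validation.

Symptom totals (MADRS or YMRS, 0-60) are regressed on a feature panel with
a random forest. Generalization is estimated with an outer 5-fold split
(stratified by target quartile to stabilize small-sample folds) while an
inner 3-fold grid search selects the forest's hyperparameters on each outer
training set, so model selection never sees the held-out fold. Per-fold and
averaged R^2 / MSE / MAE are reported; R^2 on held-out folds may be
negative. Features enter unscaled — tree ensembles are invariant to
monotone feature scaling, so standardization would add nothing.

"Sex-adjusted" variants append a binary sex column (male=0, female=1) to
the predictor matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold

from .attribution import AttributionMatrix, ShapleyExplainer, shapley_attribution
from .langfeatures import LANGUAGE_FEATURES
from .segmentation import CONVERSATIONAL_FEATURES
from .voicequality import ACOUSTIC_FEATURES

SEX_ENCODING: Mapping[str, int] = {"male": 0, "female": 1}

# Small, honest grid: a single forest size (estimates stabilize well before
# 200 trees at these sample sizes) with depth and leaf-size options spanning
# aggressive to strongly regularized fits, so the inner CV can pick the
# smoothness appropriate for panels of 1-25 features at n of tens to
# thousands. Fully config-exposed.
DEFAULT_GRID: Mapping[str, Sequence] = {
    "n_estimators": [200],
    "max_depth": [None, 5],
    "min_samples_leaf": [1, 3, 10],
}


def regression_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float]:
    """(r2, mse, mae). r2 = 1 - SSres/SStot about the mean of y_true; it is
    NaN when y_true has zero variance and may be negative on held-out data."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal nonzero lengths")
    resid = y_true - y_pred
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return r2, mse, mae


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named predictor panel; adjust_sex appends the binary sex column."""

    name: str
    columns: tuple[str, ...]
    adjust_sex: bool = False

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("feature set must name at least one column")

    def with_sex(self, adjust: bool) -> "FeatureSetSpec":
        return FeatureSetSpec(self.name, self.columns, adjust)


def standard_feature_sets(available: Sequence[str] | None = None) -> dict[str, FeatureSetSpec]:
    """The three canonical panels: NLP + conversational, acoustic, and their
    union; optionally restricted to columns present in a table."""
    nlp = [*LANGUAGE_FEATURES, *CONVERSATIONAL_FEATURES]
    acoustic = list(ACOUSTIC_FEATURES)
    if available is not None:
        nlp = [c for c in nlp if c in available]
        acoustic = [c for c in acoustic if c in available]
    sets = {}
    if nlp:
        sets["nlp_conversational"] = FeatureSetSpec("nlp_conversational", tuple(nlp))
    if acoustic:
        sets["acoustic"] = FeatureSetSpec("acoustic", tuple(acoustic))
    if nlp and acoustic:
        sets["combined"] = FeatureSetSpec("combined", tuple(nlp + acoustic))
    return sets


@dataclass(frozen=True)
class FoldMetrics:
    fold_index: int
    r2: float
    mse: float
    mae: float
    n_train: int
    n_test: int


@dataclass
class ModelEvaluation:
    """Per-fold and averaged metrics for one feature set x target x
    adjustment combination."""

    per_fold: list[FoldMetrics]
    target: str
    spec: FeatureSetSpec
    seed: int
    n_rows_used: int
    n_rows_dropped: int
    best_params: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for fm in self.per_fold:
            if fm.mae**2 > fm.mse + 1e-9:
                raise AssertionError(
                    f"fold {fm.fold_index}: mae^2 {fm.mae**2:.6f} exceeds "
                    f"mse {fm.mse:.6f}"
                )

    @property
    def r2_avg(self) -> float:
        vals = [fm.r2 for fm in self.per_fold]
        return float("nan") if any(np.isnan(v) for v in vals) else float(np.mean(vals))

    @property
    def mse_avg(self) -> float:
        return float(np.mean([fm.mse for fm in self.per_fold]))

    @property
    def mae_avg(self) -> float:
        return float(np.mean([fm.mae for fm in self.per_fold]))

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "feature_set": self.spec.name,
            "adjust_sex": self.spec.adjust_sex,
            "seed": self.seed,
            "n_rows_used": self.n_rows_used,
            "n_rows_dropped": self.n_rows_dropped,
            "averages": {"r2": self.r2_avg, "mse": self.mse_avg, "mae": self.mae_avg},
            "per_fold": [
                {"fold": fm.fold_index, "r2": fm.r2, "mse": fm.mse, "mae": fm.mae,
                 "n_train": fm.n_train, "n_test": fm.n_test}
                for fm in self.per_fold
            ],
            "best_params": self.best_params,
        }


class TunedForestRegressor(BaseEstimator, RegressorMixin):
    """Random forest with an internal k-fold grid search over a small,
    honest hyperparameter grid; refit on the full training data.

    Fitted attributes: model_ (the refit best forest), best_params_,
    feature_names_in_ when fit on a DataFrame.
    """

    def __init__(
        self,
        grid: Mapping[str, Sequence] | None = None,
        inner_folds: int = 3,
        random_state: int | None = None,
    ):
        self.grid = grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        grid = dict(self.grid) if self.grid is not None else dict(DEFAULT_GRID)
        search = GridSearchCV(
            RandomForestRegressor(random_state=self.random_state),
            param_grid=grid,
            cv=KFold(self.inner_folds, shuffle=True, random_state=self.random_state),
            scoring="neg_mean_squared_error",
        )
        search.fit(X, y)
        self.model_ = search.best_estimator_
        self.best_params_ = search.best_params_
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self.model_.predict(np.asarray(X, dtype=float))


def build_design(
    table: pd.DataFrame, spec: FeatureSetSpec, target: str
) -> tuple[pd.DataFrame, pd.Series, int]:
    """(X, y, n_dropped): the predictor matrix (with sex appended when the
    spec is adjusted), the target totals, and the count of listwise-dropped
    rows with missing values."""
    missing = [c for c in spec.columns if c not in table.columns]
    if missing:
        raise KeyError(f"feature columns not in table: {missing}")
    target_col = target if target in table.columns else f"{target}_total"
    X = table[list(spec.columns)].astype(float).copy()
    if spec.adjust_sex:
        X["sex_code"] = table["sex"].map(SEX_ENCODING).astype(float)
    y = table[target_col].astype(float)
    ok = X.notna().all(axis=1) & y.notna()
    return X[ok], y[ok], int((~ok).sum())


class NestedForestEvaluator(BaseEstimator):
    """Nested cross-validation evaluation of TunedForestRegressor.

    Outer folds are shuffled and seeded; by default they are stratified by
    target quartile, which keeps small-sample fold targets comparable (an
    unstratified switch is provided).
    """

    def __init__(
        self,
        outer_folds: int = 5,
        inner_folds: int = 3,
        grid: Mapping[str, Sequence] | None = None,
        stratify_by_quartile: bool = True,
        random_state: int = 0,
    ):
        self.outer_folds = outer_folds
        self.inner_folds = inner_folds
        self.grid = grid
        self.stratify_by_quartile = stratify_by_quartile
        self.random_state = random_state

    def _outer_splits(self, X: np.ndarray, y: np.ndarray):
        if self.stratify_by_quartile:
            bins = pd.qcut(pd.Series(y).rank(method="first"), 4, labels=False)
            if bins.nunique() >= 2:
                splitter = StratifiedKFold(
                    self.outer_folds, shuffle=True, random_state=self.random_state
                )
                return list(splitter.split(X, bins))
        splitter = KFold(self.outer_folds, shuffle=True, random_state=self.random_state)
        return list(splitter.split(X))

    def evaluate(
        self, table: pd.DataFrame, spec: FeatureSetSpec, target: str
    ) -> ModelEvaluation:
        X_df, y_s, n_dropped = build_design(table, spec, target)
        if len(X_df) < 10:
            raise ValueError(
                f"need >= 10 complete rows for nested CV, got {len(X_df)}"
            )
        X = X_df.to_numpy(dtype=float)
        y = y_s.to_numpy(dtype=float)
        folds: list[FoldMetrics] = []
        best_params: list[dict] = []
        for k, (tr, te) in enumerate(self._outer_splits(X, y)):
            if te.size < 2:
                raise ValueError(f"outer fold {k} has {te.size} test rows (< 2)")
            model = TunedForestRegressor(
                grid=self.grid,
                inner_folds=self.inner_folds,
                random_state=self.random_state,
            ).fit(X[tr], y[tr])
            r2, mse, mae = regression_metrics(y[te], model.predict(X[te]))
            folds.append(FoldMetrics(k, r2, mse, mae, tr.size, te.size))
            best_params.append(model.best_params_)
        return ModelEvaluation(
            per_fold=folds,
            target=target,
            spec=spec,
            seed=self.random_state,
            n_rows_used=len(X_df),
            n_rows_dropped=n_dropped,
            best_params=best_params,
        )

    def fit_full(
        self, table: pd.DataFrame, spec: FeatureSetSpec, target: str
    ) -> tuple[TunedForestRegressor, pd.DataFrame, pd.Series]:
        """Inner-CV-tuned forest refit on all complete rows (for
        attribution); returns (model, X, y)."""
        X_df, y_s, _ = build_design(table, spec, target)
        model = TunedForestRegressor(
            grid=self.grid, inner_folds=self.inner_folds,
            random_state=self.random_state,
        ).fit(X_df, y_s)
        return model, X_df, y_s


def nested_cv_evaluate(
    table: pd.DataFrame,
    spec: FeatureSetSpec,
    target: str,
    seed: int = 0,
    **kwargs,
) -> ModelEvaluation:
    """Functional wrapper over NestedForestEvaluator."""
    return NestedForestEvaluator(random_state=seed, **kwargs).evaluate(
        table, spec, target
    )


def report_table(evaluations: Sequence[ModelEvaluation]) -> pd.DataFrame:
    """Metric x fold rows, (target, adjustment) columns, one row-block per
    feature set — the standard nested-CV performance report layout.
    Averages that include a missing fold value are NaN (rendered as a dash),
    never silently dropped."""
    if not evaluations:
        raise ValueError("need at least one evaluation")
    n_folds = max(len(ev.per_fold) for ev in evaluations)
    rows: dict[tuple[str, str], dict[tuple[str, str], float]] = {}
    for ev in evaluations:
        col = (ev.target, "adjusted" if ev.spec.adjust_sex else "unadjusted")
        for metric, avg in (("R2", ev.r2_avg), ("MSE", ev.mse_avg), ("MAE", ev.mae_avg)):
            rows.setdefault((ev.spec.name, f"{metric} average"), {})[col] = avg
            for fm in ev.per_fold:
                key = (ev.spec.name, f"{metric} fold {fm.fold_index + 1}")
                value = {"R2": fm.r2, "MSE": fm.mse, "MAE": fm.mae}[metric]
                rows.setdefault(key, {})[col] = value
    index = pd.MultiIndex.from_tuples(rows.keys(), names=["feature_set", "metric"])
    df = pd.DataFrame(list(rows.values()), index=index)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["target", "adjustment"])
    return df.sort_index(axis=1)


def format_report(report: pd.DataFrame) -> str:
    """Plain-text rendering with missing averages shown as an em dash."""
    return report.to_string(na_rep="—", float_format=lambda v: f"{v:.2f}")


__all__ = [
    "AttributionMatrix",
    "DEFAULT_GRID",
    "FeatureSetSpec",
    "FoldMetrics",
    "ModelEvaluation",
    "NestedForestEvaluator",
    "SEX_ENCODING",
    "ShapleyExplainer",
    "TunedForestRegressor",
    "build_design",
    "format_report",
    "nested_cv_evaluate",
    "regression_metrics",
    "report_table",
    "shapley_attribution",
    "standard_feature_sets",
]
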