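"""Yield regression: feature tables, the four model kinds, metrics,
collinearity screening, iterative feature selection and comparison statistics.

The four model kinds are multiple linear regression (MLR, closed-form OLS),
random forest (RF), gradient-boosting regressor (GBR) and XGBoost (XGB), the
latter three delegated to scikit-learn / xgboost with fixed default
hyperparameters (RF: max_depth 21, max_features 11, n_estimators 500; XGB:
colsample_bytree 0.9, gamma 0.30, learning_rate 0.05, max_depth 6,
n_estimators 200, subsample 0.7; GBR: learning_rate 0.1, max_depth 5,
n_estimators 200, subsample 0.7).  Accuracy is measured by R-squared
(``1 - SSres/SStot`` about the test mean) and RMSE.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from xgboost import XGBRegressor

MODEL_KINDS = ("MLR", "RF", "GBR", "XGB")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "MLR": {},
    "RF": {"max_depth": 21, "max_features": 11, "n_estimators": 500},
    "XGB": {
        "colsample_bytree": 0.9,
        "gamma": 0.30,
        "learning_rate": 0.05,
        "max_depth": 6,
        "n_estimators": 200,
        "subsample": 0.7,
    },
    "GBR": {"learning_rate": 0.1, "max_depth": 5, "n_estimators": 200, "subsample": 0.7},
}


class InsufficientDataError(ValueError):
    pass


class NegativeIntervalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """One row per retained polygon: predictors plus the yield target."""

    data: pd.DataFrame
    target: str = "yield_mg_ha"
    stage_label: str = ""
    dap: int | None = None

    def __post_init__(self) -> None:
        if self.target not in self.data.columns:
            raise ValueError(f"target column {self.target!r} missing")
        if self.data.columns.duplicated().any():
            raise ValueError("column names must be unique")

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.data.columns if c != self.target]

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.predictors]

    @property
    def y(self) -> pd.Series:
        return self.data[self.target]

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, predictors: Sequence[str]) -> "FeatureTable":
        cols = list(predictors) + [self.target]
        return replace(self, data=self.data[cols])

    def dropna(self) -> tuple["FeatureTable", int]:
        """Drop rows with any missing value; return (clean table, n dropped)."""
        clean = self.data.dropna()
        return replace(self, data=clean), len(self.data) - len(clean)


def split_train_test(
    table: FeatureTable, ratio: float = 0.8, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Seed-reproducible uniform random split; train size = round(ratio * n).

    The partition is disjoint and exhaustive.  An 80:20 split of 8581 rows
    yields 6865 training and 1716 testing rows.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n = table.n
    if n < 2:
        raise InsufficientDataError(f"need at least 2 rows, got {n}")
    n_train = int(np.floor(ratio * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return (
        replace(table, data=table.data.iloc[train_idx]),
        replace(table, data=table.data.iloc[test_idx]),
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class LinearYieldRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares by closed form (scikit-learn compatible).

    Fitted attributes: ``coef_``, ``intercept_``, ``coef_se_`` (standard
    errors), ``rank_``.  A rank-deficient design falls back to the
    minimum-norm pseudo-inverse solution with a warning.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        A = np.column_stack([np.ones(n), X])
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < p + 1:
            warnings.warn(
                f"rank-deficient design (rank {rank} < {p + 1}); "
                "using the minimum-norm pseudo-inverse solution",
                stacklevel=2,
            )
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.rank_ = int(rank)
        resid = y - A @ beta
        dof = max(n - rank, 1)
        sigma2 = float(resid @ resid) / dof
        # SEs from the pseudo-inverse covariance (exact for full-rank designs)
        cov = sigma2 * np.linalg.pinv(A.T @ A)
        self.coef_se_ = np.sqrt(np.clip(np.diag(cov)[1:], 0, None))
        self.intercept_se_ = float(np.sqrt(max(cov[0, 0], 0.0)))
        self._x_sd = X.std(axis=0, ddof=0)
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_

    def standardized_importances(self) -> np.ndarray:
        """Normalized |standardized coefficient| per predictor (sums to 1)."""
        raw = np.abs(self.coef_ * self._x_sd)
        total = raw.sum()
        return raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))


@dataclass(frozen=True)
class ModelConfig:
    kind: str
    hyperparameters: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")

    def resolved_hyperparameters(self) -> dict:
        hp = dict(DEFAULT_HYPERPARAMETERS[self.kind])
        if self.hyperparameters:
            hp.update(self.hyperparameters)
        return hp


def make_estimator(config: ModelConfig, n_features: int | None = None):
    """Instantiate the scikit-learn-style estimator for a model config."""
    hp = config.resolved_hyperparameters()
    if config.kind == "MLR":
        return LinearYieldRegressor()
    if config.kind == "RF":
        if n_features is not None and isinstance(hp.get("max_features"), int):
            hp["max_features"] = min(hp["max_features"], n_features)
        return RandomForestRegressor(random_state=config.seed, n_jobs=1, **hp)
    if config.kind == "GBR":
        return GradientBoostingRegressor(random_state=config.seed, **hp)
    return XGBRegressor(random_state=config.seed, n_jobs=1, verbosity=0, **hp)


@dataclass
class FitResult:
    """A fitted model plus its per-predictor importances."""

    config: ModelConfig
    estimator: object
    feature_names: list[str]
    feature_importances: pd.Series
    train_ids: list

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X[self.feature_names], float)))


def fit_model(config: ModelConfig, train: FeatureTable) -> FitResult:
    """Fit one model kind on a training table.

    Importances are impurity/gain-based for the tree ensembles (non-negative,
    summing to 1) and normalized |standardized coefficient| for MLR, so the
    selection loop treats all kinds uniformly.
    """
    if train.n == 0:
        raise InsufficientDataError("empty training table")
    est = make_estimator(config, n_features=len(train.predictors))
    X = np.asarray(train.X, dtype=float)
    y = np.asarray(train.y, dtype=float)
    est.fit(X, y)
    if config.kind == "MLR":
        imp = est.standardized_importances()
    else:
        imp = np.asarray(est.feature_importances_, dtype=float)
        total = imp.sum()
        imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    return FitResult(
        config=config,
        estimator=est,
        feature_names=train.predictors,
        feature_importances=pd.Series(imp, index=train.predictors),
        train_ids=list(train.data.index),
    )


@dataclass
class Metrics:
    r2: float
    rmse: float
    n: int


def evaluate(fit: FitResult, test: FeatureTable) -> Metrics:
    """R-squared (about the test mean) and RMSE on a held-out table."""
    if test.n == 0:
        raise InsufficientDataError("empty test table")
    y = np.asarray(test.y, dtype=float)
    yhat = fit.predict(test.X)
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return Metrics(r2=float("nan"), rmse=rmse, n=test.n)
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return Metrics(r2=r2, rmse=rmse, n=test.n)


# ---------------------------------------------------------------------------
# Collinearity and feature selection
# ---------------------------------------------------------------------------

def variance_inflation_factors(X: pd.DataFrame) -> pd.Series:
    """VIF per predictor: ``1 / (1 - R2_j)`` from regressing predictor j on
    the remaining predictors (with intercept).  Perfect collinearity gives
    ``+inf``."""
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors for VIF")
    arr = np.asarray(X, dtype=float)
    out = {}
    for j, name in enumerate(cols):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        beta, _, _, _ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            out[name] = float("inf")  # constant column: degenerate
            continue
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def collinearity_screen(table: FeatureTable, vif_cut: float = 10.0) -> list[str]:
    """Predictors whose VIF exceeds the cut, ordered worst-first
    (infinite VIFs first, alphabetical among ties)."""
    vifs = variance_inflation_factors(table.X)
    flagged = vifs[vifs > vif_cut]
    return list(flagged.sort_index().sort_values(ascending=False, kind="stable").index)


@dataclass
class SelectionStep:
    predictors: list[str]
    rmse: float
    r2: float
    dropped: list[str]
    importances: pd.Series


def iterative_feature_selection(
    train: FeatureTable,
    test: FeatureTable,
    config: ModelConfig,
    vif_cut: float = 10.0,
    importance_floor: float = 0.005,
    rmse_rise_tol: float = 0.01,
) -> tuple[list[str], list[SelectionStep]]:
    """Iteratively drop collinear and uninformative predictors.

    Each round fits the model, evaluates test RMSE, then drops the worst VIF
    offender above ``vif_cut`` plus every predictor with importance below
    ``importance_floor`` (ties broken alphabetically).  The loop stops when
    nothing is droppable or when the test RMSE rises more than
    ``rmse_rise_tol`` (relative) above the best seen.  The finalized model is
    the one with the fewest predictors among iterations whose RMSE is within
    the tolerance band of the minimum (ties broken by lower RMSE); the
    selected predictors are returned ordered by that iteration's importance,
    along with the full history.
    """
    preds = sorted(train.predictors)
    history: list[SelectionStep] = []
    best: SelectionStep | None = None

    while preds:
        sub_train, sub_test = train.subset(preds), test.subset(preds)
        fit = fit_model(config, sub_train)
        metrics = evaluate(fit, sub_test)

        drop: list[str] = []
        if len(preds) >= 2:
            vifs = variance_inflation_factors(sub_train.X)
            over = vifs[vifs > vif_cut]
            if len(over):
                worst = over.sort_index().sort_values(ascending=False, kind="stable").index[0]
                drop.append(worst)
        low = fit.feature_importances[fit.feature_importances < importance_floor]
        drop.extend(p for p in sorted(low.index) if p not in drop)

        step = SelectionStep(
            predictors=list(preds),
            rmse=metrics.rmse,
            r2=metrics.r2,
            dropped=drop,
            importances=fit.feature_importances,
        )
        history.append(step)
        if best is None or (step.rmse, len(step.predictors)) < (best.rmse, len(best.predictors)):
            best = step

        if not drop:
            break
        if step.rmse > best.rmse * (1.0 + rmse_rise_tol) and len(history) > 1:
            break
        remaining = [p for p in preds if p not in drop]
        if not remaining:
            warnings.warn("selection would empty the predictor set; keeping best iteration")
            break
        preds = remaining

    # Finalize: fewest predictors among iterations within the tolerance band
    # of the lowest test RMSE, then lowest RMSE among those.
    min_rmse = min(h.rmse for h in history)
    candidates = [h for h in history if h.rmse <= min_rmse * (1.0 + rmse_rise_tol)]
    best = min(candidates, key=lambda h: (len(h.predictors), h.rmse))
    selected = list(best.importances.loc[best.predictors].sort_values(ascending=False, kind="stable").index)
    return selected, history


class VIFImportanceSelector(BaseEstimator):
    """scikit-learn style wrapper around :func:`iterative_feature_selection`.

    ``fit(X, y)`` performs an internal train/test split and records
    ``selected_features_`` and ``history_``; ``transform`` keeps the selected
    columns.  Composes with sklearn pipelines on DataFrame input.
    """

    def __init__(self, kind: str = "RF", vif_cut: float = 10.0,
                 importance_floor: float = 0.005, split_ratio: float = 0.8, seed: int = 0):
        self.kind = kind
        self.vif_cut = vif_cut
        self.importance_floor = importance_floor
        self.split_ratio = split_ratio
        self.seed = seed

    def fit(self, X: pd.DataFrame, y):
        data = pd.DataFrame(X).copy()
        data["yield_mg_ha"] = np.asarray(y, dtype=float)
        table = FeatureTable(data=data)
        train, test = split_train_test(table, self.split_ratio, self.seed)
        self.selected_features_, self.history_ = iterative_feature_selection(
            train, test, ModelConfig(kind=self.kind, seed=self.seed),
            vif_cut=self.vif_cut, importance_floor=self.importance_floor,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]


# ---------------------------------------------------------------------------
# Comparison statistics
# ---------------------------------------------------------------------------

def _letters_from_lsd(means: pd.Series, lsd: float) -> dict[str, str]:
    """Compact letter display: 'a' marks the highest mean.  With a single LSD
    threshold, non-significance is an interval property on the sorted means,
    so maximal intervals of mutually non-different groups become letters."""
    order = means.sort_values(ascending=False, kind="stable")
    names = list(order.index)
    k = len(names)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and order.iloc[i] - order.iloc[j + 1] <= lsd:
            j += 1
        intervals.append((i, j))
    maximal = [
        iv for iv in intervals
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)
    ]
    seen = []
    for iv in maximal:  # deduplicate, preserve order
        if iv not in seen:
            seen.append(iv)
    letters = {name: "" for name in names}
    for letter_idx, (i, j) in enumerate(sorted(seen)):
        for g in range(i, j + 1):
            letters[names[g]] += chr(ord("a") + letter_idx)
    return letters


def compare_methods(
    rmse_by_method: Mapping[str, Sequence[float]] | pd.DataFrame, alpha: float = 0.05
) -> tuple[float, dict[str, str]]:
    """One-way ANOVA of RMSEs across regression methods (growth stages as
    replicates) followed, when significant, by Fisher's protected LSD with a
    compact letter display ('a' = highest mean RMSE).

    ``rmse_by_method`` maps method name -> RMSE per stage (equal lengths,
    >= 2).  Returns ``(anova_p, letters)``.
    """
    if isinstance(rmse_by_method, pd.DataFrame):
        groups = {str(m): np.asarray(rmse_by_method.loc[m], float) for m in rmse_by_method.index}
    else:
        groups = {str(m): np.asarray(v, float) for m, v in rmse_by_method.items()}
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1 or min(sizes) < 2:
        raise InsufficientDataError("every method needs the same number (>= 2) of values")
    S = sizes.pop()
    k = len(groups)
    if k < 2:
        raise InsufficientDataError("need at least 2 methods")

    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    means = pd.Series({m: v.mean() for m, v in groups.items()})
    ssb = S * float(((means - grand) ** 2).sum())
    ssw = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    df_b, df_e = k - 1, k * (S - 1)

    if ssw == 0.0 and ssb == 0.0:
        p = 1.0
    elif ssw == 0.0:
        p = 0.0
    else:
        F = (ssb / df_b) / (ssw / df_e)
        p = float(stats.f.sf(F, df_b, df_e))

    if not p < alpha:
        return p, {m: "a" for m in groups}
    mse = ssw / df_e
    lsd = float(stats.t.ppf(1.0 - alpha / 2.0, df_e) * np.sqrt(2.0 * mse / S))
    return p, _letters_from_lsd(means, lsd)


def soil_inclusion_test(full_rmses: Sequence[float], reduced_rmses: Sequence[float]) -> float:
    """One-tailed paired t-test that dropping the soil/slope predictors
    raises RMSE: H1 is ``mean(reduced - full) > 0``; returns the p-value.

    Degenerate conventions: all-zero differences return 0.5 (no evidence
    either way); zero-variance nonzero differences return 0.0 if positive,
    1.0 if negative.
    """
    full = np.asarray(full_rmses, dtype=float)
    red = np.asarray(reduced_rmses, dtype=float)
    if full.shape != red.shape or full.size < 2:
        raise InsufficientDataError("need paired lists of equal length >= 2")
    d = red - full
    if np.allclose(d, 0.0):
        return 0.5
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if d.mean() > 0 else 1.0
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(stats.t.sf(t, d.size - 1))


def days_after_planting(planting: dt.date, flight: dt.date) -> int:
    """Calendar-day difference between a flight and the planting date."""
    days = (flight - planting).days
    if days < 0:
        raise NegativeIntervalError(f"flight {flight} precedes planting {planting}")
    return days


__all__ = [
    "MODEL_KINDS",
    "DEFAULT_HYPERPARAMETERS",
    "FeatureTable",
    "ModelConfig",
    "FitResult",
    "Metrics",
    "SelectionStep",
    "LinearYieldRegressor",
    "VIFImportanceSelector",
    "InsufficientDataError",
    "NegativeIntervalError",
    "split_train_test",
    "make_estimator",
    "fit_model",
    "evaluate",
    "variance_inflation_factors",
    "collinearity_screen",
    "iterative_feature_selection",
    "compare_methods",
    "soil_inclusion_test",
    "days_after_planting",
]
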