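"""Predictive benchmarking harness: five learner families, stratified
train/test splits, cross-validated grid search, and multi-seed robustness.

The comparison pits ordinary least squares, support-vector regression, a
single decision tree, a random forest and gradient-boosted trees against
each other on held-out MSE/RMSE/MAE/R^2, averaging over repeated random
80:20 splits. "Proportional stratification" of a continuous outcome is
implemented as decile-bin stratified splitting. The boosted-tree family
defaults to the tuned configuration of the reference analysis (300 rounds,
depth 5, learning rate 0.05, subsample 0.8, colsample 0.9, lambda 3,
alpha 0.1, min_child_weight 3, gamma 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

ALGORITHMS = ("ols", "svm", "dtree", "rforest", "xgboost")


def xgb_default_params() -> dict:
    """Tuned gradient-boosting configuration used as the reference learner."""
    return {
        "n_estimators": 300,
        "max_depth": 5,
        "learning_rate": 0.05,
        "subsample": 0.8,
        "colsample_bytree": 0.9,
        "reg_lambda": 3.0,
        "reg_alpha": 0.1,
        "min_child_weight": 3,
        "gamma": 0.01,
        "tree_method": "hist",
        "n_jobs": 1,
    }


def default_grids() -> dict[str, dict]:
    """Hyper-parameter grids bracketing the tuned values of each family."""
    return {
        "ols": {},
        "svm": {"C": [0.3, 1.0, 3.0], "gamma": ["scale", 0.03]},
        "dtree": {"max_depth": [3, 5, 7, None], "min_samples_leaf": [1, 5, 20]},
        "rforest": {"n_estimators": [100, 300], "max_depth": [5, 10, None]},
        "xgboost": {
            "n_estimators": [100, 300, 500],
            "max_depth": [3, 5, 7],
            "learning_rate": [0.01, 0.05, 0.1],
        },
    }


def make_learner(name: str, params: dict | None = None, seed: int = 0):
    """Instantiate one of the five learner families."""
    params = dict(params or {})
    if name == "ols":
        return LinearRegression(**params)
    if name == "svm":
        return SVR(**params)
    if name == "dtree":
        return DecisionTreeRegressor(random_state=seed, **params)
    if name == "rforest":
        params.setdefault("n_estimators", 200)
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if name == "xgboost":
        merged = xgb_default_params()
        merged.update(params)
        return XGBRegressor(random_state=seed, **merged)
    raise ValueError(f"unknown learner family {name!r}; choose from {ALGORITHMS}")


def split_train_test(y, ratio: float = 0.8, seed: int = 0, n_bins: int = 10):
    """Decile-stratified random index partition into train and test.

    Returns (train_idx, test_idx): disjoint, exhaustive, with the train
    fraction within one row of ``ratio``. Stratification falls back to a
    plain shuffle when the outcome bins are too small to stratify.
    """
    y = np.asarray(y)
    n = y.size
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    if n < 2 or min(round(n * ratio), n - round(n * ratio)) < 1:
        raise ValueError(f"n = {n} too small for a {ratio:.0%} split")
    strat = None
    if n_bins >= 2:
        bins = pd.qcut(pd.Series(y), q=min(n_bins, n), labels=False, duplicates="drop")
        if bins.value_counts().min() >= 2 and bins.nunique() >= 2:
            strat = bins
    idx = np.arange(n)
    train, test = train_test_split(idx, test_size=1.0 - ratio, random_state=seed,
                                   shuffle=True, stratify=strat)
    return np.sort(train), np.sort(test)


def evaluate_metrics(y_true, y_pred):
    """(mse, rmse, mae, r2) on an evaluation set.

    R^2 = 1 - SS_res/SS_tot on the evaluated set; a constant ``y_true``
    leaves it undefined (returned as NaN with a warning).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant y_true: R^2 undefined", UserWarning, stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return {"mse": mse, "rmse": float(np.sqrt(mse)), "mae": mae, "r2": r2}


def grid_search(family: str, grid: dict, X, y, folds: int = 5, seed: int = 0):
    """Exhaustive CV grid search minimising mean MSE; ties break by grid order.

    Returns (best_params, best_cv_mse).
    """
    if family not in ALGORITHMS:
        raise ValueError(f"unknown learner family {family!r}")
    if folds < 2:
        raise ValueError("need folds >= 2")
    if not grid:
        return {}, float("nan")
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(make_learner(family, seed=seed), param_grid=grid,
                      scoring="neg_mean_squared_error", cv=cv, n_jobs=1)
    gs.fit(np.asarray(X), np.asarray(y))
    return dict(gs.best_params_), float(-gs.best_score_)


@dataclass(frozen=True)
class ModelReport:
    algorithm: str
    mse: float
    rmse: float
    mae: float
    r2: float
    best_hyperparameters: dict
    split_seed: int
    cv_folds: int


@dataclass
class Leaderboard:
    """Per-algorithm metric means/SDs over split seeds, plus the winner."""

    reports: list[ModelReport]
    table: pd.DataFrame
    winner: str
    failures: dict[str, str] = field(default_factory=dict)


def benchmark_once(X, y, seed: int, families=ALGORITHMS, ratio: float = 0.8,
                   folds: int = 5, use_grid_search: bool = False,
                   grids: dict | None = None):
    """One split seed: fit every family, return ModelReports and failures."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    train, test = split_train_test(y, ratio=ratio, seed=seed)
    reports, failures = [], {}
    grids = grids or default_grids()
    for family in families:
        try:
            params = {}
            if use_grid_search and grids.get(family):
                params, _ = grid_search(family, grids[family], X[train], y[train],
                                        folds=folds, seed=seed)
            model = make_learner(family, params, seed=seed)
            model.fit(X[train], y[train])
            m = evaluate_metrics(y[test], model.predict(X[test]))
            reports.append(ModelReport(algorithm=family, best_hyperparameters=params,
                                       split_seed=seed, cv_folds=folds, **m))
        except Exception as exc:  # family failure is recorded, not fatal
            failures[family] = f"{type(exc).__name__}: {exc}"
    return reports, failures


def compare_algorithms(X, y, seeds, families=ALGORITHMS, ratio: float = 0.8,
                       folds: int = 5, use_grid_search: bool = False,
                       grids: dict | None = None) -> Leaderboard:
    """Benchmark the learner families over repeated stratified splits.

    The leaderboard aggregates per-seed test metrics to means and SDs; the
    winner is the family with the highest mean R^2. The aggregate is
    invariant to the order of ``seeds``.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one split seed")
    all_reports, all_failures = [], {}
    for seed in sorted(seeds):
        reps, fails = benchmark_once(X, y, seed, families=families, ratio=ratio,
                                     folds=folds, use_grid_search=use_grid_search,
                                     grids=grids)
        all_reports.extend(reps)
        for fam, msg in fails.items():
            all_failures[f"{fam}@seed{seed}"] = msg
    if not all_reports:
        raise RuntimeError(f"every learner family failed: {all_failures}")
    df = pd.DataFrame([{"algorithm": r.algorithm, "mse": r.mse, "rmse": r.rmse,
                        "mae": r.mae, "r2": r.r2} for r in all_reports])
    agg = df.groupby("algorithm").agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    agg = agg.loc[[f for f in families if f in agg.index]]
    winner = agg["r2_mean"].idxmax()
    return Leaderboard(reports=all_reports, table=agg, winner=winner,
                       failures=all_failures)
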