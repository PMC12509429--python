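"""Double machine learning: cross-fitted partialling-out with bootstrap CIs.

For a continuous outcome Y (the standardized gap), a continuous treatment T
(one z-scored predictor) and confounders W (all remaining predictors), the
partial linear effect theta is estimated in two stages:

1. cross-fitting: with a K-fold partition, nuisance models g(W) ~ E[Y|W]
   and h(W) ~ E[T|W] are trained on the K-1 complementary folds and predict
   the held-out fold, giving out-of-fold residuals
   e_y = Y - g_hat(W) and e_t = T - h_hat(W);
2. residual-on-residual regression without intercept,
   theta_hat = sum(e_t * e_y) / sum(e_t^2),
   either pooled over all residuals or per fold with theta = mean_k theta_k.

Standard errors and 95% normal-approximation intervals come from
resampling residual pairs with replacement (the full-pipeline bootstrap,
which refits the nuisances per replicate, is available behind a flag).
Subgroup analysis dichotomises the sample at a median (ties to the lower
group) and re-runs the full estimator per side, subject to a minimum
subgroup size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from .instruments import OUTCOME_COLUMN
from .models import xgb_default_params

MIN_SUBGROUP_SIZE = 250  # recommended floor for subgroup effect estimation


def make_nuisance(learner, seed: int = 0):
    """Nuisance learner factory: 'linear', 'ridge', 'xgboost', or an estimator."""
    if learner == "linear":
        return LinearRegression()
    if learner == "ridge":
        return Ridge(alpha=1.0)
    if learner == "xgboost":
        return XGBRegressor(random_state=seed, **xgb_default_params())
    if hasattr(learner, "fit") and hasattr(learner, "predict"):
        return clone(learner)
    raise ValueError(f"unknown nuisance learner {learner!r}")


@dataclass
class ResidualSet:
    """Out-of-fold residuals from cross-fitted nuisance models."""

    e_y: np.ndarray
    e_t: np.ndarray
    fold_assignment: np.ndarray
    nuisance_scores: dict[str, float]
    n_folds: int


@dataclass(frozen=True)
class DMLConfig:
    learner: object = "xgboost"
    n_folds: int = 5
    bootstrap_b: int = 5000
    seed: int = 0
    theta_mode: str = "per-fold"  # per-fold | pooled
    full_pipeline_bootstrap: bool = False


@dataclass
class DMLResult:
    treatment: str
    theta: float
    theta_per_fold: list[float]
    theta_pooled: float
    n_folds: int
    se: float
    ci95: tuple[float, float]
    bootstrap_b: int
    seed: int
    theta_mode: str
    nuisance_scores: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "theta": self.theta,
            "theta_per_fold": list(self.theta_per_fold),
            "theta_pooled": self.theta_pooled,
            "n_folds": self.n_folds,
            "se": self.se,
            "ci95": list(self.ci95),
            "bootstrap_b": self.bootstrap_b,
            "seed": self.seed,
            "theta_mode": self.theta_mode,
            "nuisance_scores": self.nuisance_scores,
        }


def crossfit_residuals(y, t, W, learner="xgboost", n_folds: int = 5,
                       seed: int = 0) -> ResidualSet:
    """Out-of-fold residuals e_y, e_t from K-fold cross-fitted nuisances.

    For each fold k the nuisance models are trained on the other K-1 folds
    and predict fold k only, so no residual is produced by a model that saw
    its own observation. The treatment must vary and must not appear among
    the confounder columns.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    Wm = np.asarray(W, dtype=float)
    if n_folds < 2:
        raise ValueError("need n_folds >= 2")
    if t.std() == 0:
        raise ValueError("treatment is constant: no identifying variation")
    for j in range(Wm.shape[1]):
        if np.allclose(Wm[:, j], t):
            name = W.columns[j] if isinstance(W, pd.DataFrame) else f"column {j}"
            raise ValueError(f"treatment also appears in W ({name}); "
                             "W must exclude the treatment")
    e_y = np.empty_like(y)
    e_t = np.empty_like(t)
    folds = np.empty(len(y), dtype=int)
    yhat = np.empty_like(y)
    that = np.empty_like(t)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for k, (train, test) in enumerate(kf.split(Wm)):
        gm = make_nuisance(learner, seed=seed).fit(Wm[train], y[train])
        hm = make_nuisance(learner, seed=seed).fit(Wm[train], t[train])
        yhat[test] = gm.predict(Wm[test])
        that[test] = hm.predict(Wm[test])
        folds[test] = k
    e_y = y - yhat
    e_t = t - that
    scores = {"r2_outcome": float(r2_score(y, yhat)),
              "r2_treatment": float(r2_score(t, that))}
    return ResidualSet(e_y=e_y, e_t=e_t, fold_assignment=folds,
                       nuisance_scores=scores, n_folds=n_folds)


def theta_hat(e_y, e_t) -> float:
    """No-intercept residual-on-residual slope sum(e_t e_y) / sum(e_t^2)."""
    e_y = np.asarray(e_y, dtype=float)
    e_t = np.asarray(e_t, dtype=float)
    denom = float(np.dot(e_t, e_t))
    if denom <= 0.0:
        raise ValueError("treatment residuals have zero variance")
    return float(np.dot(e_t, e_y)) / denom


def kfold_theta(rs: ResidualSet):
    """Per-fold and pooled effect estimates from a residual set.

    Returns (theta_per_fold, theta_fold_mean, theta_pooled); folds whose
    treatment residuals are degenerate are flagged and skipped in the
    average.
    """
    per_fold = []
    for k in range(rs.n_folds):
        sel = rs.fold_assignment == k
        try:
            per_fold.append(theta_hat(rs.e_y[sel], rs.e_t[sel]))
        except ValueError:
            warnings.warn(f"fold {k} has degenerate treatment residuals; skipped",
                          UserWarning, stacklevel=2)
    if not per_fold:
        raise ValueError("no fold produced a valid estimate")
    pooled = theta_hat(rs.e_y, rs.e_t)
    return per_fold, float(np.mean(per_fold)), pooled


def bootstrap_inference(e_y, e_t, B: int = 5000, seed: int = 0,
                        theta: float | None = None):
    """Pair-resampling bootstrap of the residual regression.

    Resamples (e_y, e_t) pairs with replacement, recomputes theta_hat per
    replicate; se is the replicate SD and the 95% CI is the normal
    approximation theta +/- 1.96 se around the point estimate. Degenerate
    replicates (zero treatment-residual variance) are discarded.

    Returns (se, ci95, n_used_replicates).
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replications")
    e_y = np.asarray(e_y, dtype=float)
    e_t = np.asarray(e_t, dtype=float)
    n = e_y.size
    point = theta_hat(e_y, e_t) if theta is None else float(theta)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    ey_b = e_y[idx]
    et_b = e_t[idx]
    denom = np.einsum("ij,ij->i", et_b, et_b)
    good = denom > 0
    if not good.all():
        warnings.warn(f"{int((~good).sum())} degenerate bootstrap replicates discarded",
                      UserWarning, stacklevel=2)
    thetas = np.einsum("ij,ij->i", et_b, ey_b)[good] / denom[good]
    se = float(np.std(thetas, ddof=1))
    ci = (point - 1.96 * se, point + 1.96 * se)
    return se, ci, int(good.sum())


def dml_ate(data: pd.DataFrame, treatment: str, outcome: str = OUTCOME_COLUMN,
            config: DMLConfig | None = None) -> DMLResult:
    """Full pipeline: cross-fit -> theta -> bootstrap, for one treatment.

    ``data`` is an encoded (numeric) table; W is every column except the
    treatment and the outcome. With ``theta_mode="per-fold"`` the reported
    theta is the mean of the K fold estimates; the pooled estimate is
    always carried alongside.
    """
    cfg = config or DMLConfig()
    if treatment not in data.columns:
        raise ValueError(f"treatment column {treatment!r} not in data")
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} not in data")
    W = data.drop(columns=[treatment, outcome])
    rs = crossfit_residuals(data[outcome], data[treatment], W,
                            learner=cfg.learner, n_folds=cfg.n_folds,
                            seed=cfg.seed)
    per_fold, fold_mean, pooled = kfold_theta(rs)
    theta = fold_mean if cfg.theta_mode == "per-fold" else pooled
    if cfg.full_pipeline_bootstrap:
        se, ci = _full_pipeline_bootstrap(data, treatment, outcome, cfg, theta)
    else:
        se, ci, _ = bootstrap_inference(rs.e_y, rs.e_t, B=cfg.bootstrap_b,
                                        seed=cfg.seed, theta=theta)
    return DMLResult(treatment=treatment, theta=theta, theta_per_fold=per_fold,
                     theta_pooled=pooled, n_folds=cfg.n_folds, se=se, ci95=ci,
                     bootstrap_b=cfg.bootstrap_b, seed=cfg.seed,
                     theta_mode=cfg.theta_mode,
                     nuisance_scores=rs.nuisance_scores)


def _full_pipeline_bootstrap(data, treatment, outcome, cfg: DMLConfig, theta):
    """Refit the whole cross-fitting pipeline on each bootstrap resample."""
    rng = np.random.default_rng(cfg.seed)
    thetas = []
    light = replace(cfg, full_pipeline_bootstrap=False)
    for b in range(cfg.bootstrap_b):
        sample = data.sample(n=len(data), replace=True,
                             random_state=int(rng.integers(2**31)))
        sample = sample.reset_index(drop=True)
        rs = crossfit_residuals(sample[outcome], sample[treatment],
                                sample.drop(columns=[treatment, outcome]),
                                learner=light.learner, n_folds=light.n_folds,
                                seed=light.seed)
        _, fold_mean, pooled = kfold_theta(rs)
        thetas.append(fold_mean if light.theta_mode == "per-fold" else pooled)
    se = float(np.std(thetas, ddof=1))
    return se, (theta - 1.96 * se, theta + 1.96 * se)


def ate_table(results) -> pd.DataFrame:
    """Effect table shaped as (variable, ATE, standard error, CI bounds)."""
    return pd.DataFrame([{
        "variable": r.treatment,
        "ate": r.theta,
        "standard_error": r.se,
        "ci_low": r.ci95[0],
        "ci_high": r.ci95[1],
    } for r in results])


@dataclass
class SubgroupResult:
    split_variable: str
    median: float
    rule: str
    group_sizes: dict[str, int]
    min_size: int
    results: dict[str, list[DMLResult]]
    outcome_r2: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for group, res in self.results.items():
            df = ate_table(res)
            df.insert(0, "group", group)
            df.insert(0, "split_variable", self.split_variable)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def subgroup_ates(data: pd.DataFrame, split_var: str, treatments,
                  outcome: str = OUTCOME_COLUMN, config: DMLConfig | None = None,
                  min_size: int = MIN_SUBGROUP_SIZE) -> SubgroupResult:
    """Median-split heterogeneous effects: re-run DML per side per treatment.

    The sample is dichotomised at the median of ``split_var`` with ties
    assigned to the lower group. Each side must reach ``min_size``
    respondents; otherwise the analysis is refused. The per-group outcome
    R^2 is the out-of-fold fit of the outcome nuisance, averaged over
    treatments.
    """
    cfg = config or DMLConfig()
    if split_var not in data.columns:
        raise ValueError(f"split variable {split_var!r} not in data")
    if not np.issubdtype(data[split_var].dtype, np.number):
        raise ValueError(f"split variable {split_var!r} must be numeric")
    med = float(data[split_var].median())
    lower_mask = data[split_var] <= med
    sizes = {"lower": int(lower_mask.sum()), "higher": int((~lower_mask).sum())}
    for group, size in sizes.items():
        if size < min_size:
            raise ValueError(
                f"{group} subgroup has {size} respondents, below the minimum "
                f"of {min_size} required for subgroup effect estimation"
            )
    results: dict[str, list[DMLResult]] = {}
    outcome_r2: dict[str, float] = {}
    for group, mask in (("lower", lower_mask), ("higher", ~lower_mask)):
        sub = data.loc[mask].reset_index(drop=True)
        res = [dml_ate(sub, tr, outcome=outcome, config=cfg) for tr in treatments]
        results[group] = res
        outcome_r2[group] = float(np.mean([r.nuisance_scores["r2_outcome"]
                                           for r in res]))
    return SubgroupResult(split_variable=split_var, median=med,
                          rule="ties-to-lower", group_sizes=sizes,
                          min_size=min_size, results=results,
                          outcome_r2=outcome_r2)
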