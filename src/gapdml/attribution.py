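"""Shapley-value attribution with an exact enumeration core.

The attribution of a prediction f(x) to its features uses the interventional
value function: the value of a coalition S is the mean prediction when the
features in S are fixed at the instance's values and the remaining features
are drawn from an empirical background sample,

    v(S) = E_b[ f(x_S, b_{~S}) ],

and phi_j is the Shapley combination of marginal contributions
sum_S |S|!(p-|S|-1)!/p! * (v(S+j) - v(S)). The exact enumerator over all 2^p
coalitions is the definition of correctness; a permutation-sampling
estimator provides the scalable path and is certified against it.

Dimension-level summaries aggregate mean |phi| over named feature groups,
and dependence curves pair a feature column with its phi column under a
LOWESS smoother (tricube-weighted local linear regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm

ENUMERATION_CAP = 15


@dataclass(frozen=True)
class ShapleyValues:
    phi: np.ndarray
    baseline: float
    se: np.ndarray | None = None


@dataclass
class AttributionMatrix:
    """Per-respondent, per-feature Shapley values with their baseline."""

    phi: pd.DataFrame
    baseline: float
    feature_names: list[str]
    background_ref: str


@dataclass
class ImportanceRanking:
    importance: pd.Series          # mean |phi| per feature, descending
    ranks: pd.Series               # 1 = most important
    dimension_sums: dict[str, float] = field(default_factory=dict)


@dataclass
class DependenceCurve:
    x: np.ndarray
    phi: np.ndarray
    grid: np.ndarray
    smooth: np.ndarray
    span: float


def _as_background(background) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.ndim == 1:
        bg = bg[None, :]
    if bg.size == 0:
        raise ValueError("background set must be non-empty")
    return bg


def exact_shapley(predict, instance, background, max_features: int = ENUMERATION_CAP,
                  return_baseline: bool = False):
    """Exact Shapley values by enumeration over all 2^p coalitions.

    ``predict`` must map an (m, p) array to m predictions. Exact mode is
    limited to ``max_features`` features; beyond that use
    :func:`sampled_shapley`.
    """
    x = np.asarray(instance, dtype=float).ravel()
    bg = _as_background(background)
    p = x.size
    if bg.shape[1] != p:
        raise ValueError("background and instance feature counts differ")
    if p > max_features:
        raise ValueError(
            f"{p} features exceeds the enumeration cap ({max_features}); "
            "use sampled_shapley instead"
        )
    n_masks = 1 << p
    bits = np.arange(p)
    values = np.empty(n_masks)
    for mask in range(n_masks):
        keep = ((mask >> bits) & 1).astype(bool)
        X = np.where(keep, x, bg)
        values[mask] = float(np.mean(predict(X)))
    w = [factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)]
    phi = np.zeros(p)
    for mask in range(n_masks):
        s = bin(mask).count("1")
        if s == p:
            continue
        for j in range(p):
            bit = 1 << j
            if not mask & bit:
                phi[j] += w[s] * (values[mask | bit] - values[mask])
    if return_baseline:
        return ShapleyValues(phi=phi, baseline=float(values[0]))
    return phi


def sampled_shapley(predict, instance, background, n_permutations: int = 2000,
                    seed: int = 0, chunk: int = 128) -> ShapleyValues:
    """Permutation-sampling Shapley estimate with Monte-Carlo standard errors.

    For each sampled feature ordering, the marginal contribution of feature
    j is the change in the interventional coalition value when j joins the
    features preceding it; averaging over orderings is unbiased for the
    exact Shapley value.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    x = np.asarray(instance, dtype=float).ravel()
    bg = _as_background(background)
    p = x.size
    n_bg = bg.shape[0]
    rng = np.random.default_rng(seed)
    contribs = np.empty((n_permutations, p))
    baseline = float(np.mean(predict(bg)))
    for start in range(0, n_permutations, chunk):
        perms = np.array([rng.permutation(p) for _ in range(min(chunk, n_permutations - start))])
        c = perms.shape[0]
        # masks[t, k] = features present after k additions in permutation t
        masks = np.zeros((c, p + 1, p), dtype=bool)
        for t in range(c):
            for k in range(p):
                masks[t, k + 1] = masks[t, k]
                masks[t, k + 1, perms[t, k]] = True
        rows = np.where(masks[:, :, None, :], x, bg[None, None, :, :])
        preds = predict(rows.reshape(-1, p)).reshape(c, p + 1, n_bg).mean(axis=2)
        deltas = np.diff(preds, axis=1)  # (c, p) in permutation order
        for t in range(c):
            contribs[start + t, perms[t]] = deltas[t]
    phi = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations) \
        if n_permutations > 1 else np.full(p, np.nan)
    return ShapleyValues(phi=phi, baseline=baseline, se=se)


def attribution_matrix(predict, X, background, mode: str = "exact",
                       feature_names=None, seed: int = 0,
                       n_permutations: int = 500,
                       background_ref: str = "supplied") -> AttributionMatrix:
    """Shapley values for every row of X (exact or sampled mode)."""
    X = np.asarray(X, dtype=float)
    bg = _as_background(background)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    baseline = float(np.mean(predict(bg)))
    rows = []
    for i in range(X.shape[0]):
        if mode == "exact":
            rows.append(exact_shapley(predict, X[i], bg))
        elif mode == "sampled":
            rows.append(sampled_shapley(predict, X[i], bg,
                                        n_permutations=n_permutations,
                                        seed=seed + i).phi)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    phi = pd.DataFrame(np.vstack(rows), columns=list(feature_names))
    return AttributionMatrix(phi=phi, baseline=baseline,
                             feature_names=list(feature_names),
                             background_ref=background_ref)


def importance_ranking(attr: AttributionMatrix,
                       dimension_map: dict[str, tuple[str, ...]] | None = None
                       ) -> ImportanceRanking:
    """Mean |phi| per feature, descending ranks, and dimension aggregates.

    Ties keep the original feature order (stable sort), so all-zero
    attributions yield a deterministic ranking.
    """
    if attr.phi.empty:
        raise ValueError("attribution matrix is empty")
    imp = attr.phi.abs().mean(axis=0)
    order = np.argsort(-imp.to_numpy(), kind="stable")
    imp = imp.iloc[order]
    ranks = pd.Series(np.arange(1, len(imp) + 1), index=imp.index)
    sums = {}
    if dimension_map:
        for dim, members in dimension_map.items():
            missing = [m for m in members if m not in attr.phi.columns]
            if missing:
                raise ValueError(f"dimension {dim!r} names unknown features: {missing}")
            sums[dim] = float(sum(imp[m] for m in members))
    return ImportanceRanking(importance=imp, ranks=ranks, dimension_sums=sums)


def gain_ranking(model, feature_names) -> pd.Series:
    """Split-gain importance of a fitted tree model (the non-Shapley ranking)."""
    imp = pd.Series(np.asarray(model.feature_importances_, dtype=float),
                    index=list(feature_names))
    return imp.sort_values(ascending=False, kind="stable")


def dependence_curve(feature_values, phi_values, span: float = 0.6,
                     robustness_iters: int = 2) -> DependenceCurve:
    """LOWESS-smoothed dependence of phi on a feature.

    Locally weighted linear regression with tricube weights; the smoothed
    curve is evaluated on the sorted unique feature values.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(phi_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature and phi columns must be equal-length vectors")
    if x.size < 10:
        raise ValueError("need at least 10 points to smooth")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if span * x.size < 3:
        raise ValueError("smoother window smaller than 3 points; increase span")
    fitted = sm.nonparametric.lowess(y, x, frac=span, it=robustness_iters,
                                     return_sorted=True)
    grid = np.unique(x)
    smooth = np.interp(grid, fitted[:, 0], fitted[:, 1])
    return DependenceCurve(x=x, phi=y, grid=grid, smooth=smooth, span=span)


def beeswarm_table(attr: AttributionMatrix, X: pd.DataFrame) -> pd.DataFrame:
    """Tidy (feature, value, phi) table for summary/beeswarm plotting."""
    frames = []
    for col in attr.feature_names:
        frames.append(pd.DataFrame({
            "feature": col,
            "value": np.asarray(X[col], dtype=float),
            "phi": attr.phi[col].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)
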