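"""Construct scoring, psychometric validation, and feature encoding.

Convergent validity and reliability are summarised per construct by
Cronbach's alpha (internal consistency of the observed items), the average
variance extracted

    AVE = mean(lambda_i^2)

and the composite reliability

    CR = (sum lambda_i)^2 / [(sum lambda_i)^2 + sum(1 - lambda_i^2)],

both functions of the standardized loadings lambda alone. Sampling adequacy
of an item block is measured by the Kaiser-Meyer-Olkin statistic (shared vs
partial correlation) and Bartlett's test of sphericity. Loadings are inputs
(instrument calibration), not estimates: no factor model is fit here.

Feature encoding follows the modelling convention of the analysis: continuous
predictors are z-scored, nominal predictors one-hot encoded, and the encoded
table is screened for pairwise |r| < 0.60 (a diagnostic warning, not a hard
failure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

CORRELATION_SCREEN = 0.60


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (reporting convention for validity tables)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class ConstructValidation:
    name: str
    loadings: tuple[float, ...]
    ave: float
    cr: float
    alpha: float | None = None


def _check_loadings(loadings) -> np.ndarray:
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("loading vector is empty")
    if np.any(lam <= 0) or np.any(lam > 1):
        raise ValueError(f"loadings must lie in (0, 1], got {lam}")
    return lam


def ave(loadings) -> float:
    """Average variance extracted: mean of squared standardized loadings."""
    lam = _check_loadings(loadings)
    return float(np.mean(lam**2))


def composite_reliability(loadings) -> float:
    """Composite reliability (sum lam)^2 / [(sum lam)^2 + sum(1 - lam^2)]."""
    lam = _check_loadings(loadings)
    s2 = float(np.sum(lam)) ** 2
    return s2 / (s2 + float(np.sum(1.0 - lam**2)))


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of an n x k item matrix.

    alpha = k/(k-1) * (1 - sum(var_i) / var(total)); requires at least two
    items, three respondents, and a non-degenerate total score.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x k item matrix with k >= 2")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance: alpha undefined")
    k = X.shape[1]
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def kmo(corr) -> float:
    """Overall Kaiser-Meyer-Olkin sampling-adequacy statistic.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum p_ij^2) over off-diagonal entries,
    where p_ij are anti-image partial correlations obtained from the inverse
    of the correlation matrix. An exact identity matrix (no shared variance)
    is defined as KMO = 0.
    """
    R = np.asarray(corr, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] < 3:
        raise ValueError("need a square correlation matrix of dimension >= 3")
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"correlation matrix is singular (condition number {cond:.3g})")
    inv = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = float(np.sum(R[off] ** 2))
    p2 = float(np.sum(partial[off] ** 2))
    if r2 == 0.0:
        return 0.0
    return r2 / (r2 + p2)


def bartlett_sphericity(corr, n: int):
    """Bartlett's test of sphericity against an identity correlation matrix.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R) on p(p-1)/2 degrees of freedom.
    Returns (chi2, df, p_value).
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("need more observations than variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def validate_construct(name: str, loadings, items=None) -> ConstructValidation:
    """Bundle AVE/CR (from loadings) and alpha (from items, if supplied)."""
    lam = tuple(float(v) for v in _check_loadings(loadings))
    alpha = cronbach_alpha(items) if items is not None else None
    return ConstructValidation(name=name, loadings=lam, ave=ave(lam),
                               cr=composite_reliability(lam), alpha=alpha)


def validation_table(loadings_map: dict, items_map: dict | None = None,
                     ndigits: int = 3) -> pd.DataFrame:
    """Validity summary over constructs, rounded to reporting precision."""
    rows = []
    for name, lam in loadings_map.items():
        items = None if items_map is None else items_map.get(name)
        v = validate_construct(name, lam, items)
        rows.append({
            "construct": name,
            "n_items": len(v.loadings),
            "alpha": None if v.alpha is None else round_half_up(v.alpha, ndigits),
            "ave": round_half_up(v.ave, ndigits),
            "cr": round_half_up(v.cr, ndigits),
        })
    return pd.DataFrame(rows).set_index("construct")


def validation_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering of a validity table (AVE/CR columns)."""
    lines = ["| Construct | Items | alpha | AVE | CR |",
             "|---|---|---|---|---|"]
    for name, row in table.iterrows():
        alpha = "" if row["alpha"] is None or pd.isna(row["alpha"]) else f"{row['alpha']:.3f}"
        lines.append(f"| {name} | {int(row['n_items'])} | {alpha} "
                     f"| {row['ave']:.3f} | {row['cr']:.3f} |")
    return "\n".join(lines) + "\n"


@dataclass
class EncodedTable:
    """Numeric model-ready table with its encoding provenance."""

    frame: pd.DataFrame
    encoding_map: dict[str, list[str]]
    standardization: pd.DataFrame
    corr_warnings: list[tuple[str, str, float]] = field(default_factory=list)
    max_abs_corr: float = 0.0
    dropped_reference_levels: dict[str, str] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def model_matrix(self) -> pd.DataFrame:
        """Encoded table with each categorical group's first level dropped."""
        drop = list(self.dropped_reference_levels.values())
        return self.frame.drop(columns=drop)


def encode_features(table: pd.DataFrame, schema: dict[str, str],
                    screen: float = CORRELATION_SCREEN) -> EncodedTable:
    """Z-score continuous columns, one-hot nominal columns, screen correlations.

    Every column of ``table`` must be labelled ``"continuous"`` or
    ``"categorical"`` in ``schema``. One-hot groups keep all levels in the
    encoded frame (partition of unity per row); ``model_matrix()`` drops each
    group's first level to avoid exact collinearity. Constant continuous
    columns are rejected (they cannot be z-scored). Pairs of encoded columns
    from different source columns with |r| >= ``screen`` are attached as
    warnings.
    """
    unknown = [c for c in table.columns if c not in schema]
    if unknown:
        raise ValueError(f"schema does not label columns: {unknown}")
    bad = {c: k for c, k in schema.items()
           if c in table.columns and k not in ("continuous", "categorical")}
    if bad:
        raise ValueError(f"schema labels must be continuous/categorical, got {bad}")

    pieces, enc_map, std_rows, dropped = [], {}, [], {}
    for col in table.columns:
        if schema[col] == "continuous":
            x = table[col].to_numpy(dtype=float)
            mu, sd = float(x.mean()), float(x.std(ddof=0))
            if sd == 0.0:
                raise ValueError(f"column {col!r} is constant: cannot z-score")
            pieces.append(pd.Series((x - mu) / sd, index=table.index, name=col))
            enc_map[col] = [col]
            std_rows.append({"feature": col, "mean": mu, "sd": sd})
        else:
            levels = sorted(pd.unique(table[col]))
            names = [f"{col}={lv}" for lv in levels]
            for lv, nm in zip(levels, names):
                pieces.append(pd.Series((table[col] == lv).astype(float),
                                        index=table.index, name=nm))
            enc_map[col] = names
            dropped[col] = names[0]
    frame = pd.concat(pieces, axis=1)

    source_of = {enc: src for src, encs in enc_map.items() for enc in encs}
    corr = frame.corr().to_numpy()
    cols = list(frame.columns)
    warn_pairs, max_abs = [], 0.0
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if source_of[cols[i]] == source_of[cols[j]]:
                continue  # within-group one-hot columns are collinear by design
            r = abs(float(corr[i, j]))
            if np.isfinite(r):
                max_abs = max(max_abs, r)
                if r >= screen:
                    warn_pairs.append((cols[i], cols[j], float(corr[i, j])))
    if warn_pairs:
        warnings.warn(
            f"{len(warn_pairs)} encoded feature pairs exceed |r| >= {screen}",
            UserWarning, stacklevel=2,
        )
    return EncodedTable(frame=frame, encoding_map=enc_map,
                        standardization=pd.DataFrame(std_rows),
                        corr_warnings=warn_pairs, max_abs_corr=max_abs,
                        dropped_reference_levels=dropped)
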