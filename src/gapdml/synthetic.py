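"""Synthetic survey generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes:

* 7-point Likert item blocks generated from a single-factor model per
  construct — item = lambda * F + sqrt(1 - lambda^2) * e, discretized by
  equal-probability normal quantile cuts — with a block-structured latent
  correlation (0.30 within the HBM and UTAUT theory blocks, 0.15 across)
  that keeps every pairwise predictor correlation under the 0.60 screen;
* ordinal demographic / activity covariates drawn from discretized-normal
  categorical distributions moment-fitted to the published means and SDs;
* actual and ideal PARS-3 triples with ideal >= actual componentwise; and
* a standardized-gap outcome built from a structural specification with
  signed linear effects, optional non-linear shapes (inverted-U, threshold,
  U-shape), optional pairwise interactions, and Gaussian noise.

The default structural specification carries the reference effect pattern of
the analysis (BAR and Midnight widen the gap; SE, BEN, UI, SS, SI and PN
narrow it) with the non-linear shapes attached to UI, SS and SI, so every
downstream stage can be tested against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import gap as gap_mod
from .instruments import (
    ALL_CONSTRUCTS,
    CONTINUOUS_TARGETS,
    DEFAULT_LOADINGS,
    DEMOGRAPHIC_COLUMNS,
    HBM_CONSTRUCTS,
    ORDINAL_TARGETS,
    OUTCOME_COLUMN,
    PREDICTOR_COLUMNS,
    UTAUT_CONSTRUCTS,
)

CORRELATION_BOUND = 0.60


@dataclass(frozen=True)
class ConstructSpec:
    """One latent construct and its Likert item block."""

    name: str
    item_labels: tuple[str, ...]
    loadings: tuple[float, ...]
    n_levels: int = 7

    def __post_init__(self):
        if len(self.loadings) != len(self.item_labels) or len(self.loadings) < 1:
            raise ValueError(f"{self.name}: need matching, non-empty items and loadings")
        lam = np.asarray(self.loadings, dtype=float)
        if np.any(lam <= 0) or np.any(lam > 1):
            raise ValueError(f"{self.name}: loadings must lie in (0, 1], got {lam}")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


@dataclass(frozen=True)
class NonlinearTerm:
    construct: str
    shape: str  # inverted_u | threshold | u_shape
    params: tuple[tuple[str, float], ...]  # e.g. (("amplitude", .1), ("center", -1.25))

    def param(self, key: str) -> float:
        return dict(self.params)[key]


@dataclass(frozen=True)
class StructuralSpec:
    """Ground-truth data-generating process for the gap outcome.

    Effects are defined on z-scored predictor columns, so linear
    coefficients are effects per 1 SD of the predictor.
    """

    linear_coeffs: tuple[tuple[str, float], ...]
    nonlinear_terms: tuple[NonlinearTerm, ...] = ()
    interactions: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float = 0.25
    factor_corr_bound: float = CORRELATION_BOUND

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def coeff_map(self) -> dict[str, float]:
        return dict(self.linear_coeffs)

    def referenced_columns(self) -> set[str]:
        cols = {c for c, _ in self.linear_coeffs}
        cols |= {t.construct for t in self.nonlinear_terms}
        for a, b, _ in self.interactions:
            cols |= {a, b}
        return cols


@dataclass(frozen=True)
class Pars3Config:
    """Actual-grade distribution and ideal-inflation parameters.

    ``inflation_rates`` are per-component success probabilities for the
    truncated binomial increments ideal - actual; zero rates give
    ideal == actual exactly. ``gap_link`` scales the inflation with the
    structural propensity so larger latent gaps produce larger ideal
    aspirations.
    """

    intensity_probs: tuple[float, ...] = (0.25, 0.30, 0.20, 0.15, 0.10)
    duration_probs: tuple[float, ...] = (0.10, 0.25, 0.30, 0.20, 0.15)
    frequency_probs: tuple[float, ...] = (0.20, 0.25, 0.25, 0.20, 0.10)
    inflation_rates: tuple[float, float, float] = (0.35, 0.35, 0.35)
    gap_link: float = 1.0


def default_construct_specs(n_levels: int = 7) -> tuple[ConstructSpec, ...]:
    """The thirteen HBM/UTAUT construct blocks at their calibrated loadings."""
    return tuple(
        ConstructSpec(
            name=name,
            item_labels=tuple(f"{name}{i + 1}" for i in range(len(lams))),
            loadings=lams,
            n_levels=n_levels,
        )
        for name, lams in DEFAULT_LOADINGS.items()
    )


def default_latent_correlation(names=ALL_CONSTRUCTS, within: float = 0.30,
                               between: float = 0.15) -> pd.DataFrame:
    """Block-structured construct correlation: `within` inside a theory block
    (HBM or UTAUT), `between` across blocks."""
    names = tuple(names)
    block = {n: ("HBM" if n in HBM_CONSTRUCTS else "UTAUT") for n in names}
    k = len(names)
    R = np.full((k, k), between)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if block.get(a) == block.get(b):
                R[i, j] = within
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=names, columns=names)


def default_structural_spec() -> StructuralSpec:
    """Reference effect pattern with non-linear shapes on UI, SS and SI.

    Linear coefficients follow the signed per-SD effect sizes of the
    reference analysis; the shapes encode the inverted-U (UI), threshold
    (SS, at +0.5 SD) and mild U (SI) dependence patterns. A small positive
    SE x UI interaction makes the UI effect strongest when self-efficacy is
    low. noise_sd = 0.30 puts the explainable variance share of a flexible
    learner near the predictive performance the analysis reports.
    """
    return StructuralSpec(
        linear_coeffs=(
            ("BAR", 0.186), ("SE", -0.157), ("UI", -0.118), ("SS", -0.076),
            ("BEN", -0.116), ("Midnight", 0.108), ("PN", -0.095), ("SI", -0.026),
        ),
        nonlinear_terms=(
            NonlinearTerm("UI", "inverted_u", (("amplitude", 0.15), ("center", 0.0))),
            NonlinearTerm("SS", "threshold", (("drop", 0.25), ("location", 0.5))),
            NonlinearTerm("SI", "u_shape", (("amplitude", 0.03), ("center", 0.8))),
        ),
        interactions=(("SE", "UI", 0.08),),
        noise_sd=0.30,
    )


def linear_structural_spec(noise_sd: float = 0.25) -> StructuralSpec:
    """Purely linear variant of the default spec (for estimator recovery)."""
    return replace(default_structural_spec(), nonlinear_terms=(), interactions=(),
                   noise_sd=noise_sd)


@dataclass(frozen=True)
class SurveyConfig:
    construct_specs: tuple[ConstructSpec, ...] = field(default_factory=default_construct_specs)
    within_corr: float = 0.30
    between_corr: float = 0.15
    structural: StructuralSpec = field(default_factory=default_structural_spec)
    outcome_mode: str = "direct"  # direct | pars3
    pars3: Pars3Config = field(default_factory=Pars3Config)
    continuous_items: bool = False

    def __post_init__(self):
        if self.outcome_mode not in ("direct", "pars3"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")


@dataclass
class SyntheticDataset:
    """A generated survey with its ground truth attached."""

    survey: pd.DataFrame          # 29 predictors + delta_z outcome
    latent: pd.DataFrame          # latent factor scores per construct
    items: pd.DataFrame           # raw Likert item table
    pars3: pd.DataFrame           # actual/ideal triples
    eta: np.ndarray               # noiseless structural signal
    true_effects: StructuralSpec
    seed: int
    config: SurveyConfig

    def to_csv(self, path, sidecar_path=None):
        """Write the survey table as CSV with a JSON provenance sidecar."""
        self.survey.to_csv(path, index=False)
        if sidecar_path is not None:
            meta = {
                "seed": self.seed,
                "n": int(len(self.survey)),
                "outcome": OUTCOME_COLUMN,
                "predictors": list(self.survey.columns[:-1]),
                "outcome_mode": self.config.outcome_mode,
                "noise_sd": self.true_effects.noise_sd,
                "linear_coeffs": dict(self.true_effects.linear_coeffs),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def generate_constructs(specs, n: int, corr=None, seed=None, rng=None,
                        continuous: bool = False):
    """Draw latent factors and their Likert item blocks.

    Items are linear in the construct factor with the specified loading and
    unique noise sd sqrt(1 - lambda^2); discretization (unless
    ``continuous``) assigns levels 1..n_levels by equal-probability normal
    quantile thresholds, preserving rank correlation with the factor.

    Returns (latent DataFrame n x k, items DataFrame).
    """
    specs = tuple(specs)
    if n < 2:
        raise ValueError("need n >= 2")
    names = [s.name for s in specs]
    if corr is None:
        corr = default_latent_correlation(names)
    R = np.asarray(corr, dtype=float)
    if R.shape != (len(specs), len(specs)):
        raise ValueError("correlation matrix does not match construct count")
    off = R[~np.eye(len(specs), dtype=bool)]
    if off.size and np.max(np.abs(off)) >= CORRELATION_BOUND:
        raise ValueError(
            f"latent correlations must satisfy |r| < {CORRELATION_BOUND}; "
            f"max |off-diagonal| = {np.max(np.abs(off)):.3f}"
        )
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        raise ValueError(f"correlation matrix is not positive semi-definite "
                         f"(min eigenvalue {eig.min():.3e})")
    rng = np.random.default_rng(seed) if rng is None else rng
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(specs)))
    F = rng.standard_normal((n, len(specs))) @ L.T
    latent = pd.DataFrame(F, columns=names)

    item_cols = {}
    for idx, spec in enumerate(specs):
        f = F[:, idx]
        for label, lam in zip(spec.item_labels, spec.loadings):
            y = lam * f + np.sqrt(max(0.0, 1.0 - lam**2)) * rng.standard_normal(n)
            if continuous:
                item_cols[label] = y
            else:
                cuts = stats.norm.ppf(np.arange(1, spec.n_levels) / spec.n_levels)
                item_cols[label] = (np.searchsorted(cuts, y) + 1).astype(float)
    return latent, pd.DataFrame(item_cols)


@lru_cache(maxsize=None)
def _fit_ordinal_probs(lo: int, hi: int, mean: float, sd: float):
    """Moment-fit a discretized-normal categorical on levels lo..hi.

    Probabilities p_k come from integrating a N(mu, sigma) density over
    unit-width bins around each level; (mu, sigma) are chosen to match the
    target mean and SD as closely as the support allows.
    """
    levels = np.arange(lo, hi + 1, dtype=float)
    edges = np.concatenate([[-np.inf], levels[:-1] + 0.5, [np.inf]])

    def probs(mu, sigma):
        c = stats.norm.cdf(edges, loc=mu, scale=sigma)
        p = np.diff(c)
        return p / p.sum()

    def loss(theta):
        mu, log_sigma = theta
        p = probs(mu, np.exp(log_sigma))
        m = float(np.sum(p * levels))
        v = float(np.sum(p * (levels - m) ** 2))
        return (m - mean) ** 2 + (np.sqrt(v) - sd) ** 2

    res = optimize.minimize(loss, x0=[mean, np.log(max(sd, 0.2))],
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    mu, log_sigma = res.x
    return levels, probs(mu, np.exp(log_sigma))


def generate_demographics(n: int, seed=None, rng=None) -> pd.DataFrame:
    """Sample the sixteen ordinal/continuous covariates at their target moments."""
    rng = np.random.default_rng(seed) if rng is None else rng
    cols = {}
    for name, (lo, hi, mean, sd) in ORDINAL_TARGETS.items():
        levels, p = _fit_ordinal_probs(lo, hi, mean, sd)
        cols[name] = rng.choice(levels, size=n, p=p)
    for name, (mean, sd) in CONTINUOUS_TARGETS.items():
        cols[name] = mean + sd * rng.standard_normal(n)
    return pd.DataFrame(cols, columns=list(DEMOGRAPHIC_COLUMNS))


def generate_pars3(n: int, seed=None, rng=None, config: Pars3Config | None = None,
                   propensity=None) -> pd.DataFrame:
    """Actual and ideal PARS-3 triples with ideal >= actual componentwise.

    Actual grades follow the configured categorical distributions; ideal
    grades are actual plus truncated binomial increments over the remaining
    headroom, with success rates optionally scaled by a per-respondent
    propensity (larger propensity -> larger aspiration inflation).
    """
    cfg = config or Pars3Config()
    rng = np.random.default_rng(seed) if rng is None else rng
    ranges = gap_mod.DEFAULT_RANGES
    dists = {"intensity": cfg.intensity_probs, "duration": cfg.duration_probs,
             "frequency": cfg.frequency_probs}
    if propensity is None:
        scale = np.ones(n)
    else:
        propensity = np.asarray(propensity, dtype=float)
        z = (propensity - propensity.mean()) / (propensity.std(ddof=0) or 1.0)
        scale = 2.0 / (1.0 + np.exp(-cfg.gap_link * z))  # in (0, 2), mean ~1

    out = {}
    for comp, rate in zip(gap_mod.PARS3_COMPONENTS, cfg.inflation_rates):
        lo, hi = ranges[comp]
        p = np.asarray(dists[comp], dtype=float)
        if p.size != hi - lo + 1:
            raise ValueError(f"{comp}: need {hi - lo + 1} level probabilities")
        actual = rng.choice(np.arange(lo, hi + 1), size=n, p=p / p.sum())
        headroom = hi - actual
        inc = rng.binomial(headroom, np.clip(rate * scale, 0.0, 1.0))
        out[f"actual_{comp}"] = actual
        out[f"ideal_{comp}"] = actual + inc
    return pd.DataFrame(out)


_SHAPES = {
    "inverted_u": lambda x, t: -t.param("amplitude") * (x - t.param("center")) ** 2,
    "threshold": lambda x, t: -t.param("drop") * (x > t.param("location")).astype(float),
    "u_shape": lambda x, t: t.param("amplitude") * (x - t.param("center")) ** 2,
}


def structural_signal(z: pd.DataFrame, spec: StructuralSpec) -> np.ndarray:
    """Noiseless structural value eta(z) on z-scored predictor columns."""
    missing = spec.referenced_columns() - set(z.columns)
    if missing:
        raise ValueError(f"structural spec references unknown columns: {sorted(missing)}")
    eta = np.zeros(len(z))
    for name, coeff in spec.linear_coeffs:
        eta += coeff * z[name].to_numpy(dtype=float)
    for term in spec.nonlinear_terms:
        if term.shape not in _SHAPES:
            raise ValueError(f"unknown shape {term.shape!r}")
        eta += _SHAPES[term.shape](z[term.construct].to_numpy(dtype=float), term)
    for a, b, coeff in spec.interactions:
        eta += coeff * z[a].to_numpy(dtype=float) * z[b].to_numpy(dtype=float)
    return eta


def generate_outcome(scores: pd.DataFrame, spec: StructuralSpec, seed=None,
                     rng=None, standardize: bool = True):
    """Outcome vector from the structural spec plus Gaussian noise.

    ``scores`` holds predictor columns (construct composites, covariates);
    with ``standardize`` they are z-scored before the spec is applied, so
    coefficients are per-SD effects. Returns (y, eta).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    z = scores.apply(lambda c: _zscore(c.to_numpy(dtype=float)), axis=0) \
        if standardize else scores
    eta = structural_signal(z, spec)
    y = eta + spec.noise_sd * rng.standard_normal(len(z))
    return y, eta


def generate_survey(n: int, seed: int = 0, config: SurveyConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic survey: 29 predictors + the delta_z outcome.

    Regenerating with the same (n, seed, config) reproduces the table
    bit-for-bit. In ``direct`` mode the outcome is the structural signal plus
    noise (exact ground truth); in ``pars3`` mode the structural signal
    drives the ideal-inflation of the PARS-3 triples and the outcome is the
    standardized gap computed from those triples.
    """
    cfg = config or SurveyConfig()
    if n < 10:
        raise ValueError("need n >= 10")
    ss = np.random.SeedSequence(seed)
    r_constructs, r_demo, r_pars, r_noise = (np.random.default_rng(c)
                                             for c in ss.spawn(4))

    names = [s.name for s in cfg.construct_specs]
    corr = default_latent_correlation(names, cfg.within_corr, cfg.between_corr)
    latent, items = generate_constructs(cfg.construct_specs, n, corr=corr,
                                        rng=r_constructs,
                                        continuous=cfg.continuous_items)
    scores = pd.DataFrame({s.name: items[list(s.item_labels)].mean(axis=1)
                           for s in cfg.construct_specs})
    demo = generate_demographics(n, rng=r_demo)
    predictors = pd.concat([scores, demo], axis=1)

    z = predictors.apply(lambda c: _zscore(c.to_numpy(dtype=float)), axis=0)
    eta = structural_signal(z, cfg.structural)

    if cfg.outcome_mode == "direct":
        pars3 = generate_pars3(n, rng=r_pars, config=cfg.pars3, propensity=eta)
        y = eta + cfg.structural.noise_sd * r_noise.standard_normal(n)
    else:
        pars3 = generate_pars3(n, rng=r_pars, config=cfg.pars3, propensity=eta)
        scored = gap_mod.score_table(pars3)
        y = scored["delta_z"].to_numpy()

    survey = predictors.copy()
    survey[OUTCOME_COLUMN] = y
    survey = survey[list(PREDICTOR_COLUMNS) + [OUTCOME_COLUMN]]
    return SyntheticDataset(survey=survey, latent=latent, items=items,
                            pars3=pars3, eta=eta, true_effects=cfg.structural,
                            seed=seed, config=cfg)
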