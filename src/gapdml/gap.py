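"""PARS-3 activity scoring and the standardized intention-behavior gap.

The Physical Activity Rating Scale-3 scores activity as the product
``intensity x duration x frequency`` of three ordinal grades. Under the
default coding (intensity 1-5, duration 0-4, frequency 1-5) the maximum is
100. The study outcome is the baseline-corrected gap

    dZ = (Ideal - Actual) / sigma_actual

where sigma_actual is the standard deviation of the actual scores over the
whole sample, so a raw gap of 20 points counts the same number of population
standard-deviation units regardless of an individual's baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default ordinal grade ranges: (min, max) per component
DEFAULT_RANGES: dict[str, tuple[int, int]] = {
    "intensity": (1, 5),
    "duration": (0, 4),
    "frequency": (1, 5),
}

PARS3_COMPONENTS = ("intensity", "duration", "frequency")


@dataclass(frozen=True)
class GapScores:
    """Per-respondent activity scores and gap measures."""

    actual: np.ndarray
    ideal: np.ndarray
    raw_gap: np.ndarray
    delta_z: np.ndarray
    sigma_actual: float
    sd_convention: str = "sample"


def pars3_score(intensity, duration, frequency, ranges=None):
    """PARS-3 score: intensity x duration x frequency (default max 100).

    Accepts scalars or equal-length arrays; grades outside the configured
    coding ranges are rejected.
    """
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    parts = {"intensity": np.asarray(intensity), "duration": np.asarray(duration),
             "frequency": np.asarray(frequency)}
    for name, vals in parts.items():
        lo, hi = ranges[name]
        if np.any(vals < lo) or np.any(vals > hi):
            raise ValueError(
                f"{name} grade outside configured range [{lo}, {hi}]: "
                f"min={vals.min()}, max={vals.max()}"
            )
    out = parts["intensity"] * parts["duration"] * parts["frequency"]
    return out.item() if np.isscalar(intensity) else out


def raw_gap(ideal, actual):
    """Un-normalized gap Ideal - Actual (the traditional absolute gap Z)."""
    return np.asarray(ideal) - np.asarray(actual) if not np.isscalar(ideal) else ideal - actual


def delta_z(ideal, actual, sd_convention: str = "sample"):
    """Standardized gap (Ideal - Actual) / sigma_actual.

    Parameters
    ----------
    ideal, actual : array-like, equal length >= 2
        Ideal and actual PARS-3 scores.
    sd_convention : {"sample", "population"}
        Denominator of sigma_actual (n-1 or n). The choice rescales every
        dZ by the same constant and is recorded on the result.

    Returns
    -------
    GapScores
    """
    ideal = np.asarray(ideal, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if ideal.shape != actual.shape or ideal.ndim != 1:
        raise ValueError("ideal and actual must be equal-length 1-d vectors")
    if ideal.size < 2:
        raise ValueError("need at least 2 respondents to estimate sigma_actual")
    if sd_convention not in ("sample", "population"):
        raise ValueError(f"unknown sd convention {sd_convention!r}")
    ddof = 1 if sd_convention == "sample" else 0
    sigma = float(np.std(actual, ddof=ddof))
    if sigma == 0.0:
        raise ValueError("actual scores are constant: sigma_actual = 0, delta_z undefined")
    gap = ideal - actual
    return GapScores(actual=actual, ideal=ideal, raw_gap=gap,
                     delta_z=gap / sigma, sigma_actual=sigma,
                     sd_convention=sd_convention)


def score_table(triples: pd.DataFrame, sd_convention: str = "sample",
                ranges=None) -> pd.DataFrame:
    """Score a table of actual/ideal PARS-3 triples.

    Expects columns ``actual_intensity, actual_duration, actual_frequency``
    and the ``ideal_*`` counterparts; returns a frame with actual/ideal
    scores, the raw gap Z and the standardized gap dZ.
    """
    actual = pars3_score(triples["actual_intensity"], triples["actual_duration"],
                         triples["actual_frequency"], ranges=ranges)
    ideal = pars3_score(triples["ideal_intensity"], triples["ideal_duration"],
                        triples["ideal_frequency"], ranges=ranges)
    scores = delta_z(ideal, actual, sd_convention=sd_convention)
    return pd.DataFrame({
        "actual_score": scores.actual,
        "ideal_score": scores.ideal,
        "raw_gap": scores.raw_gap,
        "delta_z": scores.delta_z,
    }, index=triples.index)
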