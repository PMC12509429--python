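"""Survey instruments: item pools, standardized loadings, and coding frames.

The analysis measures thirteen composite constructs on 7-point Likert items —
five Health Belief Model (HBM) constructs (perceived benefits BEN, affective
attitude AT, perceived barriers BAR, perceived severity SEV, self-efficacy SE)
and eight smart-sport-tool constructs from the Unified Theory of Acceptance
and Use of Technology (UTAUT: performance expectancy PE, effort expectancy EE,
social influence SI, facilitating conditions FC, personal innovation PN,
perceived risk PR, social support SS, usage intention UI) — alongside sixteen
ordinal physical-activity, demographic and lifestyle covariates.

The standardized loading vectors and the ordinal coding frames below are the
published calibration of the instrument; they are inputs to the pipeline, not
quantities it estimates.
"""

from __future__ import annotations

# Standardized factor loadings per construct, in item order.
HBM_LOADINGS: dict[str, tuple[float, ...]] = {
    "BEN": (0.850, 0.913),
    "AT": (0.897, 0.824),
    "BAR": (0.504, 0.728, 0.730, 0.741, 0.651),
    "SEV": (0.723, 0.761, 0.858),
    "SE": (0.829, 0.934, 0.942, 0.837),
}

UTAUT_LOADINGS: dict[str, tuple[float, ...]] = {
    "PE": (0.915, 0.938, 0.919, 0.844),
    "EE": (0.900, 0.915, 0.921),
    "SI": (0.836, 0.955, 0.884),
    "FC": (0.820, 0.871, 0.828),
    "PN": (0.867, 0.864, 0.925, 0.895),
    "PR": (0.663, 0.819, 0.858, 0.746, 0.822),
    "SS": (0.737, 0.814, 0.864, 0.875),
    "UI": (0.929, 0.936, 0.883, 0.927),
}

DEFAULT_LOADINGS: dict[str, tuple[float, ...]] = {**HBM_LOADINGS, **UTAUT_LOADINGS}

HBM_CONSTRUCTS: tuple[str, ...] = tuple(HBM_LOADINGS)
UTAUT_CONSTRUCTS: tuple[str, ...] = tuple(UTAUT_LOADINGS)
ALL_CONSTRUCTS: tuple[str, ...] = HBM_CONSTRUCTS + UTAUT_CONSTRUCTS

# Ordinal covariates: (lowest level, highest level, target mean, target SD).
# Sm_number is coded 0-3 with 0 = non-user (a 1-3 support cannot carry the
# target SD of 1.152; 0 mirrors the non-user level of Sm_duration).
ORDINAL_TARGETS: dict[str, tuple[int, int, float, float]] = {
    "PA_level": (1, 4, 2.27, 0.777),
    "PA_organize": (1, 3, 1.36, 0.479),
    "PA_purpose": (1, 7, 4.11, 1.856),
    "PA_comsume": (1, 5, 1.82, 0.980),
    "Sm_duration": (0, 5, 1.45, 1.324),
    "Sm_frequency": (0, 4, 1.57, 1.109),
    "Sm_number": (0, 3, 1.51, 1.152),
    "Sm_purpose": (1, 7, 2.93, 2.017),
    "Sex": (1, 2, 1.51, 0.500),
    "Age": (1, 4, 2.13, 1.046),
    "Career": (1, 4, 2.57, 1.104),
    "Education": (1, 4, 2.58, 0.874),
    "Consumption_level": (1, 5, 2.61, 0.841),
    "Health": (1, 5, 3.48, 0.910),
    "Midnight": (1, 5, 3.44, 1.205),
}

# Continuous covariates: (target mean, target SD).
CONTINUOUS_TARGETS: dict[str, tuple[float, float]] = {
    "BMI": (21.31, 2.948),
}

DEMOGRAPHIC_COLUMNS: tuple[str, ...] = tuple(ORDINAL_TARGETS) + tuple(CONTINUOUS_TARGETS)

PREDICTOR_COLUMNS: tuple[str, ...] = ALL_CONSTRUCTS + DEMOGRAPHIC_COLUMNS
OUTCOME_COLUMN = "delta_z"

# The eight focal treatments carried through attribution and effect estimation.
FOCAL_TREATMENTS: tuple[str, ...] = ("BAR", "SE", "UI", "SS", "BEN", "Midnight", "PN", "SI")

# Dimension aggregates used when summarising attribution output.
DIMENSION_MAP: dict[str, tuple[str, ...]] = {
    "psychological_cognition": ("BAR", "SE"),
    "smart_sport": ("UI", "SS"),
}

# Encoding schema: nominal covariates are one-hot encoded, everything else
# (construct composites and ordered scales) is z-scored.
DEFAULT_SCHEMA: dict[str, str] = {
    **{c: "continuous" for c in ALL_CONSTRUCTS},
    **{c: "continuous" for c in DEMOGRAPHIC_COLUMNS},
    "Sex": "categorical",
    "Career": "categorical",
    "PA_organize": "categorical",
}
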