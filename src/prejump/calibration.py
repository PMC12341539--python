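"""Built-in calibration values for the pre-jump-height indicator system.

The published study of 16 juvenile trampoline gymnasts reports, for each of
the 16 representative indicators, the cohort mean ± SD, the Pearson
correlation with pre-jump height, and the grey relational grade.  The raw
athlete data were not deposited, so these summary values are the only
quantitative anchor available; they are embedded here (verbatim, at printed
precision) as the default moment specification for the synthetic-cohort
generator and as reference grades for classification checks.

Rows are ordered by published grey relational rank.  Units follow the
published table (cm, degrees, ratios, questionnaire scores); the standing
long jump value is stored exactly as printed.
"""

from __future__ import annotations

import pandas as pd

from .synthetic_cohort import MomentSpec

__all__ = [
    "CRITERION_NAME",
    "reference_moment_spec",
    "reference_grade_table",
]

CRITERION_NAME = "Pre-jump height"
CRITERION_MEAN = 3.13  # metres
CRITERION_SD = 0.36

# (indicator, mean, sd, pearson r with criterion, grey relational grade)
_INDICATORS: list[tuple[str, float, float, float, float]] = [
    ("Standing long jump", 212.75, 17.64, 0.871, 0.9469),
    ("Height", 152.66, 9.98, 0.840, 0.9428),
    ("Leg length", 0.565, 0.011, 0.875, 0.9408),
    ("Shoulder width", 0.195, 0.007, 0.762, 0.9369),
    ("Arm hang angle", 173.44, 5.15, 0.627, 0.9345),
    ("Counter-jump height/pre-jump height ratio", 0.144, 0.015, 0.754, 0.9316),
    ("30-s hanging leg raise", 19.69, 1.16, 0.686, 0.9315),
    ("BMI", 17.23, 1.62, 0.771, 0.9288),
    ("Hip joint angle at landing", 21.14, 2.19, 0.675, 0.9203),
    ("State anxiety", 37.44, 6.13, -0.631, 0.9116),
    ("Trampoline-induced acrophobic sensations", 13.31, 3.49, -0.554, 0.8659),
    ("Daily acrophobic sensations", 40.81, 18.60, 0.495, 0.8274),
    ("Ankle joint cushioning amplitude", 10.15, 5.09, 0.576, 0.8023),
    ("10-s time perception", 0.209, 0.144, -0.287, 0.7486),
    ("Supine straight-leg raise at 45 degrees perception", 4.56, 4.15, -0.254, 0.6732),
    ("10 self-rotations perception", 66.69, 78.17, -0.292, 0.6574),
]


def reference_moment_spec() -> MomentSpec:
    """Moment specification calibrated to the published cohort summary."""
    return MomentSpec(
        indicator_names=tuple(row[0] for row in _INDICATORS),
        means=tuple(row[1] for row in _INDICATORS),
        sds=tuple(row[2] for row in _INDICATORS),
        criterion_name=CRITERION_NAME,
        criterion_mean=CRITERION_MEAN,
        criterion_sd=CRITERION_SD,
        criterion_corrs=tuple(row[3] for row in _INDICATORS),
    )


def reference_grade_table() -> pd.DataFrame:
    """Published Pearson correlations and grey relational grades, by rank."""
    return pd.DataFrame(
        _INDICATORS, columns=["Indicator", "mean", "sd", "Pearson_r", "Grey_grade"]
    )[["Indicator", "Pearson_r", "Grey_grade"]]
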