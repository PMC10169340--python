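"""Shared predictor vocabulary for the least-regular-care model.

Defines the categorical predictors with their level order and reference
level, the binary condition predictors, canonical term names for dummy
columns, and the default simulation ground truth: the marginal composition
of a large Israeli HMO chronic-disease cohort (n = 70,095, patients age 40+
with heart failure, COPD or diabetes) and the adjusted odds ratios of its
fully adjusted least-regular-quintile model.  Term names are shared between
the synthetic generator (which uses the log odds ratios as ground-truth
effects) and the design encoder (which recovers them), so the two ends of
the pipeline can never drift apart.
"""
from __future__ import annotations

import math

N_REFERENCE_COHORT = 70_095

AGE_LEVELS = ["40-49", "50-59", "60-69", "70-79", "80-89", "90+"]
# Age is anchored to 2015 (the year patient-level variables refer to), so the
# 40-49 band corresponds to birth years 1966-1975.
BIRTH_YEAR_BANDS = {
    "40-49": (1966, 1975),
    "50-59": (1956, 1965),
    "60-69": (1946, 1955),
    "70-79": (1936, 1945),
    "80-89": (1926, 1935),
    "90+": (1910, 1925),
}
SEX_LEVELS = ["female", "male"]
ETHNIC_LEVELS = ["general", "arab", "ultra_orthodox"]
REGION_LEVELS = ["central", "north", "jerusalem", "south"]
SES_LEVELS = ["highest", "higher", "lower", "lowest"]
# Area SES deciles grouped: 1-3 poorest .. 8-10 wealthiest.
SES_DECILES = {"lowest": (1, 3), "lower": (4, 5), "higher": (6, 7), "highest": (8, 10)}
EGFR_LEVELS = ["60+", "45-59", "30-44", "<30"]

# (column, ordered levels, reference level)
CATEGORICAL_PREDICTORS = [
    ("age_group", AGE_LEVELS, "40-49"),
    ("sex", SEX_LEVELS, "female"),
    ("ethnic_group", ETHNIC_LEVELS, "general"),
    ("region", REGION_LEVELS, "central"),
    ("ses_group", SES_LEVELS, "highest"),
    ("egfr_category", EGFR_LEVELS, "60+"),
]

PHYSICAL_CONDITIONS = [
    "atrial_fibrillation", "cancer", "chronic_lung_disease", "cad_angina",
    "cad_mi", "dementia", "diabetes", "epilepsy", "heart_failure",
    "hypertension", "ibd", "osteoporosis", "peripheral_arterial_disease",
    "rheumatoid_arthritis", "stroke_history", "venous_thromboembolism",
]
MENTAL_CONDITIONS = [
    "alcohol_misuse", "adhd", "anxiety", "bipolar", "depression", "ptsd",
    "schizophrenia",
]
INDEX_CONDITIONS = ["heart_failure", "chronic_lung_disease", "diabetes"]
BINARY_PREDICTORS = PHYSICAL_CONDITIONS + ["current_smoker"] + MENTAL_CONDITIONS


def term_name(column: str, level: str | None = None) -> str:
    return column if level is None else f"{column}:{level}"


def model_terms() -> list[str]:
    """Ordered non-reference term names of the fully adjusted model."""
    terms: list[str] = []
    for col, levels, ref in CATEGORICAL_PREDICTORS:
        terms.extend(term_name(col, lv) for lv in levels if lv != ref)
    terms.extend(BINARY_PREDICTORS)
    return terms


# Adjusted odds ratios of the reference cohort's fully adjusted model;
# ln(OR) is the ground-truth effect used by the synthetic generator.
DEFAULT_ADJUSTED_OR: dict[str, float] = {
    "age_group:50-59": 0.92,
    "age_group:60-69": 0.86,
    "age_group:70-79": 0.83,
    "age_group:80-89": 0.86,
    "age_group:90+": 0.90,
    "sex:male": 1.19,
    "ethnic_group:arab": 1.19,
    "ethnic_group:ultra_orthodox": 1.10,
    "region:north": 1.04,
    "region:jerusalem": 1.10,
    "region:south": 1.00,
    "ses_group:higher": 1.09,
    "ses_group:lower": 1.07,
    "ses_group:lowest": 1.06,
    "egfr_category:45-59": 0.98,
    "egfr_category:30-44": 1.00,
    "egfr_category:<30": 1.00,
    "atrial_fibrillation": 1.08,
    "cancer": 0.85,
    "chronic_lung_disease": 0.93,
    "cad_angina": 0.90,
    "cad_mi": 1.07,
    "dementia": 1.05,
    "diabetes": 0.79,
    "epilepsy": 0.94,
    "heart_failure": 0.98,
    "hypertension": 0.92,
    "ibd": 1.00,
    "osteoporosis": 0.85,
    "peripheral_arterial_disease": 0.92,
    "rheumatoid_arthritis": 0.92,
    "current_smoker": 1.12,
    "stroke_history": 0.94,
    "venous_thromboembolism": 1.09,
    "alcohol_misuse": 1.28,
    "adhd": 0.91,
    "anxiety": 0.91,
    "bipolar": 1.12,
    "depression": 0.92,
    "ptsd": 0.97,
    "schizophrenia": 0.80,
}

DEFAULT_TRUE_LOG_ODDS = {k: math.log(v) for k, v in DEFAULT_ADJUSTED_OR.items()}

# Marginal cell counts of the reference cohort, used as sampling weights.
# SES and ethnic-group counts do not sum to n in the published profile; they
# are renormalised to probabilities when sampling.
AGE_COUNTS = {"40-49": 8890, "50-59": 18333, "60-69": 22831,
              "70-79": 13424, "80-89": 5907, "90+": 710}
SEX_COUNTS = {"male": 35066, "female": 35029}
ETHNIC_COUNTS = {"arab": 11345, "ultra_orthodox": 4166, "general": 53959}
REGION_COUNTS = {"north": 18234, "central": 21234, "jerusalem": 9196, "south": 21431}
SES_COUNTS = {"highest": 5821, "higher": 11263, "lower": 30285, "lowest": 11263}
EGFR_COUNTS = {"60+": 55294, "45-59": 8056, "30-44": 4205, "<30": 2540}

# Condition prevalences among included patients (cell count / n).  Headache
# has a prevalence but no diagnosis code list and is not a model predictor;
# it is carried for completeness of the cohort profile only.
CONDITION_COUNTS: dict[str, int] = {
    "atrial_fibrillation": 8548,
    "cancer": 7693,
    "chronic_lung_disease": 20279,
    "cad_angina": 20270,
    "cad_mi": 7612,
    "dementia": 820,
    "diabetes": 54899,
    "epilepsy": 643,
    "headache": 4671,
    "heart_failure": 11761,
    "hypertension": 32414,
    "ibd": 1233,
    "osteoporosis": 14385,
    "peripheral_arterial_disease": 7572,
    "rheumatoid_arthritis": 1965,
    "current_smoker": 13672,
    "stroke_history": 3302,
    "venous_thromboembolism": 3709,
    "alcohol_misuse": 215,
    "adhd": 1272,
    "anxiety": 20860,
    "bipolar": 998,
    "depression": 19789,
    "ptsd": 1795,
    "schizophrenia": 1353,
}

DEFAULT_PREVALENCES = {k: v / N_REFERENCE_COHORT for k, v in CONDITION_COUNTS.items()}
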