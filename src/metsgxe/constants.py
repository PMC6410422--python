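"""Shared constants: AAM categories, MetS cutoffs, and reference cohort figures.

The reference figures come from the published KARE descriptive table for
3,180 Korean women (ages 40-69); they parameterise the synthetic-data
generator and the desk-scale consistency checks.
"""

from __future__ import annotations

# Age-at-menarche (AAM) categories, in years. 11 and 12 are pooled because
# of small numbers at the early tail; 17 and 18 are pooled likewise.
AAM_CATEGORIES: tuple[str, ...] = ("<=12", "13", "14", "15", "16", ">=17")
REFERENCE_CATEGORY: str = "16"
EARLY_CATEGORY: str = "<=12"

# AAM values retained after exclusions (<=10, >=19 and missing are dropped).
AAM_MIN, AAM_MAX = 11, 18

# Published per-category counts for the 3,180-woman reference cohort.
KARE_CATEGORY_COUNTS: dict[str, int] = {
    "<=12": 77,
    "13": 269,
    "14": 531,
    "15": 669,
    "16": 689,
    ">=17": 945,
}
KARE_TOTAL_N: int = 3180

# Post-QC SNP count of the reference genome-wide scan (Affymetrix 5.0 array).
KARE_N_SNPS: int = 344_396

# NCEP-ATP III metabolic-syndrome component cutoffs for women, with the
# Korean waist-circumference criterion. ">=" cutoffs are inclusive, "<" strict.
WC_CUTOFF_CM: float = 85.0        # central obesity: WC >= 85
TG_CUTOFF_MGDL: float = 150.0     # hypertriglyceridemia: TG >= 150
HDL_CUTOFF_MGDL: float = 50.0     # low HDL: HDL < 50
SBP_CUTOFF_MMHG: float = 130.0    # hypertension: SBP >= 130 or DBP >= 85 or meds
DBP_CUTOFF_MMHG: float = 85.0
FG_CUTOFF_MGDL: float = 100.0     # high fasting glucose: FG >= 100 or meds
METS_MIN_CRITERIA: int = 3

# Default adjustment covariates for all regression models.
DEFAULT_COVARIATES: tuple[str, ...] = ("age", "area", "income", "education", "crp")

# Mandatory columns of a raw cohort table.
COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id", "aam", "sbp", "dbp", "fg", "fi", "wc", "tg", "hdl",
    "antihypertensive_med", "antidiabetic_med", "age", "area", "income",
    "education", "crp", "smoking", "alcohol", "obs_score",
)
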