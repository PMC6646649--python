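"""Reference operating figures from a published sequential AI-CAD
mammography reader study (seven readers, 90 missed-cancer priors + 32
normals, read once unaided and once with CAD marks).

These printed per-reader table values serve two purposes: they are the
calibration targets for the synthetic-study generator's default
"published-marginals" configuration, and they are inputs to the worked
examples and reproduction script (group means, conservation identities,
AUC-change arithmetic). They are data about the study design, not
outputs of this package.
"""

from __future__ import annotations

N_CANCER = 90
N_NORMAL = 32
N_READERS = 7

READER_IDS = tuple(f"reader{i}" for i in range(1, 8))
READER_YEARS = (3, 3, 42, 5, 6, 3, 19)

# Per-reader cancer detection rate (% of the 90 cancer cases recalled),
# before and after the CAD second look, with the printed deltas.
CDR_PRE_PCT = (42, 54, 25, 46, 71, 56, 61)
CDR_POST_PCT = (68, 68, 41, 53, 75, 60, 67)
CDR_INCREASE_PCT = (26, 14, 16, 7, 4, 4, 6)
CDR_PCT_CHANGE = (62, 26, 64, 15, 6, 7, 10)

# Per-reader false-positive recalls over the 32 normal cases:
# count before, conversions to recall, reversals of recall, count after.
FP_PRE = (7, 6, 4, 8, 6, 9, 9)
FP_INCREASE = (4, 2, 2, 0, 0, 0, 0)
FP_REDUCTION = (3, 0, 1, 2, 0, 0, 0)
FP_POST = (8, 8, 5, 6, 6, 9, 9)

# Per-class decision accounting over the cancer cases
# (17 calcification-leading cases, 73 mass-leading cases):
# unaided recalls, conversions after a CAD flag, ignored CAD flags.
CALC_RECALLED_PRE = (8, 9, 1, 7, 14, 5, 8)
CALC_ADDITIONAL = (6, 3, 8, 1, 1, 2, 3)
CALC_IGNORED = (3, 5, 8, 9, 2, 10, 6)
MASS_RECALLED_PRE = (30, 40, 22, 34, 50, 45, 47)
MASS_ADDITIONAL = (17, 10, 6, 5, 3, 2, 2)
MASS_IGNORED = (8, 9, 22, 16, 10, 8, 7)

N_CALC_CASES = 17
N_MASS_CASES = 73

# Lesion composition of the 90 cancer cases. Tuples are ordered with
# the leading component first (which fixes the calc/mass dichotomy:
# 16 pure-calcification + 1 calcification-leading mixed case = 17 calc).
LESION_MIX = (
    (("mass",), 50),
    (("microcalcifications",), 16),
    (("mass", "microcalcifications"), 9),
    (("architectural_distortion",), 5),
    (("mass", "architectural_distortion"), 4),
    (("asymmetry",), 3),
    (("architectural_distortion", "microcalcifications"), 1),
    (("microcalcifications", "asymmetry"), 1),
    (("focal_asymmetry",), 1),
)

# Breast-density mix of the cancer cases (categories 1-4).
DENSITY_COUNTS = (4, 43, 37, 6)

# Pooled readers-as-a-group AUCs (aggregate 0-7 recall score).
POOLED_AUC_PRE = 0.7599
POOLED_AUC_POST = 0.8148

# Stand-alone CAD figures on this case set.
CAD_CASE_SENSITIVITY = 0.98
CAD_STANDALONE_AUC = 0.66

# Cohort accounting stage counts (biopsy population -> reader-study set).
COHORT_TOTAL_PATIENTS = 1393
COHORT_CANCER_BIOPSY = 499
COHORT_BENIGN_BIOPSY = 973
COHORT_BOTH_BIOPSY = 79
COHORT_WITH_PRIORS = 317
COHORT_RETROSPECTIVE = 139
COHORT_DE_NOVO = 178
COHORT_ACTIONABLE = 90
COHORT_NON_ACTIONABLE = 40
COHORT_EXCLUDED = 9
COHORT_ACTIONABLE_EXAMS = 155
PRIOR_GAP_DAYS = (271, 2117)  # > 270-day rule; max observed 5.8 years
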