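"""Published composition of the Yunnan lung-cancer cohort.

The retrospective cohort behind this package was never deposited; what is
public is its stratified composition (counts by region of residence and mode
of diagnosis) and a handful of crude case-fatality counts. Those printed
counts are inputs to the analysis: they anchor the Table-1-style derived
quantities (sex ratios, screened fractions), calibrate the synthetic-cohort
generator defaults, and supply the observed (p1, p2, p3) that drive the
length-bias correction.

Strata are keyed ``(region, screened)`` with region in ``{"XF", "nonXF"}``
(XF = Xuanwei–Fuyuan, the coal-pollution-exposed counties of Yunnan).
"""

from __future__ import annotations

# Stratum sizes: region x diagnosed-by-screening.
STRATUM_N = {
    ("nonXF", False): 2565,
    ("nonXF", True): 143,
    ("XF", False): 574,
    ("XF", True): 123,
}

# Counts per categorical variable, per stratum, same key order as STRATUM_N.
# Values are {level: count} dictionaries.
STRATUM_COUNTS = {
    "sex": {
        ("nonXF", False): {"female": 708, "male": 1857},
        ("nonXF", True): {"female": 65, "male": 78},
        ("XF", False): {"female": 218, "male": 356},
        ("XF", True): {"female": 52, "male": 71},
    },
    "ethnicity": {
        ("nonXF", False): {"Han": 2364, "nonHan": 201},
        ("nonXF", True): {"Han": 137, "nonHan": 6},
        ("XF", False): {"Han": 566, "nonHan": 8},
        ("XF", True): {"Han": 122, "nonHan": 1},
    },
    "stage": {
        ("nonXF", False): {"I": 192, "II": 188, "III": 799, "IV": 1380},
        ("nonXF", True): {"I": 63, "II": 14, "III": 36, "IV": 28},
        ("XF", False): {"I": 119, "II": 69, "III": 155, "IV": 230},
        ("XF", True): {"I": 55, "II": 25, "III": 27, "IV": 16},
    },
    "histology": {
        ("nonXF", False): {"adenocarcinoma": 1017, "other": 466, "small_cell": 341, "squamous": 741},
        ("nonXF", True): {"adenocarcinoma": 105, "other": 18, "small_cell": 5, "squamous": 15},
        ("XF", False): {"adenocarcinoma": 342, "other": 100, "small_cell": 46, "squamous": 86},
        ("XF", True): {"adenocarcinoma": 103, "other": 12, "small_cell": 3, "squamous": 5},
    },
    "bmi_category": {
        ("nonXF", False): {"underweight": 307, "normal": 1311, "overweight": 478, "obese": 430},
        ("nonXF", True): {"underweight": 6, "normal": 70, "overweight": 32, "obese": 35},
        ("XF", False): {"underweight": 55, "normal": 293, "overweight": 115, "obese": 107},
        ("XF", True): {"underweight": 4, "normal": 66, "overweight": 28, "obese": 25},
    },
    "smoker": {
        ("nonXF", False): {"no": 1247, "yes": 1318},
        ("nonXF", True): {"no": 99, "yes": 44},
        ("XF", False): {"no": 306, "yes": 268},
        ("XF", True): {"no": 74, "yes": 49},
    },
    "surgery": {
        ("nonXF", False): {"no": 1958, "yes": 607},
        ("nonXF", True): {"no": 33, "yes": 110},
        ("XF", False): {"no": 292, "yes": 282},
        ("XF", True): {"no": 17, "yes": 106},
    },
    "chemo": {
        ("nonXF", False): {"no": 963, "yes": 1602},
        ("nonXF", True): {"no": 49, "yes": 94},
        ("XF", False): {"no": 233, "yes": 341},
        ("XF", True): {"no": 54, "yes": 69},
    },
    "radio": {
        ("nonXF", False): {"no": 2138, "yes": 427},
        ("nonXF", True): {"no": 126, "yes": 17},
        ("XF", False): {"no": 497, "yes": 77},
        ("XF", True): {"no": 115, "yes": 8},
    },
    "targeted": {
        ("nonXF", False): {"no": 2276, "yes": 289},
        ("nonXF", True): {"no": 131, "yes": 12},
        ("XF", False): {"no": 542, "yes": 32},
        ("XF", True): {"no": 116, "yes": 7},
    },
}

# Crude case-fatality inputs of the length-bias correction, as printed:
# deaths within 5 years / group size for symptomatic and screen-detected
# cases, and the screened share of the cohort. The denominators (3148, 270,
# 3415) come from a slightly different accounting than the analyzed 3405;
# both sets of figures are stored at face value.
FATALITY_COUNTS = {
    "symptomatic_deaths_5y": 1829,
    "symptomatic_n": 3148,
    "screened_deaths_5y": 57,
    "screened_n": 270,
    "cohort_n": 3415,
}

# Published multivariate Cox log-hazard-ratios (full-cohort model); used as
# realistic effect sizes when calibrating the synthetic-cohort generator.
PUBLISHED_LOG_HR = {
    "age_gt65": 0.131,
    "sex_male": 0.189,
    "ethnicity_Han": 0.228,
    "stage_II": 0.959,
    "stage_III": 1.40,
    "stage_IV": 1.88,
    "surgery": -0.731,
    "chemo": -0.413,
    "radio": -0.244,
    "targeted": -0.313,
    "region_XF": -0.238,
    "screened": -0.441,
}

# Mean sojourn time of preclinical lung cancer reported by the Mayo Lung
# Project, in years; 1/2.24 ~ 0.45 per year is the generative default rate.
MAYO_MEAN_SOJOURN_YEARS = 2.24
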