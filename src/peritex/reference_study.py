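"""Published summary numbers of the reference clinical study.

The pipeline in this package mirrors a published pilot study that applied
peritumoral-zone CT texture analysis to distinguish high-grade gliomas
(HGGs, n = 17) from solitary brain metastases (BMs, n = 19).  The patient
images are not public, but the study's printed summary tables — the
selection shortlists, univariate p-values, the exclusion cascade, and the
combined prediction model's operating point — are usable inputs for
consistency checks of the workflow arithmetic (threshold bookkeeping,
significance counts, Youden index recomputation).  Values are transcribed
as printed; p-values reported only as "< 0.001" carry ``censored=True`` and
a ``p_value`` equal to that bound.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GROUP_SIZES",
    "INITIAL_REPORTS",
    "REPORT_LEVEL_EXCLUSIONS",
    "PATIENT_LEVEL_EXCLUSIONS",
    "FISHER_SHORTLIST",
    "POE_ACC_SHORTLIST",
    "UNIVARIATE_TABLE",
    "STATED_ALPHA",
    "STATED_M",
    "STATED_THRESHOLD",
    "MODEL_SENSITIVITY_PCT",
    "MODEL_SPECIFICITY_PCT",
    "MODEL_CRITERION",
    "MODEL_AUC",
    "MODEL_R2",
    "MODEL_R2_ADJUSTED",
    "MODEL_MCC",
]

#: (HGG, BM) group sizes of the final study population.
GROUP_SIZES = (17, 19)

#: Radiology-report search hits before any exclusion.
INITIAL_REPORTS = 686

#: Report-level exclusions (label, count); 686 -> 499 medical records.
REPORT_LEVEL_EXCLUSIONS = [
    ("extra-axial tumors", 54),
    ("infratentorial tumors", 60),
    ("intraventricular tumors", 5),
    ("multiple intra-axial tumors", 68),
]

#: Patient-level exclusions applied to the 499 records; ends at 36 included.
PATIENT_LEVEL_EXCLUSIONS = [
    ("benign, infectious or inflammatory lesions", 58),
    ("circumscript or low-grade gliomas", 29),
    ("no final histopathological result", 35),
    ("recurrences of malignant lesions", 54),
    ("non-enhanced CT scans", 71),
    ("post-operatory control studies", 186),
    ("tumor affected by artifacts", 9),
    ("peritumoral zone narrower than 10 mm", 21),
]


@dataclass(frozen=True)
class UnivariateEntry:
    """One row of the published univariate screening table."""

    parameter: str
    method: str  # which reduction shortlist printed the row
    p_value: float
    censored: bool  # True when printed as "< bound"
    median_hgg: float
    iqr_hgg: tuple[float, float]
    median_bm: float
    iqr_bm: tuple[float, float]


UNIVARIATE_TABLE: list[UnivariateEntry] = [
    UnivariateEntry("Perc10", "fisher", 0.001, True, 32.8, (24, 38), 8.12, (6, 14)),
    UnivariateEntry("WavEnHH_s-2", "fisher", 0.0013, False, 8.5, (3.95, 10.87), 15.8, (11, 20.1)),
    UnivariateEntry("CN6D4Contrast", "fisher", 0.001, True, 32.15, (24.3, 37.8), 18.6, (8.6, 22.14)),
    UnivariateEntry("Teta3", "fisher", 0.6, False, 0.17, (0.01, 0.41), 0.19, (0.13, 0.61)),
    UnivariateEntry("Kurtosis", "fisher", 0.33, False, 10.6, (0.13, 68.4), 18.8, (28.2, 59.3)),
    UnivariateEntry("CN6D5Correlat", "fisher", 0.06, False, 0.58, (0.51, 0.77), 0.51, (0.26, 0.64)),
    UnivariateEntry("RZD5GLevNonU", "fisher", 0.001, True, 3041.8, (1310.7, 3969.2), 1081.2, (641.01, 1922.92)),
    UnivariateEntry("RZD3Fraction", "fisher", 0.041, False, 0.77, (0.7, 0.81), 0.68, (0.41, 0.77)),
    UnivariateEntry("CH5D4DifVarnc", "fisher", 0.001, True, 20.43, (12.51, 24.8), 6.23, (3.3, 15.6)),
    UnivariateEntry("Perc50", "fisher", 0.07, False, 19.24, (11, 26), 16.43, (7, 25)),
    UnivariateEntry("CZ2D4DifVarnc", "poe_acc", 0.001, True, 22.13, (12.94, 26.11), 7.26, (3.81, 15.41)),
    UnivariateEntry("WavEnHL_s-3", "poe_acc", 0.001, True, 10.65, (5.33, 21.12), 28.68, (16.2, 38.02)),
    UnivariateEntry("CV3S6SumAverg", "poe_acc", 0.049, False, 64.15, (39.12, 84.9), 52.8, (26.7, 74.17)),
    UnivariateEntry("RVD6LngREmph", "poe_acc", 0.62, False, 2.31, (1.81, 3.19), 5.73, (2.46, 38.14)),
    UnivariateEntry("CZ5S6Correlat", "poe_acc", 0.01, False, 0.56, (0.21, 0.82), 0.29, (0.01, 0.65)),
    UnivariateEntry("CN4S6Entropy", "poe_acc", 0.03, False, 1.13, (0.04, 2.27), 3.01, (1.7, 5.89)),
    UnivariateEntry("CV1S6AngScMom", "poe_acc", 0.46, False, 0.12, (0.01, 0.22), 0.29, (0.06, 0.36)),
]

#: Ten-feature shortlist of the Fisher-coefficient reduction.
FISHER_SHORTLIST = [e.parameter for e in UNIVARIATE_TABLE if e.method == "fisher"]

#: Ten-feature shortlist of the POE+ACC reduction: its seven table rows plus
#: the three parameters both methods selected.
POE_ACC_SHORTLIST = ["Perc10", "WavEnHH_s-2", "RZD5GLevNonU"] + [
    e.parameter for e in UNIVARIATE_TABLE if e.method == "poe_acc"
]

#: Screening significance convention: 0.05 divided by 19 tests (17 unique
#: selected parameters plus age and sex); the study prints the resulting
#: threshold as 0.0023.
STATED_ALPHA = 0.05
STATED_M = 19
STATED_THRESHOLD = 0.0023

#: Combined prediction model: operating point and fit quality as printed.
MODEL_SENSITIVITY_PCT = 93.33
MODEL_SPECIFICITY_PCT = 100.0
MODEL_CRITERION = 0.57
MODEL_AUC = 0.992
MODEL_R2 = 0.7153
MODEL_R2_ADJUSTED = 0.6583
MODEL_MCC = 0.8457
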