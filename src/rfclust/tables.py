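"""Published per-cluster composition of the discovery and validation cohorts.

These constants transcribe the epidemiologic characteristics of the six
risk-factor clusters (CL1..CL6) reported for the Korean discovery cohort
(Ansan/Ansung, n = 10,023) and the pooled cross-sectional validation
cohorts (HEXA + CAVAS + KNHANES, n = 215,083).  They parameterise the
synthetic-cohort generator and provide the printed 2xk diabetic /
non-diabetic contingency tables that the heterogeneity statistics are
checked against.

Clusters are numbered in ascending order of type 2 diabetes prevalence.
Sex is coded male = 0, female = 1.  HTN (hypertension) and FHDM (family
history of diabetes) are 0/1 flags that are constant within each
discovery cluster.
"""

from __future__ import annotations

import numpy as np

# Discovery cohort (Ansan/Ansung), one row per cluster CL1..CL6:
# n, n_male, n_female, age mean, age sd, bmi mean, bmi sd, htn, fhdm,
# n nondiabetic, n diabetic.
DISCOVERY_CLUSTERS = [
    # name  n     M     F     age_m  age_sd bmi_m  bmi_sd htn fhdm ndm   dm
    ("CL1", 1985, 1985, 0,    45.72, 4.13,  24.22, 2.81,  0,  0,   1808, 177),
    ("CL2", 3241, 0,    3241, 51.04, 8.74,  24.35, 3.15,  0,  0,   2937, 304),
    ("CL3", 862,  374,  488,  47.89, 6.90,  24.61, 2.95,  0,  1,   690,  172),
    ("CL4", 1013, 1013, 0,    61.87, 4.23,  23.11, 2.90,  0,  0,   807,  206),
    ("CL5", 2645, 1258, 1387, 56.41, 8.57,  25.50, 3.21,  1,  0,   2050, 595),
    ("CL6", 277,  122,  155,  53.27, 8.45,  26.20, 3.06,  1,  1,   156,  121),
]

# Pooled cross-sectional validation cohorts, same layout.  HTN/FHDM flags
# are the dominant category (cluster 5 contains a handful of discordant
# participants in the published table).
VALIDATION_CLUSTERS = [
    ("CL1", 24768, 24768, 0,     46.84, 4.66, 24.09, 2.88, 0, 0, 23761, 1007),
    ("CL2", 83436, 0,     83436, 51.90, 7.91, 23.40, 2.85, 0, 0, 80783, 2653),
    ("CL3", 27465, 8099,  19366, 50.55, 7.72, 23.73, 2.88, 0, 1, 24390, 3075),
    ("CL4", 19271, 19271, 0,     61.70, 4.41, 23.60, 2.62, 0, 0, 17374, 1897),
    ("CL5", 50155, 21231, 28924, 57.33, 7.80, 25.09, 3.06, 1, 0, 41636, 8519),
    ("CL6", 9988,  3784,  6204,  55.50, 7.95, 25.29, 3.03, 1, 1, 6823,  3165),
]


def contingency_counts(which: str = "discovery") -> np.ndarray:
    """Return the published 2 x 6 (nondiabetic, diabetic) x cluster counts.

    Parameters
    ----------
    which : {"discovery", "validation"}

    Returns
    -------
    ndarray of shape (2, 6); row 0 nondiabetic, row 1 diabetic.
    """
    rows = {"discovery": DISCOVERY_CLUSTERS, "validation": VALIDATION_CLUSTERS}[which]
    return np.array([[r[10] for r in rows], [r[11] for r in rows]])
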