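"""Bundled baseline dataset: six healthy adult male Sprague-Dawley rats.

Published group-level measurements from a four-week longitudinal
characterisation (body weight, plasma ICG concentrations at 1/5/10 min
post-injection, Doppler hemodynamics, and selected serum biochemistry with
literature reference intervals).  These serve as validation fixtures and
demo inputs; loaders return tidy pandas frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RAT_IDS = ["rat1", "rat2", "rat3", "rat4", "rat5", "rat6"]

#: Weekly body weight (g), weeks 1-4 (ages 12-16 weeks).
WEIGHTS_G = {
    "rat1": [390.70, 390.30, 406.70, 418.20],
    "rat2": [369.00, 367.30, 376.00, 385.30],
    "rat3": [367.40, 372.20, 392.00, 408.50],
    "rat4": [328.10, 340.00, 353.90, 372.00],
    "rat5": [355.20, 350.50, 370.20, 383.20],
    "rat6": [413.70, 427.20, 435.90, 454.40],
}

#: Plasma ICG concentration mean (μg/mL) at minutes 1, 5, 10.
ICG_TIMES_MIN = [1.0, 5.0, 10.0]
ICG_UGML = {
    "rat1": [128.10, 19.45, 5.41],
    "rat2": [161.47, 28.58, 5.75],
    "rat3": [160.63, 33.14, 7.44],
    "rat4": [189.16, 38.13, 3.47],
    "rat5": [165.91, 47.51, 2.90],
    "rat6": [130.65, 19.24, 6.91],
}
#: Replicate SDs accompanying the means above.
ICG_UGML_SD = {
    "rat1": [55.618, 2.28, 3.32],
    "rat2": [65.82, 9.23, 3.60],
    "rat3": [27.68, 6.95, 0.52],
    "rat4": [51.05, 2.86, 0.05],
    "rat5": [23.91, 8.82, 0.76],
    "rat6": [10.21, 3.54, 0.99],
}

#: Doppler / hemodynamic per-rat values.  Keys are measurement codes:
#: portal_area mm^2; portal_psv, ha_psv, ha_edv mm/s; ha_vti, renal_vti mm;
#: ha_ri, pci, ap dimensionless (pci in mm^2 per mm/s); hr bpm;
#: co mL/min; lrad mm (left renal artery diameter); rbf mL/min.
HEMODYNAMICS = {
    "portal_area": [3.09, 3.60, 3.53, 2.67, 3.12, 4.48],
    "portal_psv": [131.25, 161.00, 148.60, 176.20, 130.55, 156.75],
    "ha_psv": [864.37, 687.47, 643.69, 627.48, 581.00, 755.47],
    "ha_edv": [424.33, 266.29, 309.93, 262.63, 232.95, 304.78],
    "ha_vti": [110.03, 82.37, 79.06, 73.06, 60.09, 84.23],
    "ha_ri": [0.52, 0.59, 0.51, 0.57, 0.62, 0.61],
    "pci": [0.02, 0.02, 0.02, 0.02, 0.03, 0.03],
    "ap": [6.64, 4.39, 4.44, 3.84, 4.64, 4.98],
    "hr": [331.50, 303.13, 321.08, 316.71, 362.13, 351.50],
    "co": [79.64, 67.09, 74.03, 67.91, 74.12, 90.71],
    "lrad": [0.91, 0.90, 0.81, 0.85, 0.92, 0.90],
    "renal_vti": [64.37, 71.04, 67.21, 68.91, 63.59, 72.01],
    "rbf": [14.07, 13.27, 11.01, 12.07, 15.18, 16.28],
}

#: Published group means shown alongside the per-rat values, for regression
#: against recomputation (mean over the six rats, 2 dp).
HEMODYNAMICS_GROUP_MEAN = {
    "portal_area": 3.41,
    "portal_psv": 150.72,
    "ha_psv": 693.24,
    "ha_edv": 300.15,
    "ha_vti": 81.47,
    "ha_ri": 0.57,
    "pci": 0.023,
    "ap": 4.82,
    "hr": 331.01,
    "co": 75.58,
    "lrad": 0.88,
    "renal_vti": 67.86,
    "rbf": 13.65,
}

#: Serum biochemistry weekly group means (μ ± SD over n = 6), weeks 1-4,
#: plus one published reference interval per analyte where available.
BIOCHEMISTRY_WEEKLY_MEAN = {
    "total_protein": [4.58, 4.93, 4.84, 4.59],
    "albumin": [1.88, 1.02, 2.32, 2.11],
    "ast": [62.68, 51.70, 54.92, 44.50],
    "alt": [36.62, 34.25, 37.77, 31.42],
    "bilirubin": [1.74, 0.99, 1.18, 1.31],
    "prothrombin_time": [41.57, 74.30, 18.83, 17.73],
}

#: Published comparison intervals (lower, upper), same units as above.
PUBLISHED_INTERVALS = {
    "total_protein": (5.68, 9.25),
    "albumin": (2.83, 4.05),
    "ast": (64.1, 168.1),
    "alt": (30.8, 73.4),
    "bilirubin": (0.0, 0.3),
    "prothrombin_time": (8.1, 18.3),
}


def load_weights() -> pd.DataFrame:
    """Long-format weights: subject, week (1-4), weight_g."""
    rows = [
        {"subject": rat, "week": wk + 1, "weight_g": w}
        for rat in RAT_IDS
        for wk, w in enumerate(WEIGHTS_G[rat])
    ]
    return pd.DataFrame(rows)


def load_icg() -> pd.DataFrame:
    """Long-format ICG series: subject, time_min, concentration_ugml, replicate_sd."""
    rows = [
        {
            "subject": rat,
            "time_min": t,
            "concentration_ugml": c,
            "replicate_sd": s,
        }
        for rat in RAT_IDS
        for t, c, s in zip(ICG_TIMES_MIN, ICG_UGML[rat], ICG_UGML_SD[rat])
    ]
    return pd.DataFrame(rows)


def load_hemodynamics() -> pd.DataFrame:
    """Wide per-subject hemodynamics, one row per rat."""
    df = pd.DataFrame(HEMODYNAMICS, index=RAT_IDS)
    df.index.name = "subject"
    return df.reset_index()


def load_biochemistry() -> pd.DataFrame:
    """Long-format weekly biochemistry group means: analyte, week, value."""
    rows = [
        {"subject": "group_mean", "analyte": analyte, "week": wk + 1, "value": v}
        for analyte, values in BIOCHEMISTRY_WEEKLY_MEAN.items()
        for wk, v in enumerate(values)
    ]
    return pd.DataFrame(rows)


def icg_group_average_series() -> tuple[np.ndarray, np.ndarray]:
    """(times, group-mean concentrations) averaged over the six rats."""
    t = np.asarray(ICG_TIMES_MIN)
    conc = np.mean([ICG_UGML[r] for r in RAT_IDS], axis=0)
    return t, conc
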