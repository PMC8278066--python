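"""Reference validation datasets for the FLP/AZH qNMR assay.

These are the replicate measurements from the assay's original bench
validation: percent recoveries of fluticasone propionate (FLP) and
azelastine hydrochloride (AZH) in pure form by the qNMR method and by the
independent HPLC comparison method, the intra-/inter-day precision
replicates, the sample-stability time series, and the laboratory-mixture
and nasal-spray application results. Each qNMR recovery is itself the mean
of three determinations.

They serve two purposes: as worked inputs for the statistics layer (the
analysis drivers recompute every summary statistic from them) and as frozen
fixtures for the test suite. The published calibration parameters for both
drugs are included for use as worked calibration models.

Where a tabulated amount-found value disagrees with its percent recovery at
the printed precision, the recovery is treated as authoritative.
"""

from __future__ import annotations

__all__ = [
    "FLP_PURE_RECOVERIES_QNMR",
    "FLP_PURE_RECOVERIES_HPLC",
    "AZH_PURE_RECOVERIES_QNMR",
    "AZH_PURE_RECOVERIES_HPLC",
    "PURE_FORM_TAKEN_FOUND",
    "PRECISION_INTRA_DAY",
    "PRECISION_INTER_DAY",
    "STABILITY_SERIES",
    "LAB_MIXTURE",
    "NASAL_SPRAY",
    "PUBLISHED_CALIBRATION",
]

# --- accuracy study, pure form: (taken mg/ml, found mg/ml, % recovery) ---

PURE_FORM_TAKEN_FOUND = {
    "FLP": [
        (0.25, 0.25, 98.80),
        (0.30, 0.30, 100.33),
        (0.80, 0.82, 102.00),
        (1.00, 1.00, 100.10),
        (5.00, 4.98, 99.52),
        (10.00, 10.04, 100.36),
        (15.00, 14.98, 99.84),
        (20.00, 20.04, 100.18),
    ],
    "AZH": [
        (0.20, 0.20, 98.50),
        (0.30, 0.29, 98.00),
        (0.80, 0.81, 101.38),
        (1.00, 1.00, 99.60),
        (5.00, 4.99, 99.78),
        (8.00, 8.01, 100.18),
        (10.00, 10.00, 99.96),
        (15.00, 14.99, 99.95),
    ],
}

FLP_PURE_RECOVERIES_QNMR = [r for _, _, r in PURE_FORM_TAKEN_FOUND["FLP"]]
AZH_PURE_RECOVERIES_QNMR = [r for _, _, r in PURE_FORM_TAKEN_FOUND["AZH"]]

# HPLC comparison method, same study (four concentration levels)
FLP_PURE_RECOVERIES_HPLC = [100.19, 99.26, 101.71, 99.65]
AZH_PURE_RECOVERIES_HPLC = [98.84, 99.13, 101.04, 99.43]

# --- precision: % found replicates per concentration (mg/ml) ---

PRECISION_INTRA_DAY = {
    "FLP": {
        1.0: [101.27, 100.06, 101.22],
        5.0: [100.12, 99.52, 100.00],
        10.0: [101.57, 100.36, 100.96],
    },
    "AZH": {
        1.0: [99.64, 100.36, 100.72],
        5.0: [100.29, 99.78, 99.28],
        10.0: [98.53, 99.96, 99.25],
    },
}

PRECISION_INTER_DAY = {
    "FLP": {
        1.0: [101.08, 100.06, 99.46],
        5.0: [100.48, 99.52, 99.76],
        10.0: [100.96, 100.36, 99.16],
    },
    "AZH": {
        1.0: [98.57, 100.36, 99.64],
        5.0: [100.29, 99.78, 98.04],
        10.0: [98.53, 99.96, 100.39],
    },
}

# --- stability: (time h, percent assay) at ambient temperature ---

STABILITY_SERIES = {
    "FLP": [(0, 100.36), (6, 100.42), (12, 100.30), (24, 100.06)],
    "AZH": [(0, 99.96), (6, 99.86), (12, 99.57), (24, 99.93)],
}

# --- laboratory-prepared 1:2.74 mixture: (taken, found, % recovery qNMR) ---

LAB_MIXTURE = {
    "FLP": {
        "qnmr": [(0.37, 0.37, 100.84), (1.83, 1.80, 98.70), (2.92, 2.90, 99.23)],
        "hplc_recoveries": [99.99, 102.37, 101.62],
    },
    "AZH": {
        "qnmr": [(1.00, 1.00, 100.36), (5.00, 4.99, 99.78), (8.00, 7.95, 99.37)],
        "hplc_recoveries": [99.89, 100.33, 101.43],
    },
}

# --- nasal-spray suspension assay (taken, found, % recovery qNMR) ---

NASAL_SPRAY = {
    "FLP": {
        "qnmr": [(0.40, 0.39, 98.64), (0.60, 0.60, 100.63), (0.80, 0.79, 98.34)],
        "hplc_recoveries": [99.16, 98.82, 100.89],
    },
    "AZH": {
        "qnmr": [
            (1.096, 1.11, 100.98),
            (1.644, 1.63, 98.98),
            (2.192, 2.18, 99.42),
        ],
        "hplc_recoveries": [99.96, 100.13, 101.75],
    },
}

# --- published calibration parameters (ratio = intercept + slope * C) ---

PUBLISHED_CALIBRATION = {
    "FLP": {
        "slope": 0.02,
        "intercept": 64e-4,
        "r": 0.9999,
        "sy_x": 43e-5,
        "sa": 21e-5,
        "sb": 2e-5,
        "range_mg_ml": (0.25, 20.0),
    },
    "AZH": {
        "slope": 0.03,
        "intercept": 1e-4,
        "r": 0.9999,
        "sy_x": 27e-5,
        "sa": 13e-5,
        "sb": 2e-5,
        "range_mg_ml": (0.20, 15.0),
    },
}
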