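"""Reference values shipped with the package.

These are the figures established during development, validation and
inter-laboratory evaluation of the HILIC-fluorescence method for apple
procyanidins: relative response factors (RRFs) for dp2-10 versus
epicatechin, the per-analyte LOQ ladder, method precision, spike
recoveries, the extract stability time series, and the per-laboratory
results of the seven-lab comparison.  They serve as default fixtures for
the quantification pipeline and as ground truth for the synthetic-data
generator.
"""

from __future__ import annotations

import pandas as pd

# ---------------------------------------------------------------------------
# Relative response factors (slope_dp / slope_epicatechin), mean of the
# three daily determinations ("mean of means"), in-house method.
# ---------------------------------------------------------------------------

#: default RRF truth/fixture: in-house determination (lab 2 of the
#: two-location reproducibility study)
RRF_MEAN_OF_MEANS: dict[str, float] = {
    "dp2": 0.587,
    "dp3": 0.442,
    "dp4": 0.265,
    "dp5": 0.238,
    "dp6": 0.172,
    "dp7": 0.148,
    "dp8": 0.113,
    "dp9": 0.080,
    "dp10": 0.062,
}

#: between-day RSD (%) of the daily RRFs (epicatechin row is the RSD of its
#: own daily response factors)
RRF_RSD_PERCENT: dict[str, float] = {
    "epicatechin": 4.0,
    "dp2": 4.0,
    "dp3": 5.0,
    "dp4": 12.0,
    "dp5": 10.0,
    "dp6": 9.0,
    "dp7": 9.0,
    "dp8": 19.0,
    "dp9": 34.0,
    "dp10": 4.0,
}

#: alternate RRF fixture: independent determination at the second test
#: location (different analyst and instrument)
RRF_LAB1: dict[str, float] = {
    "dp2": 0.489,
    "dp3": 0.347,
    "dp4": 0.295,
    "dp5": 0.244,
    "dp6": 0.177,
    "dp7": 0.154,
    "dp8": 0.103,
    "dp9": 0.058,
    "dp10": 0.038,
}

# ---------------------------------------------------------------------------
# Reported LOQs: theoretical LOQ from 10σ/S was 0.5 μg/mL, but the reported
# LOQ is clamped to the lowest calibration level used for each analyte's RRF.
# ---------------------------------------------------------------------------

THEORETICAL_LOQ_UG_PER_ML = 0.5

LOQ_UG_PER_ML: dict[str, float] = {
    "epicatechin": 5.0,
    "dp2": 5.0,
    "dp3": 5.0,
    "dp4": 5.0,
    "dp5": 5.0,
    "dp6": 10.0,
    "dp7": 25.0,
    "dp8": 25.0,
    "dp9": 25.0,
    "dp10": 50.0,
}

# ---------------------------------------------------------------------------
# Method precision (%RSD): repeatability (intra-day) and intermediate
# precision (inter-day), from one-way ANOVA of 3 replicates × 3 days.
# ---------------------------------------------------------------------------

PRECISION_RSD_PERCENT: dict[str, tuple[float, float]] = {
    # analyte: (repeatability, intermediate)
    "epicatechin": (4.0, 2.0),
    "dp2": (6.0, 2.0),
    "dp3": (6.0, 3.0),
    "dp4": (5.0, 2.0),
    "dp5": (3.0, 4.0),
    "dp6": (2.0, 7.0),
    "dp7": (2.0, 8.0),
    "dp8": (3.0, 10.0),
    "dp9": (4.0, 13.0),
    "dp10": (5.0, 13.0),
}

# ---------------------------------------------------------------------------
# Spike-recovery study: mean recovery (%) over the 100% / 200% fortification
# levels and the SD of the individual recoveries (u_rec).
# ---------------------------------------------------------------------------

RECOVERY_PERCENT: dict[str, tuple[float, float]] = {
    "epicatechin": (96.0, 7.0),
    "dp2": (95.0, 8.0),
    "dp3": (97.0, 6.0),
    "dp4": (83.0, 7.0),
    "dp5": (77.0, 7.0),
    "dp6": (69.0, 11.0),
    "dp7": (70.0, 9.0),
    "dp8": (60.0, 11.0),
    "dp9": (63.0, 15.0),
    "dp10": (49.0, 34.0),
}

# ---------------------------------------------------------------------------
# Extract stability study: analyte content (mg/g) at 0/48/96/168 h plus the
# intermediate-precision fraction used for the acceptance half-width.
# ---------------------------------------------------------------------------

STABILITY_TIMEPOINTS_H = (0.0, 48.0, 96.0, 168.0)

#: analyte -> (values at the four timepoints (mg/g), ip fraction)
STABILITY_SERIES: dict[str, tuple[tuple[float, float, float, float], float]] = {
    "epicatechin": ((12.9, 12.4, 12.4, 12.4), 0.04),
    "dp2": ((40.6, 39.9, 40.7, 40.8), 0.06),
    "dp3": ((45.1, 45.4, 45.9, 45.7), 0.06),
    "dp4": ((82.0, 78.6, 81.4, 79.6), 0.05),
    "dp5": ((77.1, 72.7, 71.8, 74.0), 0.03),
    "dp6": ((93.5, 91.0, 91.1, 91.6), 0.02),
    "dp7": ((78.6, 81.9, 77.7, 73.3), 0.02),
    "dp8": ((71.5, 69.7, 66.7, 67.9), 0.03),
    "dp9": ((61.6, 61.5, 64.7, 64.4), 0.04),
    "dp10": ((54.9, 52.2, 52.5, 53.2), 0.05),
}

# ---------------------------------------------------------------------------
# Inter-laboratory evaluation: per-lab mean content (mg/g) and within-lab
# %RSD for the two apple extracts and the defatted-chocolate control, seven
# retained laboratories.
# ---------------------------------------------------------------------------


def interlab_results() -> pd.DataFrame:
    """Per-laboratory results of the seven-lab evaluation (long format).

    Columns: lab, material, analyte_class, mean_mg_per_g, rsd_percent.
    """
    rows = []
    data = {
        # lab: (A mono, A olig, B mono, B olig, ctrl mono, ctrl olig) as
        #      (mean, rsd) pairs
        1: [(337.3, 3.4), (324.5, 2.5), (14.3, 2.7), (495.5, 2.0), (2.9, 2.7), (8.0, 2.6)],
        2: [(344.2, 0.9), (381.6, 2.4), (12.5, 3.0), (601.7, 1.0), (2.8, 0.9), (10.7, 10.0)],
        3: [(323.8, 2.1), (317.9, 1.8), (12.3, 4.9), (445.7, 6.3), (2.7, 9.0), (7.4, 5.6)],
        4: [(332.0, 13.9), (296.6, 12.2), (13.1, 14.8), (439.5, 9.7), (3.1, 1.4), (4.7, 17.6)],
        5: [(323.2, 2.3), (233.4, 2.7), (12.5, 3.0), (187.9, 4.8), (3.0, 0.7), (5.7, 6.9)],
        6: [(306.2, 0.1), (275.4, 0.1), (12.6, 0.3), (373.0, 2.2), (3.0, 0.6), (7.5, 1.3)],
        7: [(312.0, 0.8), (277.1, 0.7), (11.4, 1.6), (408.8, 5.4), (2.6, 1.9), (4.5, 12.1)],
    }
    cells = [
        ("extract_A", "monomers"),
        ("extract_A", "oligomers"),
        ("extract_B", "monomers"),
        ("extract_B", "oligomers"),
        ("control", "monomers"),
        ("control", "oligomers"),
    ]
    for lab, vals in data.items():
        for (material, cls), (mean, rsd) in zip(cells, vals):
            rows.append(
                {
                    "lab": lab,
                    "material": material,
                    "analyte_class": cls,
                    "mean_mg_per_g": mean,
                    "rsd_percent": rsd,
                }
            )
    return pd.DataFrame(rows)
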