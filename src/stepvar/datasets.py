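"""Published worked-example tables for a 30-subject, six-month
activity-tracker study in a prediabetes cohort.

The raw subject-level data behind these tables were never deposited, but
the printed summary statistics are sufficient inputs for reconstructing
every standardised response mean and every paired-t p-value from the change
columns, and the monthly step decline from the tracker table.  They serve
as fixtures for the summary-statistic operations in
:mod:`stepvar.stats` and as the scale reference for the synthetic-cohort
defaults.

``test`` is ``"t"`` for rows compared with a paired t-test (change column
printed as mean ± SD) and ``"w"`` for Wilcoxon rows (median [Q1–Q3];
change mean/SD unavailable, stored as NaN).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Number of subjects behind every printed summary.
N_SUBJECTS = 30

_BODY_COMPOSITION_ROWS = [
    # outcome, unit, test, baseline_mean, baseline_sd, delta_mean, delta_sd, p_printed, srm_printed
    ("weight", "kg", "t", 87.6, 16.9, -1.46, 3.31, 0.022, -0.4411),
    ("mbf", "kg", "t", 32.0, 9.72, -1.8, 2.36, np.nan, -0.7627),
    ("pbf", "%", "t", 36.1, 6.86, -1.43, 1.59, np.nan, -0.8994),
    ("vfl", "units", "w", np.nan, np.nan, np.nan, np.nan, np.nan, -0.8337),
    ("vfa", "cm^2", "t", 169.0, 79.1, -21.9, 23.9, np.nan, -0.9163),
    ("whr", "", "t", 0.948, 0.0912, -0.022, 0.0282, np.nan, -0.7801),
    ("ac", "cm", "t", 98.1, 13.0, -2.16, 2.84, np.nan, -0.7606),
    ("mbf_lt_arm", "kg", "t", 1.93, 0.612, -0.0777, 0.149, 0.008, -0.5215),
    ("mbf_rt_arm", "kg", "t", 1.91, 0.625, -0.088, 0.159, 0.005, -0.5535),
    ("mbf_lt_leg", "kg", "t", 5.84, 1.75, -0.345, 0.442, np.nan, -0.7805),
    ("mbf_rt_leg", "kg", "t", 5.83, 1.76, -0.362, 0.444, np.nan, -0.8153),
    ("mbf_trunk", "kg", "t", 16.5, 4.98, -0.924, 1.2, np.nan, -0.7700),
]

_BLOOD_TEST_ROWS = [
    ("hba1c_pct", "%", "t", 5.61, 0.352, 0.0467, 0.2788, 0.367, 0.1675),
    ("hba1c_mmol_mol", "mmol/mol", "t", 37.7, 3.74, 0.5333, 2.9564, 0.331, 0.1804),
    ("tc", "mmol/L", "t", 5.70, 1.14, 0.199, 1.1188, 0.338, 0.1779),
    ("tg", "mmol/L", "w", np.nan, np.nan, np.nan, np.nan, 0.271, -0.1844),
    ("hdl", "mmol/L", "w", np.nan, np.nan, np.nan, np.nan, 0.593, 0.1643),
    ("ldl", "mmol/L", "t", 3.44, 1.04, 0.228, 1.0574, 0.247, 0.2156),
]

_COLUMNS = [
    "outcome",
    "unit",
    "test",
    "baseline_mean",
    "baseline_sd",
    "delta_mean",
    "delta_sd",
    "p_printed",
    "srm_printed",
]


def body_composition_table() -> pd.DataFrame:
    """Printed body-mass-composition summaries (n = 30, baseline and change)."""
    return pd.DataFrame(_BODY_COMPOSITION_ROWS, columns=_COLUMNS)


def blood_tests_table() -> pd.DataFrame:
    """Printed blood-test summaries (n = 30, baseline and change)."""
    return pd.DataFrame(_BLOOD_TEST_ROWS, columns=_COLUMNS)


_MONTHLY_ROWS = [
    # metric, month_index, mean, sd, cv
    ("steps", 1, 9908, 3625, 0.43),
    ("steps", 2, 9816, 3834, 0.41),
    ("steps", 3, 8881, 3969, 0.46),
    ("steps", 4, 8217, 4117, 0.53),
    ("steps", 5, 7971, 3597, 0.52),
    ("steps", 6, 8038, 3897, 0.54),
    ("minutes_sedentary", 1, 804, 274, 0.24),
    ("minutes_sedentary", 2, 805, 287, 0.19),
    ("minutes_sedentary", 3, 816, 275, 0.18),
    ("minutes_sedentary", 4, 898, 322, 0.18),
    ("minutes_sedentary", 5, 927, 290, 0.17),
    ("minutes_sedentary", 6, 871, 266, 0.25),
    ("minutes_lightly_active", 1, 281, 117, 0.40),
    ("minutes_lightly_active", 2, 270, 116, 0.29),
    ("minutes_lightly_active", 3, 263, 121, 0.36),
    ("minutes_lightly_active", 4, 216, 132, 0.54),
    ("minutes_lightly_active", 5, 211, 105, 0.55),
    ("minutes_lightly_active", 6, 233, 99, 0.45),
    ("minutes_fairly_active", 1, 17, 15, 1.05),
    ("minutes_fairly_active", 2, 16, 14, 1.17),
    ("minutes_fairly_active", 3, 14, 11, 1.06),
    ("minutes_fairly_active", 4, 10, 10, 1.25),
    ("minutes_fairly_active", 5, 11, 10, 1.49),
    ("minutes_fairly_active", 6, 14, 13, 1.34),
    ("minutes_very_active", 1, 8, 8, 1.28),
    ("minutes_very_active", 2, 10, 10, 1.33),
    ("minutes_very_active", 3, 9, 10, 1.25),
    ("minutes_very_active", 4, 10, 15, 1.43),
    ("minutes_very_active", 5, 9, 13, 1.74),
    ("minutes_very_active", 6, 11, 14, 1.52),
]


def tracker_monthly_table() -> pd.DataFrame:
    """Printed monthly tracker summaries (pooled mean, SD, CV per metric)."""
    return pd.DataFrame(_MONTHLY_ROWS, columns=["metric", "month_index", "mean", "sd", "cv"])
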