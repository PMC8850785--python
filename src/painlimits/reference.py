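"""Bundled reference values for the pain-threshold limit model.

This module carries the published summary tables of a 112-subject
pain-onset study for collaborative-robot safety: the fitted parameters of
the expanded log-logistic threshold distribution per body location and
test condition, the significance of the gender covariate, observed sample
sizes, the assignment of subject groups to conditions, and the printed
90th-percentile columns of two earlier algometry studies used for
cross-study comparison.

These tables play two roles in the package:

* default ground truth for the synthetic-data generator, and
* direct inputs for reproducing the published limit tables and
  comparison statistics without access to the raw (non-public) data.

Conventions
-----------
Conditions are keyed by ``(row, load_type, contact_type)`` where
``load_type`` is ``"pinching"`` or ``"impact"`` and ``contact_type`` is
``"semi-sharp"`` or ``"blunt"``.  Semi-sharp limits are peak pressures in
N/cm^2, blunt limits are maximum contact forces in N.  Bilateral hand
locations share one fitted row (e.g. ``"17/18"``).
"""

from __future__ import annotations

from typing import NamedTuple

LOAD_TYPES = ("pinching", "impact")
CONTACT_TYPES = ("semi-sharp", "blunt")

#: the four experimental conditions in canonical order
CONDITIONS = (
    ("pinching", "semi-sharp"),
    ("pinching", "blunt"),
    ("impact", "semi-sharp"),
    ("impact", "blunt"),
)

LOCATION_NAMES = {
    1: "Forehead",
    2: "Temple",
    3: "Masticatory muscle",
    4: "Neck muscle",
    5: "7th cervical vertebra (C7)",
    6: "Shoulder joint",
    7: "5th lumbar vertebra (L5)",
    8: "Sternum",
    9: "Pectoral muscle",
    10: "Abdominal muscle",
    11: "Pelvic bone",
    12: "Deltoid muscle",
    13: "Humerus",
    14: "Radial bone",
    15: "Forearm muscle",
    16: "Arm nerve",
    17: "Forefinger pad (dominant)",
    18: "Forefinger pad (non-dominant)",
    19: "Forefinger DIP joint (dominant)",
    20: "Forefinger DIP joint (non-dominant)",
    21: "Thenar eminence",
    22: "Palm (dominant)",
    23: "Palm (non-dominant)",
    24: "Back of the hand (dominant)",
    25: "Back of the hand (non-dominant)",
    26: "Thigh muscle",
    27: "Kneecap",
    28: "Middle of shin",
    29: "Calf muscle",
}

#: the neck muscle was excluded from all load tests on medical advice;
#: its limits are estimated from the temple (see limits.round_for_standard)
EXCLUDED_LOCATION = 4

#: head locations use the reduced pendulum velocity step of 0.01 m/s
HEAD_LOCATIONS = frozenset({1, 2, 3, 4, 5})

#: the pectoral muscle was not tested on female subjects
MALE_ONLY_LOCATIONS = frozenset({9})

#: fitted rows; bilateral locations are pooled into a single row
MEASURED_ROWS = (
    "1", "2", "3", "5", "6", "7", "8", "9", "10", "11", "12", "13",
    "14", "15", "16", "17/18", "19/20", "21", "22/23", "24/25",
    "26", "27", "28", "29",
)

ROW_OF_LOCATION = {
    1: "1", 2: "2", 3: "3", 5: "5", 6: "6", 7: "7", 8: "8", 9: "9",
    10: "10", 11: "11", 12: "12", 13: "13", 14: "14", 15: "15", 16: "16",
    17: "17/18", 18: "17/18", 19: "19/20", 20: "19/20", 21: "21",
    22: "22/23", 23: "22/23", 24: "24/25", 25: "24/25",
    26: "26", 27: "27", 28: "28", 29: "29",
}


class ThresholdParams(NamedTuple):
    """Parameters of the expanded log-logistic threshold CDF.

    ``F(y, x_G) = [1 + exp(-(log y - beta0 - x_G*beta1)/alpha)]^-1``
    with intercept ``beta0`` (log N or log N/cm^2), gender effect
    ``beta1`` (x_G = male fraction) and shape ``alpha``.
    """

    beta0: float
    beta1: float
    alpha: float


def _params(table: dict) -> dict:
    out = {}
    for row, values in table.items():
        for (load, contact), triple in zip(CONDITIONS, values):
            out[(row, load, contact)] = ThresholdParams(*triple)
    return out


# Fitted (beta0, beta1, alpha) per row, in CONDITIONS order:
# pinching/semi-sharp, pinching/blunt, impact/semi-sharp, impact/blunt.
# A beta1 of exactly 0 was fixed (gender not relevant at that location);
# 0.0 entries at gender-relevant rows are estimates that round to zero.
THRESHOLD_PARAMS = _params({
    "1":     [(4.22, 0.00, 0.46), (4.10, 0.00, 0.53), (4.83, 0.00, 0.32), (4.50, 0.00, 0.42)],
    "2":     [(3.59, 0.00, 0.37), (3.50, 0.00, 0.56), (3.96, 0.00, 0.32), (4.12, 0.00, 0.35)],
    "3":     [(3.26, 0.00, 0.30), (3.16, 0.00, 0.49), (3.67, 0.00, 0.26), (3.90, 0.00, 0.29)],
    "5":     [(4.02, 0.00, 0.25), (3.44, 0.00, 0.43), (4.80, 0.00, 0.33), (4.01, 0.00, 0.27)],
    "6":     [(3.54, 0.38, 0.35), (3.81, 0.22, 0.21), (4.29, 0.24, 0.18), (4.21, 0.30, 0.23)],
    "7":     [(3.65, 0.00, 0.47), (4.31, 0.00, 0.36), (5.01, 0.00, 0.24), (4.90, 0.00, 0.29)],
    "8":     [(3.26, 0.63, 0.34), (3.61, 0.64, 0.30), (3.72, 0.63, 0.21), (4.02, 0.55, 0.29)],
    "9":     [(3.67, 0.00, 0.27), (3.74, 0.09, 0.25), (4.07, 0.00, 0.22), (4.42, 0.00, 0.29)],
    "10":    [(2.89, 0.84, 0.24), (3.21, 0.55, 0.34), (3.59, 0.32, 0.24), (3.71, 0.54, 0.27)],
    "11":    [(3.81, 1.15, 0.53), (3.96, 0.36, 0.30), (5.16, 0.18, 0.32), (4.44, 0.51, 0.21)],
    "12":    [(3.57, 0.63, 0.35), (3.96, 0.40, 0.32), (4.24, 0.37, 0.15), (4.19, 0.52, 0.23)],
    "13":    [(3.25, 0.57, 0.27), (3.72, 0.36, 0.25), (4.35, 0.45, 0.25), (4.56, 0.38, 0.19)],
    "14":    [(3.56, 0.60, 0.37), (4.05, 0.39, 0.24), (4.71, 0.28, 0.21), (4.74, 0.37, 0.22)],
    "15":    [(3.11, 0.90, 0.36), (4.14, 0.25, 0.26), (4.54, 0.28, 0.18), (4.77, 0.22, 0.20)],
    "16":    [(3.62, 0.00, 0.41), (4.05, 0.00, 0.29), (4.65, 0.00, 0.18), (4.74, 0.00, 0.22)],
    "17/18": [(3.90, 0.00, 0.42), (4.61, 0.00, 0.37), (5.20, 0.00, 0.25), (5.60, 0.00, 0.33)],
    "19/20": [(4.62, 0.00, 0.32), (4.67, 0.00, 0.35), (6.00, 0.00, 0.19), (5.62, 0.00, 0.28)],
    "21":    [(3.74, 0.00, 0.32), (4.45, 0.00, 0.32), (4.91, 0.00, 0.26), (5.28, 0.00, 0.27)],
    "22/23": [(3.47, 0.71, 0.24), (4.30, 0.47, 0.34), (5.20, 0.28, 0.25), (5.36, 0.27, 0.26)],
    "24/25": [(4.82, 0.00, 0.29), (4.67, 0.00, 0.28), (5.86, 0.00, 0.31), (5.25, 0.00, 0.26)],
    "26":    [(3.65, 0.63, 0.32), (4.39, 0.38, 0.29), (4.69, 0.27, 0.21), (4.76, 0.49, 0.24)],
    "27":    [(3.82, 0.96, 0.37), (4.55, 0.25, 0.32), (4.91, 0.67, 0.21), (5.00, 0.46, 0.29)],
    "28":    [(3.85, 1.17, 0.40), (4.64, 0.15, 0.24), (5.36, 0.51, 0.24), (5.08, 0.35, 0.27)],
    "29":    [(3.60, 0.56, 0.38), (4.29, 0.44, 0.28), (4.68, 0.42, 0.23), (5.02, 0.44, 0.24)],
})

#: rows where the gender effect is applied when building limit tables
GENDER_RELEVANT_ROWS = frozenset({
    "6", "8", "9", "10", "11", "12", "13", "14", "15",
    "22/23", "26", "27", "28", "29",
})


def _per_condition(table: dict) -> dict:
    out = {}
    for row, values in table.items():
        for (load, contact), v in zip(CONDITIONS, values):
            out[(row, load, contact)] = v
    return out


# Wald p-values for the gender covariate, per row in CONDITIONS order.
# Published "<0.001" entries are stored as 0.0005.
_LT = 0.0005
GENDER_P_VALUES = _per_condition({
    "1":     [0.098, 0.455, 0.098, 0.214],
    "2":     [0.450, 0.302, 0.282, 0.436],
    "3":     [0.228, 0.406, 0.262, 0.476],
    "5":     [0.122, 0.237, 0.007, 0.050],
    "6":     [0.276, 0.083, 0.017, 0.020],
    "7":     [0.218, 0.127, 0.295, 0.003],
    "8":     [0.077, _LT, _LT, 0.019],
    "9":     [_LT, 0.806, _LT, _LT],
    "10":    [_LT, 0.005, 0.083, 0.010],
    "11":    [0.033, 0.044, 0.342, _LT],
    "12":    [0.067, 0.027, _LT, _LT],
    "13":    [0.044, 0.016, _LT, _LT],
    "14":    [0.111, 0.006, 0.017, 0.003],
    "15":    [0.012, 0.104, 0.005, 0.058],
    "16":    [0.414, 0.155, 0.450, 0.403],
    "17/18": [0.113, 0.476, 0.220, 0.347],
    "19/20": [0.168, 0.389, 0.514, 0.192],
    "21":    [0.365, 0.102, 0.956, 0.240],
    "22/23": [0.003, 0.016, 0.040, 0.067],
    "24/25": [0.489, 0.716, 0.095, 0.045],
    "26":    [0.053, 0.032, 0.022, _LT],
    "27":    [0.008, 0.160, _LT, 0.007],
    "28":    [0.004, 0.251, _LT, 0.025],
    "29":    [0.151, 0.009, _LT, 0.002],
})

# Observed sample sizes (subjects with at least one valid repeat),
# per row in CONDITIONS order.
SAMPLE_SIZES = _per_condition({
    "1":     [11, 19, 20, 20],
    "2":     [11, 19, 20, 20],
    "3":     [11, 18, 20, 20],
    "5":     [9, 18, 20, 20],
    "6":     [11, 40, 39, 40],
    "7":     [10, 40, 22, 38],
    "8":     [11, 40, 20, 20],
    "9":     [6, 27, 10, 10],
    "10":    [11, 40, 20, 20],
    "11":    [11, 40, 40, 40],
    "12":    [11, 40, 39, 40],
    "13":    [11, 40, 39, 39],
    "14":    [11, 40, 40, 40],
    "15":    [11, 40, 40, 39],
    "16":    [11, 40, 40, 40],
    "17/18": [11, 41, 40, 40],
    "19/20": [11, 40, 40, 40],
    "21":    [11, 40, 40, 40],
    "22/23": [11, 40, 40, 40],
    "24/25": [11, 40, 40, 40],
    "26":    [11, 39, 40, 40],
    "27":    [11, 39, 39, 39],
    "28":    [11, 40, 40, 40],
    "29":    [11, 40, 40, 40],
})

# Assignment of subject groups to conditions, per row in CONDITIONS order.
GROUP_MAP = _per_condition({
    "1":     ["G5", "G4", "G4", "G4"],
    "2":     ["G5", "G4", "G4", "G4"],
    "3":     ["G5", "G4", "G4", "G4"],
    "5":     ["G5", "G4", "G4", "G4"],
    "6":     ["G5", "G1", "G2/3", "G2/3"],
    "7":     ["G5", "G1", "G2/3", "G2/3"],
    "8":     ["G5", "G1", "G4", "G4"],
    "9":     ["G5", "G1", "G4", "G4"],
    "10":    ["G5", "G1", "G4", "G4"],
    "11":    ["G5", "G1", "G2/3", "G2/3"],
    "12":    ["G5", "G1", "G2/3", "G2/3"],
    "13":    ["G5", "G1", "G2/3", "G2/3"],
    "14":    ["G5", "G1", "G2/3", "G2/3"],
    "15":    ["G5", "G1", "G2/3", "G2/3"],
    "16":    ["G5", "G1", "G2/3", "G2/3"],
    "17/18": ["G5", "G1", "G2", "G2"],
    "19/20": ["G5", "G1", "G2", "G2"],
    "21":    ["G5", "G1", "G2/3", "G2/3"],
    "22/23": ["G5", "G1", "G2", "G2"],
    "24/25": ["G5", "G1", "G2", "G2"],
    "26":    ["G5", "G1", "G2/3", "G2/3"],
    "27":    ["G5", "G1", "G2/3", "G2/3"],
    "28":    ["G5", "G1", "G2/3", "G2/3"],
    "29":    ["G5", "G1", "G2/3", "G2/3"],
})

#: subject-group composition: group -> (n_female, n_male)
GROUP_COMPOSITION = {
    "G1": (13, 28),
    "G2": (6, 14),
    "G3": (10, 10),
    "G2/3": (16, 24),
    "G4": (10, 10),
    "G5": (5, 6),
}


class StudyComparisonRow(NamedTuple):
    """Printed 90th-percentile columns of the cross-study comparison.

    ``s1``/``g5_57`` are pressure P90 values (N/cm^2) for a 57%-male mix
    (reference study 1 vs. this study's control group); ``s2``/``g5_100``
    the same for an all-male mix (reference study 2); ``k`` is the
    Pearson correlation between maximum contact force and peak pressure
    in the control-group trials.  ``None`` marks locations the reference
    study did not test.
    """

    s1: float
    g5_57: float
    s2: float | None
    g5_100: float
    k: float


STUDY_COMPARISON = {
    "1":     StudyComparisonRow(176, 164, 150, 230, 0.95),
    "2":     StudyComparisonRow(172, 81, None, 91, 0.95),
    "3":     StudyComparisonRow(182, 51, None, 60, 0.83),
    "5":     StudyComparisonRow(303, 90, 197, 108, 0.50),
    "6":     StudyComparisonRow(224, 92, 120, 108, 0.94),
    "7":     StudyComparisonRow(268, 104, 134, 134, 0.98),
    "8":     StudyComparisonRow(165, 79, None, 104, 0.96),
    "9":     StudyComparisonRow(266, 70, 110, 70, 0.93),
    "10":    StudyComparisonRow(335, 49, 122, 71, 0.94),
    "11":    StudyComparisonRow(255, 277, None, 454, 0.93),
    "12":    StudyComparisonRow(277, 109, None, 142, 0.97),
    "13":    StudyComparisonRow(295, 64, None, 82, 0.88),
    "14":    StudyComparisonRow(238, 111, None, 144, 0.96),
    "15":    StudyComparisonRow(251, 83, None, 122, 0.91),
    "16":    StudyComparisonRow(289, 93, 92, 107, 0.97),
    "17/18": StudyComparisonRow(402, 117, 236, 153, 0.77),
    "19/20": StudyComparisonRow(332, 213, None, 261, 0.89),
    "21":    StudyComparisonRow(261, 86, 172, 98, 0.93),
    "22/23": StudyComparisonRow(356, 81, 146, 110, 0.96),
    "24/25": StudyComparisonRow(279, 238, 288, 260, 0.62),
    "26":    StudyComparisonRow(404, 110, 121, 144, 0.96),
    "27":    StudyComparisonRow(354, 175, None, 264, 0.97),
    "28":    StudyComparisonRow(294, 222, 188, 367, 0.70),
    "29":    StudyComparisonRow(299, 116, 127, 148, 0.97),
}


def units_for(contact_type: str) -> str:
    """Measurement units per contact-type convention.

    Semi-sharp limits are peak pressures, blunt limits maximum forces.
    """
    if contact_type == "semi-sharp":
        return "N/cm^2"
    if contact_type == "blunt":
        return "N"
    raise ValueError(f"unknown contact type: {contact_type!r}")
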