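"""Reported summary statistics for the Giza 86 x Menoufi cotton cross.

These are the study-level inputs that calibrate the synthetic-data
generator and anchor the reproduction checks: per-generation trait
summaries (mean, standard error, PCV, GCV, broad-sense heritability),
the F3 phenotypic/genotypic correlation structure among the eleven
traits, and the trait means of the two parental varieties under water
deficit stress.  All values are on the scales the trial reports used
(percentages as percentages, trait means in trait units).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .traits import CANONICAL_TRAITS, F2_TRAITS, TRAIT_DIRECTIONS

_SUMMARY_COLUMNS = ("mean", "se", "pcv", "gcv", "h2b")

# trait -> (mean, SE of mean, PCV %, GCV %, h2 broad-sense %)
_F2_SUMMARY = {
    "LY/P": (19.55, 0.43, 44.26, 34.67, 60.84),
    "B/P":  (16.41, 0.33, 41.41, 30.20, 52.74),
    "BW":   (3.17, 0.02, 11.21, 6.72, 38.46),
    "S/B":  (21.03, 0.13, 12.86, 6.43, 30.78),
    "SI":   (9.57, 0.04, 9.21, 5.72, 39.74),
    "LP%":  (37.30, 0.10, 5.36, 2.64, 86.50),
    "LI":   (3.95, 0.02, 10.81, 3.99, 50.00),
}

_F3_SUMMARY = {
    "LY/P": (11.79, 1.55, 31.76, 28.91, 82.85),
    "B/P":  (11.29, 1.34, 29.94, 27.49, 84.31),
    "BW":   (3.14, 0.13, 6.68, 5.32, 63.54),
    "S/B":  (19.03, 0.85, 6.55, 4.77, 53.04),
    "SI":   (10.54, 0.19, 8.88, 8.69, 95.96),
    "LP%":  (36.44, 0.18, 3.12, 2.69, 74.03),
    "LI":   (6.05, 0.74, 9.56, 7.85, 80.45),
    "UI%":  (84.15, 0.45, 1.22, 1.10, 80.91),
    "FL":   (33.52, 0.45, 3.58, 3.31, 85.59),
    "PI":   (9.54, 0.12, 3.16, 2.91, 84.64),
    "MR":   (4.16, 0.45, 4.99, 4.43, 78.33),
}

_F4_SUMMARY = {
    "LY/P": (16.65, 0.49, 8.93, 8.41, 89.11),
    "B/P":  (14.77, 0.41, 6.02, 5.33, 78.14),
    "BW":   (3.33, 0.08, 4.14, 3.43, 69.63),
    "S/B":  (19.32, 0.39, 4.08, 3.55, 75.39),
    "SI":   (11.01, 0.18, 5.14, 4.89, 90.59),
    "LP%":  (36.62, 0.55, 3.40, 3.05, 80.39),
    "LI":   (6.37, 0.20, 6.28, 5.50, 74.68),
    "UI%":  (84.42, 0.31, 0.83, 0.74, 80.14),
    "FL":   (32.27, 0.44, 2.74, 2.39, 76.20),
    "PI":   (10.91, 0.23, 3.55, 2.84, 63.69),
    "MR":   (4.11, 0.04, 3.76, 3.57, 90.54),
}

_SUMMARIES = {"F2": _F2_SUMMARY, "F3": _F3_SUMMARY, "F4": _F4_SUMMARY}

# F3 pairwise correlations, canonical trait order.  Upper triangle of the
# reported matrix holds phenotypic correlations (family-mean basis), lower
# triangle genotypic correlations.  Stored as (i, j) -> r with i < j.
_F3_RP = {
    (0, 1): 0.969, (0, 2): 0.268, (0, 3): 0.453, (0, 4): -0.167,
    (0, 5): 0.195, (0, 6): -0.072, (0, 7): -0.062, (0, 8): 0.046,
    (0, 9): -0.075, (0, 10): 0.132,
    (1, 2): 0.063, (1, 3): 0.418, (1, 4): -0.268, (1, 5): 0.099,
    (1, 6): -0.240, (1, 7): -0.066, (1, 8): 0.001, (1, 9): -0.006,
    (1, 10): 0.051,
    (2, 3): 0.185, (2, 4): 0.606, (2, 5): -0.060, (2, 6): 0.610,
    (2, 7): 0.142, (2, 8): 0.239, (2, 9): -0.219, (2, 10): 0.296,
    (3, 4): -0.632, (3, 5): 0.211, (3, 6): -0.548, (3, 7): -0.203,
    (3, 8): -0.159, (3, 9): -0.093, (3, 10): 0.070,
    (4, 5): -0.411, (4, 6): 0.811, (4, 7): 0.274, (4, 8): 0.277,
    (4, 9): -0.011, (4, 10): 0.096,
    (5, 6): 0.162, (5, 7): -0.093, (5, 8): -0.014, (5, 9): -0.295,
    (5, 10): 0.215,
    (6, 7): 0.211, (6, 8): 0.257, (6, 9): -0.213, (6, 10): 0.250,
    (7, 8): 0.582, (7, 9): 0.053, (7, 10): 0.000,
    (8, 9): 0.123, (8, 10): -0.122,
    (9, 10): -0.909,
}

_F3_RG = {
    (0, 1): 0.975, (0, 2): 0.205, (0, 3): 0.507, (0, 4): -0.184,
    (0, 5): 0.225, (0, 6): -0.094, (0, 7): -0.076, (0, 8): 0.071,
    (0, 9): -0.084, (0, 10): 0.148,
    (1, 2): 0.015, (1, 3): 0.545, (1, 4): -0.299, (1, 5): 0.136,
    (1, 6): -0.290, (1, 7): -0.085, (1, 8): 0.015, (1, 9): -0.001,
    (1, 10): 0.046,
    (2, 3): -0.311, (2, 4): 0.787, (2, 5): -0.120, (2, 6): 0.871,
    (2, 7): 0.196, (2, 8): 0.336, (2, 9): -0.295, (2, 10): 0.411,
    (3, 4): -0.803, (3, 5): 0.419, (3, 6): -0.656, (3, 7): -0.304,
    (3, 8): -0.183, (3, 9): -0.140, (3, 10): 0.122,
    (4, 5): -0.489, (4, 6): 0.869, (4, 7): 0.308, (4, 8): 0.291,
    (4, 9): -0.010, (4, 10): 0.101,
    (5, 6): -0.007, (5, 7): -0.127, (5, 8): -0.057, (5, 9): -0.372,
    (5, 10): 0.282,
    (6, 7): 0.268, (6, 8): 0.268, (6, 9): -0.252, (6, 10): 0.300,
    (7, 8): 0.590, (7, 9): 0.067, (7, 10): 0.005,
    (8, 9): 0.128, (8, 10): -0.155,
    (9, 10): -0.927,
}

# Trait means of the parental varieties under water deficit stress.
_PARENT_MEANS = {
    "Giza 86":  (13.0, 13.0, 2.83, 16.0, 11.02, 38.8, 6.31,
                 84.63, 33.20, 10.60, 4.23),
    "Menoufi":  (10.9, 10.0, 2.73, 18.0, 9.70, 38.1, 5.99,
                 84.77, 32.47, 11.17, 4.13),
}


def generation_summary(generation: str) -> pd.DataFrame:
    """Reported per-trait summary for *generation* ('F2' | 'F3' | 'F4').

    Columns: mean, se, pcv, gcv, h2b (percent scale for the last three).
    F2 rows cover the seven yield traits only.
    """
    try:
        raw = _SUMMARIES[generation]
    except KeyError:
        raise ValueError(f"no reported summary for generation {generation!r}")
    order = F2_TRAITS if generation == "F2" else CANONICAL_TRAITS
    return pd.DataFrame.from_dict(raw, orient="index",
                                  columns=list(_SUMMARY_COLUMNS)).loc[list(order)]


def _corr_frame(tri: dict) -> pd.DataFrame:
    k = len(CANONICAL_TRAITS)
    m = np.eye(k)
    for (i, j), r in tri.items():
        m[i, j] = m[j, i] = r
    return pd.DataFrame(m, index=CANONICAL_TRAITS, columns=CANONICAL_TRAITS)


def f3_phenotypic_correlations() -> pd.DataFrame:
    """Reported F3 phenotypic correlation matrix (symmetric, diag 1)."""
    return _corr_frame(_F3_RP)


def f3_genotypic_correlations() -> pd.DataFrame:
    """Reported F3 genotypic correlation matrix (symmetric, diag 1)."""
    return _corr_frame(_F3_RG)


def parent_means() -> pd.DataFrame:
    """Trait means of the two parents (rows: Giza 86, Menoufi)."""
    return pd.DataFrame.from_dict(_PARENT_MEANS, orient="index",
                                  columns=list(CANONICAL_TRAITS))


def better_parent_values() -> pd.Series:
    """Per-trait better-parent value, respecting trait direction.

    The better parent is the one with the larger mean, except for
    micronaire where the smaller value is favourable.
    """
    pm = parent_means()
    out = {}
    for t in CANONICAL_TRAITS:
        col = pm[t]
        out[t] = col.min() if TRAIT_DIRECTIONS[t] < 0 else col.max()
    return pd.Series(out, name="better_parent")
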