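"""Benchmark quantities from a published best-worst milk-allocation study.

A best-worst scaling survey of 200 low-income households in peri-urban
Nairobi measured how families would re-allocate raw (informally marketed)
milk within the household if its price rose sharply: nine allocation
options, nine choice cards of four options each from a near-balanced
incomplete block design, one best and one worst pick per card.

This module collects the study's published summary numbers — option list,
best/worst counts, mixed-logit estimates, latent-class solution, and the
class-selection log-likelihoods — as plain Python data.  They serve two
purposes: regression inputs for the scoring and share-of-preference
arithmetic, and realistic parameter sets for the synthetic-data generator
(the raw survey responses themselves were never deposited).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "OPTION_LABELS",
    "OPTION_DESCRIPTIONS",
    "milk_option_labels",
    "milk_study_counts",
    "milk_study_mixed_estimates",
    "milk_study_class_solution",
    "milk_study_class_sweep_loglik",
    "milk_study_covariate_profiles",
]

OPTION_LABELS = [f"O{i}" for i in range(1, 10)]

OPTION_DESCRIPTIONS = {
    "O1": "Decrease raw milk for all members, no replacement",
    "O2": "Decrease raw milk for all, replace only for children under 4",
    "O3": "Decrease raw milk for all, replace for all except children under 4",
    "O4": "Decrease raw milk for all, replace for all members",
    "O5": "Keep children's raw milk, decrease for the rest of the family",
    "O6": "Decrease children's raw milk, no replacement, adults unchanged",
    "O7": "Decrease children's raw milk with replacement, adults unchanged",
    "O8": "Keep quantities by increasing the milk budget",
    "O9": "Stop buying raw milk",
}


def milk_option_labels() -> list[str]:
    return list(OPTION_LABELS)


def milk_study_counts() -> pd.DataFrame:
    """Published per-option best and worst pick counts (N=200, 9 cards)."""
    best = [45, 494, 24, 518, 305, 12, 239, 146, 17]
    worst = [205, 13, 235, 17, 45, 319, 48, 217, 699]
    return pd.DataFrame({"best": best, "worst": worst}, index=OPTION_LABELS)


def milk_study_mixed_estimates() -> pd.DataFrame:
    """Published mixed-logit means and standard deviations (reference O9 = 0).

    The O6 standard deviation was published with a negative sign; the
    mixing-distribution scale is its magnitude (the sign is not identified).
    """
    mu = [2.877, 5.594, 2.607, 5.843, 4.688, 2.315, 4.315, 2.950, 0.0]
    sigma = [0.696, 1.113, 0.472, 1.725, 1.418, -0.566, 1.079, 2.409, 0.0]
    return pd.DataFrame({"mu": mu, "sigma": sigma}, index=OPTION_LABELS)


def milk_study_class_solution() -> tuple[pd.DataFrame, np.ndarray]:
    """Published 3-class latent-class utilities and class shares (65/21/14%)."""
    beta = pd.DataFrame(
        {
            "class_1": [4.098, 6.533, 3.876, 7.129, 5.620, 3.699, 5.652, 3.484, 0.0],
            "class_2": [3.264, 5.363, 3.252, 5.006, 5.154, 2.789, 4.439, 6.031, 0.0],
            "class_3": [0.354, 1.487, -0.164, 1.151, 0.766, -0.341, 0.564, -1.226, 0.0],
        },
        index=OPTION_LABELS,
    ).T
    shares = np.array([0.65, 0.21, 0.14])
    return beta, shares


def milk_study_class_sweep_loglik() -> pd.DataFrame:
    """Published log-likelihoods of the 2..9-class latent-class fits."""
    return pd.DataFrame({
        "classes": list(range(2, 10)),
        "loglik": [-2801.49, -2664.97, -2586.98, -2562.83,
                   -2529.5, -2506.58, -2486.44, -2474.2],
    })


def milk_study_covariate_profiles() -> dict:
    """Published class compositions by household covariates (column %).

    Used as class-conditional categorical distributions when simulating
    respondent covariates alongside the 3-class preference structure.
    """
    return {
        "income": {
            "levels": ["<=10000 KES", "10001-20000 KES", "20001-30000 KES"],
            "probs": {
                "class_1": [0.169, 0.392, 0.439],
                "class_2": [0.190, 0.262, 0.548],
                "class_3": [0.286, 0.429, 0.285],
            },
        },
        "head_gender": {
            "levels": ["male", "female"],
            "probs": {
                "class_1": [0.769, 0.231],
                "class_2": [0.857, 0.143],
                "class_3": [0.893, 0.107],
            },
        },
        "head_age": {
            "levels": ["18-29", "30-39", "40-49", ">=50"],
            "probs": {
                "class_1": [0.377, 0.438, 0.131, 0.054],
                "class_2": [0.381, 0.405, 0.167, 0.047],
                "class_3": [0.250, 0.536, 0.107, 0.107],
            },
        },
        "head_education": {
            "levels": ["primary_vocational", "secondary", "technical_university"],
            "probs": {
                "class_1": [0.295, 0.449, 0.256],
                "class_2": [0.425, 0.475, 0.100],
                "class_3": [0.280, 0.600, 0.120],
            },
        },
    }
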