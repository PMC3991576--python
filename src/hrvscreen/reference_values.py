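"""Published reference statistics bundled with the package.

These are the group summary statistics (mean, SD, n per HRV measure) and the
classifier operating points reported for a 17-patient congestive-heart-failure
cohort versus 30 healthy controls drawn from the PhysioNet CHF and normal
sinus rhythm RR-interval databases (5-minute segments).  They serve three
purposes: deriving/validating the combined features, exercising the summary
t-test screen, and checking the balanced-AUC convention — no raw subject data
are shipped.
"""

from __future__ import annotations

import pandas as pd

from .feature_pipeline import GroupSummary

__all__ = [
    "reference_group_summary",
    "reference_combined_summary",
    "REFERENCE_GROUP_STATS",
    "REFERENCE_COMBINED_STATS",
    "REFERENCE_OPERATING_POINTS",
    "N_CHF",
    "N_HEALTHY",
]

N_CHF = 17
N_HEALTHY = 30

#: per-measure (mean_chf, sd_chf, mean_healthy, sd_healthy); band powers on
#: the ln(1+ms^2) scale, pNN50 and CVrr on the percent scale
REFERENCE_GROUP_STATS = {
    "sdnn": (298.2, 124.1, 81.3, 49.7),
    "pnn50": (13.1, 5.45, 2.90, 1.65),
    "rmssd": (380.4, 268.9, 480.0, 242.0),
    "cvrr": (3.79, 3.60, 8.59, 9.44),
    "vlf": (5.72, 2.08, 7.30, 2.61),
    "lf": (2.59, 0.96, 3.51, 1.66),
    "hf": (0.64, 0.26, 0.86, 0.42),
    "vhf": (0.38, 0.14, 0.43, 0.14),
    "tp": (9.33, 3.37, 12.1, 4.46),
    "lf_hf": (4.09, 0.35, 4.07, 0.31),
    "apen": (0.36, 0.28, 1.16, 0.38),
    "sampen": (0.33, 0.28, 1.21, 0.40),
}

#: the combined features' published group statistics, same layout
REFERENCE_COMBINED_STATS = {
    "sum_td": (307.47, 129.0, 75.60, 44.86),
    "sum_fd": (18.29, 6.60, 23.78, 8.79),
    "sum_ie": (0.68, 0.56, 2.37, 0.77),
}

#: published classifier rows as (classifier, features, acc, pre, sen, spe, auc), percent
REFERENCE_OPERATING_POINTS = [
    ("knn", "all_12", 57.45, 70.59, 44.44, 75.00, 59.72),
    ("knn", "time_domain", 89.36, 76.47, 92.86, 87.88, 90.37),
    ("knn", "frequency_domain", 59.57, 70.59, 46.15, 76.19, 61.17),
    ("knn", "nonlinear", 80.85, 88.24, 68.18, 92.00, 80.09),
    ("knn", "time_domain+nonlinear", 91.49, 94.12, 84.21, 96.43, 90.32),
    ("svm", "sum_td+sum_fd+sum_ie", 100.00, 100.00, 100.00, 100.00, 100.00),
    ("svm", "sum_td+sum_fd", 100.00, 100.00, 100.00, 100.00, 100.00),
    ("svm", "sum_td+sum_ie", 97.98, 100.00, 94.12, 100.00, 97.06),
    ("svm", "sum_ie+sum_fd", 97.98, 100.00, 94.12, 100.00, 97.06),
    ("svm", "sum_td", 91.49, 88.24, 88.24, 93.33, 90.78),
    ("svm", "sum_fd", 59.57, 47.06, 44.44, 68.97, 56.70),
    ("svm", "sum_ie", 95.74, 88.24, 100.00, 93.75, 96.88),
    ("svm", "all_12", 100.00, 100.00, 100.00, 100.00, 100.00),
]


def _summary_frame(stats: dict) -> pd.DataFrame:
    rows = {
        feat: (m1, s1, N_CHF, m2, s2, N_HEALTHY)
        for feat, (m1, s1, m2, s2) in stats.items()
    }
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["mean_chf", "sd_chf", "n_chf", "mean_healthy", "sd_healthy", "n_healthy"],
    )


def reference_group_summary() -> GroupSummary:
    """The published 12-measure group summary as a :class:`GroupSummary`."""
    return GroupSummary(_summary_frame(REFERENCE_GROUP_STATS))


def reference_combined_summary() -> GroupSummary:
    """The published combined-feature group summary."""
    return GroupSummary(_summary_frame(REFERENCE_COMBINED_STATS))
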