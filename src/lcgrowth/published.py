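"""Published DCHS class-allocation and abnormal-growth count tables.

These are the printed counts from the published 5-year growth
trajectory analysis of the Drakenstein Child Health Study cohort:
cross-tabulations of the five joint (zHeight + zWeight) classes
against the four univariate zHeight and zWeight classes, and the
abnormal-growth feature tables (rapid weight gain by zWeight class,
ever-stunted by zHeight class, ever-under/overweight by zWeight
class).  The counts serve as fixed reference inputs for validating
the tabulation arithmetic (row percentages, marginals, feature
percentages); the underlying cohort data are not public.

Note the published tables are internally inconsistent in two places
(the zWeight class of 584 children is printed as 581 in the
cross-tabulation, and the two feature-table denominators differ:
1136 vs 1139); each table is encoded exactly as printed.
"""

from __future__ import annotations

import pandas as pd

MULTIVARIATE_CLASSES = ["i", "ii", "iii", "iv", "v"]

HEIGHT_CLASSES = [
    "Gradual Decrease to Low",
    "Gradual Increase; Gradual Decrease to Below Expected",
    "Sharp Decrease to Low",
    "Sharp Decrease; Sharp Increase to Below Expected",
]

WEIGHT_CLASSES = [
    "Gradual Decrease to Low",
    "Gradual Increase; Gradual Decrease to Expected",
    "Sharp Decrease; Sharp Increase to Expected",
    "Sharp Increase to High",
]


def multivariate_vs_height_counts() -> pd.DataFrame:
    """Joint-model classes (rows) x univariate zHeight classes (columns)."""
    data = [
        [10, 48, 218, 42],
        [84, 46, 75, 0],
        [3, 12, 42, 18],
        [12, 138, 128, 18],
        [3, 77, 53, 109],
    ]
    return pd.DataFrame(data, index=MULTIVARIATE_CLASSES, columns=HEIGHT_CLASSES)


def multivariate_vs_height_printed_pct() -> pd.DataFrame:
    data = [
        [3.14, 15.09, 68.55, 13.21],
        [41.0, 22.4, 36.6, 0.0],
        [4.0, 16.0, 56.0, 24.0],
        [4.1, 46.6, 43.2, 6.1],
        [1.3, 31.8, 21.9, 45.0],
    ]
    return pd.DataFrame(data, index=MULTIVARIATE_CLASSES, columns=HEIGHT_CLASSES)


def multivariate_vs_weight_counts() -> pd.DataFrame:
    """Joint-model classes (rows) x univariate zWeight classes (columns)."""
    data = [
        [138, 118, 61, 1],
        [105, 100, 0, 0],
        [2, 16, 51, 6],
        [18, 265, 5, 8],
        [0, 82, 33, 127],
    ]
    return pd.DataFrame(data, index=MULTIVARIATE_CLASSES, columns=WEIGHT_CLASSES)


def multivariate_vs_weight_printed_pct() -> pd.DataFrame:
    data = [
        [43.4, 37.1, 19.2, 0.3],
        [51.2, 48.8, 0.0, 0.0],
        [2.7, 21.3, 68.0, 8.0],
        [6.1, 89.5, 1.7, 2.7],
        [0.0, 33.9, 13.6, 52.5],
    ]
    return pd.DataFrame(data, index=MULTIVARIATE_CLASSES, columns=WEIGHT_CLASSES)


HEIGHT_MARGINAL_PRINTED_PCT = pd.Series([9.9, 28.3, 45.4, 16.5], index=HEIGHT_CLASSES)
WEIGHT_MARGINAL_PRINTED_PCT = pd.Series([23.2, 51.1, 13.2, 12.5], index=WEIGHT_CLASSES)


def rwg_by_weight_class() -> pd.DataFrame:
    """Normal vs rapid-weight-gain counts within each zWeight class."""
    return pd.DataFrame(
        {
            "class": WEIGHT_CLASSES,
            "n_normal": [235, 108, 206, 9],
            "n_rwg": [3, 17, 265, 124],
            "printed_rwg_pct": [1.3, 13.6, 56.3, 93.2],
        }
    )


def stunted_by_height_class() -> pd.DataFrame:
    """Ever-stunted counts within each zHeight class, plus the cohort row."""
    return pd.DataFrame(
        {
            "class": [
                "Sharp Decrease to Low",
                "Gradual Decrease to Low",
                "Sharp Decrease, Sharp Increase to Below Expected",
                "Gradual Increase, Gradual Decrease to Below Expected",
                "Entire Cohort",
            ],
            "n_stunted": [263, 61, 136, 110, 570],
            "n_total": [516, 112, 187, 321, 1136],
            "printed_pct": [51.0, 55.0, 73.0, 34.0, 50.0],
        }
    )


def under_over_by_weight_class() -> pd.DataFrame:
    """Ever-underweight / ever-overweight counts within each zWeight class."""
    return pd.DataFrame(
        {
            "class": WEIGHT_CLASSES + ["Entire Cohort"],
            "n_underweight": [91, 75, 76, 44, 286],
            "n_overweight": [31, 18, 77, 58, 184],
            "n_total": [263, 150, 584, 142, 1139],
            "printed_underweight_pct": [35.0, 50.0, 13.0, 31.0, 25.0],
            "printed_overweight_pct": [12.0, 12.0, 13.0, 41.0, 16.0],
        }
    )
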