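"""Cross-tabulation of class allocations and abnormal-growth features.

Compares class labelings across models (counts and row percentages),
flags cells enriched relative to the cohort marginals, and derives
per-subject abnormal-growth indicators: rapid weight gain (zWeight
gain >= 0.67 between birth and nine months), and ever
stunted/underweight/overweight (any zHeight < -2 / zWeight < -2 /
zWeight > 2 before age 5; strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RWG_THRESHOLD = 0.67
BIRTH_AGE_MAX_YEARS = 0.02
NINE_MONTH_WINDOW_YEARS = (0.6, 0.9)
NINE_MONTH_TARGET_YEARS = 0.75


@dataclass
class CrossTab:
    """Counts and row-percentages of allocations between two labelings."""

    counts: pd.DataFrame       # R x C integer counts
    row_pct: pd.DataFrame      # counts / row totals x 100
    col_marginal_pct: pd.Series  # column totals / N x 100

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def crosstab(labels_a: pd.Series, labels_b: pd.Series) -> CrossTab:
    """Cross-tabulate two class labelings of the same subjects.

    Both inputs are Series indexed by subject id; a mismatch in the
    subject sets is an error listing the offenders.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    only_a = sorted(set(a.index) - set(b.index), key=str)
    only_b = sorted(set(b.index) - set(a.index), key=str)
    if only_a or only_b:
        raise ValueError(f"subject mismatch; only in first: {only_a[:10]}, only in second: {only_b[:10]}")
    b = b.loc[a.index]
    counts = pd.crosstab(a, b)
    return crosstab_from_counts(counts)


def crosstab_from_counts(counts: pd.DataFrame) -> CrossTab:
    """Build a :class:`CrossTab` directly from a table of counts."""
    counts = counts.astype(int)
    row_tot = counts.sum(axis=1)
    row_pct = counts.div(row_tot.replace(0, np.nan), axis=0) * 100.0
    col_marginal = counts.sum(axis=0) / counts.to_numpy().sum() * 100.0
    return CrossTab(counts=counts, row_pct=row_pct, col_marginal_pct=col_marginal)


def enrichment_flags(ct: CrossTab) -> pd.DataFrame:
    """Cells whose row percentage exceeds the cohort column marginal.

    Such cells indicate a strong association between the row class and
    the column class.  Returns a long table with the effect size
    (row_pct - col_marginal_pct) for every cell and a boolean flag.
    """
    rows = []
    for r in ct.counts.index:
        for c in ct.counts.columns:
            rp = float(ct.row_pct.loc[r, c])
            mp = float(ct.col_marginal_pct[c])
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "count": int(ct.counts.loc[r, c]),
                    "row_pct": rp,
                    "col_marginal_pct": mp,
                    "effect": rp - mp,
                    "flagged": rp > mp,
                }
            )
    return pd.DataFrame(rows)


def flag_rwg(zweight: pd.DataFrame):
    """Rapid-weight-gain flag from a subject's zWeight series.

    Anchors: birth = first observation at age <= 0.02 y; nine months =
    observation nearest 0.75 y within [0.6, 0.9] y.  Flag is
    z(9m) - z(birth) >= 0.67 (inclusive).  Returns True/False, or None
    when either anchor visit is missing (undefined; excluded from
    denominators).
    """
    d = zweight.sort_values("age_years")
    birth = d[d["age_years"] <= BIRTH_AGE_MAX_YEARS]
    lo, hi = NINE_MONTH_WINDOW_YEARS
    window = d[(d["age_years"] >= lo) & (d["age_years"] <= hi)]
    if birth.empty or window.empty:
        return None
    z0 = float(birth.iloc[0]["z"])
    nearest = window.iloc[(window["age_years"] - NINE_MONTH_TARGET_YEARS).abs().argmin()]
    return bool(float(nearest["z"]) - z0 >= RWG_THRESHOLD)


def flag_ever(z_series, threshold: float, direction: str):
    """Whether any observation strictly crosses a threshold.

    ``direction`` 'below' flags any z < threshold; 'above' any
    z > threshold.  Returns None for an empty series (undefined).
    """
    z = np.asarray(z_series, dtype=float)
    if z.size == 0:
        return None
    if direction == "below":
        return bool(np.any(z < threshold))
    if direction == "above":
        return bool(np.any(z > threshold))
    raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")


def abnormal_flags(zpanel: pd.DataFrame) -> pd.DataFrame:
    """Per-subject abnormal-growth flags from a standardized panel.

    Columns: subject_id, rwg, ever_stunted, ever_underweight,
    ever_overweight; entries are pandas nullable booleans with <NA>
    where the flag is undefined (missing anchor visits / no usable
    observations).
    """
    rows = []
    for sid, grp in zpanel.groupby("subject_id"):
        zh = grp[grp["response"] == "zHeight"]
        zw = grp[grp["response"] == "zWeight"]
        rows.append(
            {
                "subject_id": sid,
                "rwg": flag_rwg(zw) if not zw.empty else None,
                "ever_stunted": flag_ever(zh["z"], -2.0, "below"),
                "ever_underweight": flag_ever(zw["z"], -2.0, "below"),
                "ever_overweight": flag_ever(zw["z"], 2.0, "above"),
            }
        )
    out = pd.DataFrame(rows)
    for c in ("rwg", "ever_stunted", "ever_underweight", "ever_overweight"):
        out[c] = out[c].astype("boolean")
    return out


def class_feature_table(labels: pd.Series, flags: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Per-class counts and percentages of a binary abnormal-growth feature.

    ``labels`` is a Series of class labels indexed by subject id;
    ``flags`` is the output of :func:`abnormal_flags`.  Subjects with
    an undefined flag are excluded from the denominators.  A cohort
    column aggregates over all classes.  Percentages are rounded
    half-up to one decimal place.
    """
    merged = flags.set_index("subject_id").join(pd.Series(labels, name="_class"), how="inner")
    merged = merged[merged[feature].notna()]
    rows = []
    groups = list(merged.groupby("_class")) + [("Entire Cohort", merged)]
    for cls, grp in groups:
        n_total = len(grp)
        n_flag = int(grp[feature].sum())
        pct = _round_half_up(100.0 * n_flag / n_total, 1) if n_total else float("nan")
        rows.append({"class": cls, "n_flagged": n_flag, "n_total": n_total, "percentage": pct})
    return pd.DataFrame(rows)


def _round_half_up(x: float, ndigits: int) -> float:
    factor = 10.0**ndigits
    return float(np.floor(x * factor + 0.5) / factor)
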