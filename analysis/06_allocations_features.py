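"""Compare class allocations across models and profile abnormal growth.

Cross-tabulates the joint-model classes against the univariate
zHeight and zWeight classes (counts, row percentages, cells enriched
over the cohort marginals), then tabulates rapid weight gain and
ever-stunted / ever-under/overweight by class.
"""

import pandas as pd

from common import RESULTS, ZPANEL_CSV, ensure_dirs, require

from lcgrowth.allocation import abnormal_flags, class_feature_table, crosstab, enrichment_flags


def main() -> None:
    ensure_dirs()
    zpanel = pd.read_csv(require(ZPANEL_CSV, "02_standardize.py"))
    alloc = pd.read_csv(require(RESULTS / "allocations.csv", "04_fit_classes.py")).set_index("subject_id")

    joint = "zHeight+zWeight"
    for uni in ("zHeight", "zWeight"):
        pair = alloc[[joint, uni]].dropna()
        ct = crosstab(pair[joint], pair[uni])
        ct.counts.to_csv(RESULTS / f"crosstab_{uni}_counts.csv")
        ct.row_pct.round(1).to_csv(RESULTS / f"crosstab_{uni}_row_pct.csv")
        enriched = enrichment_flags(ct)
        enriched.to_csv(RESULTS / f"crosstab_{uni}_enrichment.csv", index=False)
        top = enriched[enriched.flagged].nlargest(3, "effect")
        print(f"joint vs {uni}: strongest enrichments (row% over cohort marginal%):")
        for _, r in top.iterrows():
            print(f"  joint class {r.row} x {uni} class {r.col}: {r.row_pct:.1f}% vs {r.col_marginal_pct:.1f}%")

    flags = abnormal_flags(zpanel)
    flags.to_csv(RESULTS / "abnormal_flags.csv", index=False)
    features = {"zWeight": ("rwg", "ever_underweight", "ever_overweight"), "zHeight": ("ever_stunted",)}
    for model, feats in features.items():
        labels = alloc[model].dropna()
        for feat in feats:
            tab = class_feature_table(labels, flags, feat)
            tab.to_csv(RESULTS / f"{model}_{feat}.csv", index=False)
            cohort_row = tab[tab["class"] == "Entire Cohort"].iloc[0]
            peak = tab[tab["class"] != "Entire Cohort"].nlargest(1, "percentage").iloc[0]
            print(f"{feat} by {model} class: cohort {cohort_row.percentage}% "
                  f"({cohort_row.n_flagged}/{cohort_row.n_total}); "
                  f"peak class {peak['class']} at {peak.percentage}%")


if __name__ == "__main__":
    main()
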