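"""Standardize the raw cohort measurements to growth z-scores.

Resolves the duplicated technical replicates (0.5 cm / 0.1 kg
tolerances, third measurement on disagreement), applies the
preterm reference switching (Fenton-role chart until 50 weeks
postmenstrual age, then WHO-role with gestational-age-corrected ages
until 2 years) and computes the four responses zHeight, zWeight,
zBMI and zWFH, dropping implausible observations (|z| > 6).
"""

import pandas as pd

from common import CHARTS_CSV, RAW_CSV, RESULTS, ZPANEL_CSV, ensure_dirs, require

from lcgrowth import standardize_cohort
from lcgrowth.lms import ChartSet
from lcgrowth.standardize import write_zpanel_csv


def main() -> None:
    ensure_dirs()
    panel = pd.read_csv(require(RAW_CSV, "01_simulate_cohort.py"))
    charts = ChartSet.from_csv(CHARTS_CSV)
    zpanel, exclusions = standardize_cohort(panel, charts)
    write_zpanel_csv(zpanel, ZPANEL_CSV)
    exclusions.to_csv(RESULTS / "exclusions.csv", index=False)

    print(f"standardized {len(zpanel)} observations from {len(panel)} visits -> {ZPANEL_CSV}")
    if len(exclusions):
        print("exclusions by reason:", exclusions["reason"].value_counts().to_dict())
    summary = zpanel.groupby("response")["z"].agg(["count", "mean", "std"]).round(3)
    summary.to_csv(RESULTS / "zscore_summary.csv")
    print(summary.to_string())


if __name__ == "__main__":
    main()
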