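"""Choose broken-stick knot locations by AIC of single-class mixed fits.

For each response, candidate knot sets (the packaged defaults, a
sparser alternative, and the extended later-age set used for
sensitivity analysis) are fit as K=1 linear mixed models and compared
by AIC.
"""

import pandas as pd

from common import RESULTS, ZPANEL_CSV, ensure_dirs, require

from lcgrowth.basis import DEFAULT_KNOTS, EXTENDED_KNOTS, SplineSpec, select_knots_aic

CANDIDATES = {
    "default": None,  # per-response default
    "sparse": (0.5, 1.5),
    "extended": EXTENDED_KNOTS,
}


def main() -> None:
    ensure_dirs()
    zpanel = pd.read_csv(require(ZPANEL_CSV, "02_standardize.py"))
    tables = []
    for response in ("zHeight", "zWeight", "zBMI", "zWFH"):
        cands = [
            SplineSpec(DEFAULT_KNOTS[response]),
            SplineSpec(CANDIDATES["sparse"]),
            SplineSpec(CANDIDATES["extended"]),
        ]
        best, table = select_knots_aic(zpanel, response, cands)
        table.insert(0, "response", response)
        tables.append(table)
        print(f"{response}: best knots by AIC = {best.knots}")
    out = pd.concat(tables, ignore_index=True)
    out.to_csv(RESULTS / "knot_selection_aic.csv", index=False)
    print(f"full AIC table -> {RESULTS / 'knot_selection_aic.csv'}")


if __name__ == "__main__":
    main()
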