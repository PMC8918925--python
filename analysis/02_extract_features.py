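"""Segment both cohorts into 5-min windows and extract the 14 features.

Writes the full per-segment feature matrices to scratch/ and a compact
class comparison (per-feature class means and one-tailed rank-sum p,
AF-HF lower) to results/feature_class_comparison.csv.
"""

import pandas as pd

from afhf.classify import wilcoxon_feature_test
from afhf.features import FEATURE_NAMES
from afhf.pipeline import build_feature_table
from afhf.rr_core import read_rr_table
from common import CIRCADIAN_STUDY, DAY_STUDY, RESULTS, SCRATCH, ensure_dirs


def main() -> None:
    ensure_dirs()
    for name, cfg in (("day_study", DAY_STUDY), ("circadian_study", CIRCADIAN_STUDY)):
        series = read_rr_table(SCRATCH / f"{name}_rr.csv")
        table = build_feature_table(series, cfg)
        table.to_csv(SCRATCH / f"{name}_features.csv", index=False)
        print(f"{name}: {len(table)} segments "
              f"({(table.circadian_tag == 'day').sum()} day / "
              f"{(table.circadian_tag == 'night').sum()} night)")

    day = pd.read_csv(SCRATCH / "day_study_features.csv")
    day = day[day.circadian_tag == "day"]
    rows = []
    for f in FEATURE_NAMES:
        means = day.groupby("label")[f].mean()
        p, _ = wilcoxon_feature_test(day, f, direction="less")
        rows.append(
            {
                "feature": f,
                "mean_afhf": round(means.get("AF-HF"), 4),
                "mean_control": round(means.get("control"), 4),
                "ranksum_p_afhf_lower": float(f"{p:.3g}"),
            }
        )
    cmp = pd.DataFrame(rows)
    cmp.to_csv(RESULTS / "feature_class_comparison.csv", index=False)
    print("\nclass comparison (day study, daytime segments):")
    print(cmp.to_string(index=False))


if __name__ == "__main__":
    main()
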