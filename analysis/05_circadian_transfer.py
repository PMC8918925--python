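"""Circadian transfer: does the daytime model survive the night?

On the circadian-study cohort (16 h recordings covering 08:00-24:00),
selects and trains on daytime segments, then applies the same tree to
the held-out test patients' night and full-day segments; finally
re-optimises a feature set on night segments for comparison.  Writes
results/circadian_transfer.json and prints a dataset x feature-set
performance grid.
"""

import json

import pandas as pd

from afhf.classify import evaluate, run_experiment
from afhf.features import FEATURE_NAMES
from common import CIRCADIAN_STUDY, RESULTS, SCRATCH, ensure_dirs


def main() -> None:
    ensure_dirs()
    table = pd.read_csv(SCRATCH / "circadian_study_features.csv")
    seeds = CIRCADIAN_STUDY.sub_seeds()
    day = table[table.circadian_tag == "day"].reset_index(drop=True)
    night = table[table.circadian_tag == "night"].reset_index(drop=True)

    day_res = run_experiment(day, list(FEATURE_NAMES), split_seed=seeds["split"],
                             single_feature_baselines=False)
    grid = {
        "day_model_on_day": day_res.report.to_dict(),
    }
    for name, other in (("night", night), ("full", table.reset_index(drop=True))):
        mask = other["patient_id"].isin(day_res.plan.test_patients).to_numpy()
        rep = evaluate(day_res.tree, other, day_res.selection.selected, mask)
        grid[f"day_model_on_{name}"] = rep.to_dict()

    night_res = run_experiment(
        night, list(FEATURE_NAMES), split_seed=seeds["split"],
        single_feature_baselines=False, plan=day_res.plan,
    )
    grid["night_model_on_night"] = night_res.report.to_dict()

    with open(RESULTS / "circadian_transfer.json", "w") as fh:
        json.dump(
            {
                "day_selected": day_res.selection.selected,
                "night_selected": night_res.selection.selected,
                "grid": {k: {m: v[m] for m in ("accuracy", "sensitivity",
                                               "specificity", "ppv",
                                               "patient_accuracy")}
                         for k, v in grid.items()},
            },
            fh, indent=2,
        )

    print("day-selected features:  ", day_res.selection.selected)
    print("night-selected features:", night_res.selection.selected)
    print(f"{'evaluation':<22} {'ACC':>6} {'sens':>6} {'spec':>6} {'PPV':>6}")
    for k, v in grid.items():
        print(f"{k:<22} {v['accuracy']:6.1f} {v['sensitivity']:6.1f} "
              f"{v['specificity']:6.1f} {v['ppv']:6.1f}")


if __name__ == "__main__":
    main()
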