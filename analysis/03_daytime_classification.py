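"""Daytime classification: greedy selection, final tree, held-out test.

Runs the full protocol on the day-study cohort's daytime segments:
correlation-gated greedy forward selection over 5 patient-grouped
folds (32/8 train/validation patients), retraining on all 40 non-test
patients, and a single evaluation on the 12 held-out test patients —
plus single-feature baselines.  Writes selection, evaluation and
baseline artifacts to results/.
"""

import json

import numpy as np
import pandas as pd

from afhf.classify import run_experiment
from afhf.features import FEATURE_NAMES
from common import DAY_STUDY, RESULTS, SCRATCH, ensure_dirs


def main() -> None:
    ensure_dirs()
    table = pd.read_csv(SCRATCH / "day_study_features.csv")
    day = table[table.circadian_tag == "day"].reset_index(drop=True)
    seeds = DAY_STUDY.sub_seeds()
    res = run_experiment(day, list(FEATURE_NAMES), split_seed=seeds["split"])

    res.selection.to_json(RESULTS / "selection_day.json")
    res.report.to_json(RESULTS / "eval_day.json")
    with open(RESULTS / "single_feature_accuracies.json", "w") as fh:
        json.dump(res.single_feature_accuracies, fh, indent=2)

    r = res.report
    print("selected features:", res.selection.selected)
    print("validation-accuracy trajectory:",
          [round(a, 4) for a in res.selection.accuracy_trajectory])
    print(f"test segments: {r.n_segments}  "
          f"ACC {r.accuracy:.1f}%  sens {r.sensitivity:.1f}%  "
          f"spec {r.specificity:.1f}%  PPV {r.ppv:.1f}%")
    print(f"patients correct by majority vote: "
          f"{sum(i['call'] == i['true_label'] for i in r.per_patient.values())}"
          f"/{len(r.per_patient)} ({r.patient_accuracy:.1f}%)")
    best = max(res.single_feature_accuracies, key=res.single_feature_accuracies.get)
    print(f"best single feature: {best} "
          f"({res.single_feature_accuracies[best]:.1f}%)")
    print("per-patient test accuracies:")
    for pid, info in r.per_patient.items():
        print(f"  {pid:<6} {info['true_label']:<8} {info['n_segments']:>3} segs  "
              f"{info['acc_pct']:6.2f}%  -> {info['call']}")


if __name__ == "__main__":
    main()
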