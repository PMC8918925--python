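"""End-to-end orchestration of the study emulation.

One run executes, for each requested circadian window: ingest (or
simulate) -> segment -> featurize -> greedy-select -> retrain ->
evaluate once on the held-out test patients -> Shapley importances,
plus the cross-window transfer evaluation (the day-selected feature
set and day-trained tree applied to night and full-day segments).
Every artifact is plain CSV/JSON; a manifest of all parameters and
derived sub-seeds makes each run reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import rr_core
from .rr_core import RRSeries, circadian_filter, segment_series
from .features import FeatureConfig, FEATURE_NAMES, feature_table
from .cohort import CohortConfig, simulate_cohort, write_manifest
from .classify import (
    ExperimentResult,
    TreeConfig,
    evaluate,
    run_experiment,
)
from .importance import shapley_importance

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_csv: str | None = None  # if None, simulate
    cohort: CohortConfig = field(default_factory=CohortConfig)
    segment_seconds: float = 300.0
    min_beats: int = 100
    windows: tuple[str, ...] = ("day", "night", "full")
    features: FeatureConfig = field(default_factory=FeatureConfig)
    gate: float = 0.6
    tree: TreeConfig = field(default_factory=TreeConfig)
    shapley_runs: int = 1000
    shapley_samples: int = 100
    seed: int = 0

    def sub_seeds(self) -> dict[str, int]:
        """Named sub-seeds fanned out from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("cohort", "split", "tree", "shapley")
        children = ss.spawn(len(names))
        return {
            n: int(c.generate_state(1)[0] % (2**31 - 1))
            for n, c in zip(names, children)
        }


def load_or_simulate(config: RunConfig) -> tuple[list[RRSeries], dict]:
    if config.input_csv is not None:
        series = rr_core.read_rr_table(config.input_csv)
        return series, {"source": str(config.input_csv)}
    seeds = config.sub_seeds()
    cohort_cfg = CohortConfig(
        n_per_class=config.cohort.n_per_class,
        duration_h=config.cohort.duration_h,
        mean_hr=tuple(config.cohort.mean_hr),
        hr_sd_bpm=config.cohort.hr_sd_bpm,
        cv_rr=tuple(config.cohort.cv_rr),
        ar_rho=tuple(config.cohort.ar_rho),
        circadian_amp=tuple(config.cohort.circadian_amp),
        artifact_rate=config.cohort.artifact_rate,
        gap_range_s=tuple(config.cohort.gap_range_s),
        seed=seeds["cohort"],
    )
    return simulate_cohort(cohort_cfg)


def build_feature_table(
    series: list[RRSeries], config: RunConfig
) -> pd.DataFrame:
    segments = []
    for s in series:
        segments.extend(
            segment_series(s, config.segment_seconds, config.min_beats)
        )
    return feature_table(segments, config.features)


def run_window(
    table: pd.DataFrame, window: str, config: RunConfig
) -> ExperimentResult:
    """Selection + final training + single test evaluation for one window."""
    sub = table.loc[table["circadian_tag"] == window] if window != "full" else table
    sub = sub.reset_index(drop=True)
    seeds = config.sub_seeds()
    tree_cfg = TreeConfig(
        min_samples_leaf=config.tree.min_samples_leaf,
        max_depth=config.tree.max_depth,
        random_state=seeds["tree"],
    )
    return run_experiment(
        sub,
        list(FEATURE_NAMES),
        split_seed=seeds["split"],
        gate=config.gate,
        tree_config=tree_cfg,
    )


def cmd_run(config: RunConfig, out_dir) -> Path:
    """Execute the whole study emulation and write all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.sub_seeds()

    manifest = {
        "seed": config.seed,
        "sub_seeds": seeds,
        "segment_seconds": config.segment_seconds,
        "min_beats": config.min_beats,
        "gate": config.gate,
        "windows": list(config.windows),
        "cohort": _jsonable(asdict(config.cohort)),
        "features": asdict(config.features),
        "tree": asdict(config.tree),
        "shapley": {"n_runs": config.shapley_runs, "n_samples": config.shapley_samples},
    }

    series, cohort_manifest = load_or_simulate(config)
    manifest["cohort_manifest"] = _jsonable(cohort_manifest)
    table = build_feature_table(series, config)
    table.to_csv(out / "features.csv", index=False)

    results: dict[str, ExperimentResult] = {}
    for window in config.windows:
        logger.info("window %s: selection + evaluation", window)
        res = run_window(table, window, config)
        results[window] = res
        res.selection.to_json(out / f"selection_{window}.json")
        res.report.to_json(out / f"eval_{window}.json")
        with open(out / f"singles_{window}.json", "w") as fh:
            json.dump(res.single_feature_accuracies, fh, indent=2)

    # Shapley importance for the day model (the study's primary window)
    primary = "day" if "day" in results else list(results)[0]
    res = results[primary]
    sub = (
        table.loc[table["circadian_tag"] == primary]
        if primary != "full"
        else table
    ).reset_index(drop=True)
    imp = shapley_importance(
        res.tree,
        sub,
        res.selection.selected,
        n_runs=config.shapley_runs,
        n_samples=config.shapley_samples,
        seed=seeds["shapley"],
    )
    imp.to_json(out / "importance.json")
    imp.to_frame().to_csv(out / "importance.csv", index=False)

    # cross-window transfer: day-trained model applied to the other windows
    transfer = {}
    if primary in results:
        for window in config.windows:
            if window == primary:
                continue
            other = (
                table.loc[table["circadian_tag"] == window]
                if window != "full"
                else table
            ).reset_index(drop=True)
            mask = other["patient_id"].isin(res.plan.test_patients).to_numpy()
            if mask.sum() == 0:
                continue
            rep = evaluate(res.tree, other, res.selection.selected, mask)
            transfer[f"{primary}_to_{window}"] = rep.to_dict()
    with open(out / "transfer.json", "w") as fh:
        json.dump(transfer, fh, indent=2)

    summary = summarize(results, transfer)
    (out / "summary.txt").write_text(summary)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def summarize(results: dict[str, ExperimentResult], transfer: dict) -> str:
    """Human-readable dataset x feature-set x metrics grid."""
    lines = ["window    features                                  ACC    sens   spec   PPV    patients"]
    for window, res in results.items():
        r = res.report
        feats = ",".join(res.selection.selected)
        lines.append(
            f"{window:<9} {feats:<41} {r.accuracy:6.1f} {r.sensitivity:6.1f} "
            f"{r.specificity:6.1f} {r.ppv:6.1f} {r.patient_accuracy:6.1f}"
        )
    for name, rep in transfer.items():
        lines.append(
            f"{name:<9} (transfer)                                {rep['accuracy']:6.1f}"
        )
    return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def cmd_features(
    input_csv, out_csv, config: RunConfig, window: str = "full"
) -> pd.DataFrame:
    """Standalone featurization of an RR table (no modelling)."""
    series = rr_core.read_rr_table(input_csv)
    segments = []
    for s in series:
        segs = segment_series(s, config.segment_seconds, config.min_beats)
        segments.extend(circadian_filter(segs, window))
    table = feature_table(segments, config.features)
    table.to_csv(out_csv, index=False)
    return table
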