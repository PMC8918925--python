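"""Correlation-gated greedy forward feature selection.

Starting from an empty set, each iteration trains the classifier on the
current set plus one candidate, for every candidate whose absolute
Pearson correlation with every already-selected feature (computed on
pooled training segments) is below the gate (0.6 by default), and
accepts the candidate with the highest mean validation accuracy across
the patient-grouped folds — but only if that accuracy strictly
improves.  Selection never touches test-set segments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    selected: list[str]
    accuracy_trajectory: list[float]
    rejected_by_correlation: dict[str, str]
    stop_reason: str  # "no-improvement" | "exhausted"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected": self.selected,
                    "accuracy_trajectory": self.accuracy_trajectory,
                    "rejected_by_correlation": self.rejected_by_correlation,
                    "stop_reason": self.stop_reason,
                },
                fh,
                indent=2,
            )


def pairwise_correlations(
    table: pd.DataFrame, feature_subset: list[str]
) -> pd.DataFrame:
    """Pearson correlation matrix of the given feature columns.

    A zero-variance feature yields NaN correlations; callers must treat
    NaN as gating (conservative: an uninformative constant feature is
    never worth adding).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 segments for correlations")
    x = table[feature_subset].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=feature_subset, columns=feature_subset)


def _passes_gate(
    candidate: str, selected: list[str], corr: pd.DataFrame, gate: float
) -> str | None:
    """Return the blocking feature name, or None if the gate passes."""
    for s in selected:
        r = corr.loc[candidate, s]
        if np.isnan(r) or abs(r) >= gate:
            return s
    return None


def greedy_forward_select(
    table: pd.DataFrame,
    features: list[str],
    folds: list[tuple[np.ndarray, np.ndarray]],
    train_eval_fn,
    gate: float = 0.6,
) -> SelectionResult:
    """Greedy forward selection over patient-grouped folds.

    Parameters
    ----------
    table : segment-level feature table with lineage columns.
    features : candidate feature names.
    folds : list of (train_row_mask, validation_row_mask) boolean arrays
        over ``table`` rows, patient-grouped and class-balanced.
    train_eval_fn : callable(table, feature_list, train_mask, val_mask)
        -> validation accuracy in [0, 1]; the classifier wrapper.
    gate : absolute-Pearson-correlation threshold; candidates at or
        above it against any selected feature are blocked.

    Ties on validation accuracy are broken toward the candidate with the
    lower mean |r| to the already-selected set, then by feature-name
    order, so the result is deterministic.
    """
    if len(table) == 0:
        raise ValueError("empty dataset")
    if not features:
        raise ValueError("no candidate features")

    # correlations on the pooled training segments across folds
    train_pool = np.zeros(len(table), dtype=bool)
    for tr, _ in folds:
        train_pool |= tr
    corr = pairwise_correlations(table.loc[train_pool], list(features))

    selected: list[str] = []
    trajectory: list[float] = []
    rejected: dict[str, str] = {}
    best_acc = 0.0
    remaining = list(features)

    while remaining:
        candidates = []
        for f in remaining:
            blocker = _passes_gate(f, selected, corr, gate)
            if blocker is not None:
                rejected.setdefault(f, blocker)
                continue
            candidates.append(f)
        if not candidates:
            return SelectionResult(selected, trajectory, rejected, "exhausted")

        scores: dict[str, float] = {}
        for f in candidates:
            accs = [
                train_eval_fn(table, selected + [f], tr, va) for tr, va in folds
            ]
            scores[f] = float(np.mean(accs))

        def _tiebreak(f: str) -> tuple[float, str]:
            mean_r = (
                float(np.mean([abs(corr.loc[f, s]) for s in selected]))
                if selected
                else 0.0
            )
            return (mean_r, f)

        top = max(scores.values())
        best = min((f for f in candidates if scores[f] == top), key=_tiebreak)
        if top <= best_acc:
            return SelectionResult(selected, trajectory, rejected, "no-improvement")
        best_acc = top
        selected.append(best)
        trajectory.append(top)
        remaining.remove(best)
        logger.info("selected %s (mean validation accuracy %.4f)", best, top)

    return SelectionResult(selected, trajectory, rejected, "exhausted")
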