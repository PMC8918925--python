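"""Decision-tree classification with patient-grouped cross-validation.

A cohort is split by patient into a held-out test set (6+6 at the
52-patient study size) and five class-balanced train/validation folds
(32/8) over the remaining patients.  Greedy selection runs on the
folds; the final tree is retrained on all non-test patients with the
selected features and evaluated once on the untouched test set.
Priors are uniform (each class weighted inversely to its frequency).
Segment metrics use AF-HF as the positive class; patients are called
by majority vote over their segments.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.tree import DecisionTreeClassifier

from .rr_core import LABEL_POSITIVE, LABEL_NEGATIVE
from .selection import SelectionResult, greedy_forward_select

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreeConfig:
    """Decision-tree hyperparameters: CART, Gini, uniform priors."""

    min_samples_leaf: int = 5
    max_depth: int | None = None
    random_state: int = 0

    def build(self) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion="gini",
            class_weight="balanced",  # uniform priors
            min_samples_leaf=self.min_samples_leaf,
            max_depth=self.max_depth,
            random_state=self.random_state,
        )


@dataclass
class SplitPlan:
    """Patient-grouped split: held-out test patients plus 5 CV folds."""

    test_patients: list[str]
    folds: list[dict[str, list[str]]]  # each {"train": [...], "validation": [...]}
    seed: int

    def validate(self, patients: dict[str, str]) -> None:
        non_test = set(patients) - set(self.test_patients)
        val_union: list[str] = []
        for fold in self.folds:
            tr, va = set(fold["train"]), set(fold["validation"])
            assert not tr & va, "patient in both train and validation"
            assert tr | va == non_test, "fold does not cover all non-test patients"
            assert not (tr | va) & set(self.test_patients), "test patient leaked"
            val_union.extend(fold["validation"])
        assert sorted(val_union) == sorted(non_test), (
            "validation folds are not a partition of the non-test patients"
        )


def make_split_plan(
    patients: list[str], labels: list[str], seed: int, n_folds: int = 5
) -> SplitPlan:
    """Class-balanced test selection plus validation-fold partition.

    At the 52-patient study size this yields 12 test patients and folds
    of 32 train / 8 validation; other cohort sizes scale proportionally
    (test fraction 12/52 per class, rounded, minimum 1).
    """
    by_class: dict[str, list[str]] = {}
    for p, lab in zip(patients, labels):
        by_class.setdefault(lab, []).append(p)
    if len(by_class) != 2 or any(len(v) < 2 for v in by_class.values()):
        raise ValueError("need at least 2 patients in each of 2 classes")

    rng = np.random.default_rng(seed)
    test: list[str] = []
    pools: dict[str, list[str]] = {}
    for lab, members in sorted(by_class.items()):
        members = sorted(members)
        n_test = max(1, round(len(members) * 6 / 26))
        if len(members) - n_test < n_folds:
            raise ValueError(
                f"class {lab!r}: need >= {n_folds + n_test} patients for "
                f"{n_folds} folds plus a test set"
            )
        perm = rng.permutation(len(members))
        test.extend(members[i] for i in perm[:n_test])
        pools[lab] = [members[i] for i in perm[n_test:]]

    folds: list[dict[str, list[str]]] = []
    # class-balanced validation folds: split each class pool into n_folds chunks
    chunks: dict[str, list[list[str]]] = {
        lab: [list(c) for c in np.array_split(pool, n_folds)]
        for lab, pool in pools.items()
    }
    non_test = sorted(p for pool in pools.values() for p in pool)
    for k in range(n_folds):
        val = sorted(p for lab in chunks for p in chunks[lab][k])
        train = sorted(set(non_test) - set(val))
        folds.append({"train": train, "validation": val})

    plan = SplitPlan(test_patients=sorted(test), folds=folds, seed=seed)
    plan.validate(dict(zip(patients, labels)))
    return plan


def _xy(table: pd.DataFrame, features: list[str], mask: np.ndarray):
    sub = table.loc[mask]
    ok = sub[features].notna().all(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("dropping %d segments with undefined features", n_drop)
    sub = sub.loc[ok]
    y = (sub["label"] == LABEL_POSITIVE).to_numpy(dtype=int)
    return sub, sub[features].to_numpy(dtype=float), y


def train_tree(
    table: pd.DataFrame,
    features: list[str],
    mask: np.ndarray | None = None,
    config: TreeConfig = TreeConfig(),
) -> DecisionTreeClassifier:
    """Fit a CART tree with uniform class priors on the masked rows."""
    if mask is None:
        mask = np.ones(len(table), dtype=bool)
    _, x, y = _xy(table, features, mask)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    tree = config.build()
    tree.fit(x, y)
    return tree


def fold_validation_accuracy(
    table: pd.DataFrame,
    features: list[str],
    train_mask: np.ndarray,
    val_mask: np.ndarray,
    config: TreeConfig = TreeConfig(),
) -> float:
    """Segment-weighted validation accuracy of one train/validate split."""
    tree = train_tree(table, features, train_mask, config)
    _, xv, yv = _xy(table, features, val_mask)
    if len(yv) == 0:
        return 0.0
    return float(np.mean(tree.predict(xv) == yv))


@dataclass
class EvalReport:
    """Segment- and patient-level evaluation with AF-HF as positive."""

    tp: int
    fp: int
    tn: int
    fn: int
    per_patient: dict[str, dict]  # id -> {n_segments, acc_pct, true_label, call}
    tie_patients: list[str]

    @property
    def n_segments(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n_segments

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def patient_calls(self) -> dict[str, str]:
        return {p: info["call"] for p, info in self.per_patient.items()}

    @property
    def patient_accuracy(self) -> float:
        ok = [
            info["call"] == info["true_label"] for info in self.per_patient.values()
        ]
        return 100.0 * float(np.mean(ok))

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "per_patient": self.per_patient,
            "patient_accuracy": self.patient_accuracy,
            "tie_patients": self.tie_patients,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def majority_call(n_positive: int, n_total: int) -> str:
    """Patient call from segment votes; an exact 50/50 tie goes to AF-HF
    (screening posture favouring sensitivity)."""
    return LABEL_POSITIVE if 2 * n_positive >= n_total else LABEL_NEGATIVE


def patients_correct_from_accuracies(
    acc_pct: dict[str, tuple[str, float]], threshold: float = 50.0
) -> dict[str, bool]:
    """Apply the majority-vote rule to per-patient segment accuracies.

    A patient whose fraction of correctly classified segments exceeds
    the 50% threshold is called correctly; at exactly the threshold the
    call goes to AF-HF, so an AF-HF patient at 50.0 counts correct and
    a control patient does not.
    """
    out = {}
    for pid, (true_label, acc) in acc_pct.items():
        if acc > threshold:
            out[pid] = True
        elif acc == threshold:
            out[pid] = true_label == LABEL_POSITIVE
        else:
            out[pid] = False
    return out


def evaluate(
    tree: DecisionTreeClassifier,
    table: pd.DataFrame,
    features: list[str],
    mask: np.ndarray | None = None,
) -> EvalReport:
    """Segment confusion counts, clinical metrics, and per-patient
    majority-vote calls for the masked rows."""
    if mask is None:
        mask = np.ones(len(table), dtype=bool)
    sub, x, y = _xy(table, features, mask)
    if len(y) == 0:
        raise ValueError("no segments to evaluate")
    pred = tree.predict(x)

    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    per_patient: dict[str, dict] = {}
    ties: list[str] = []
    pids = sub["patient_id"].to_numpy()
    for pid in pd.unique(pids):
        m = pids == pid
        n_seg = int(m.sum())
        correct = int(np.sum(pred[m] == y[m]))
        n_pos_votes = int(np.sum(pred[m] == 1))
        call = majority_call(n_pos_votes, n_seg)
        if 2 * n_pos_votes == n_seg:
            ties.append(str(pid))
        true_label = LABEL_POSITIVE if y[m][0] == 1 else LABEL_NEGATIVE
        per_patient[str(pid)] = {
            "n_segments": n_seg,
            "acc_pct": 100.0 * correct / n_seg,
            "true_label": true_label,
            "call": call,
        }
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, per_patient=per_patient,
                      tie_patients=ties)


def wilcoxon_feature_test(
    table: pd.DataFrame, feature: str, direction: str = "less"
) -> tuple[float, bool]:
    """One-tailed Wilcoxon rank-sum p-value for a feature's class shift.

    ``direction='less'`` tests whether the AF-HF distribution is
    stochastically lower (the direction of the spectral-entropy
    finding).  Returns (p, degenerate_flag); fully tied data yield
    p = 0.5 with the flag set.
    """
    pos = table.loc[table["label"] == LABEL_POSITIVE, feature].dropna()
    neg = table.loc[table["label"] == LABEL_NEGATIVE, feature].dropna()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be represented")
    if pos.nunique() == 1 and neg.nunique() == 1 and pos.iloc[0] == neg.iloc[0]:
        return 0.5, True
    _, p = mannwhitneyu(pos, neg, alternative=direction)
    return float(p), False


def _masks_for(table: pd.DataFrame, patient_sets: dict[str, list[str]]):
    pid = table["patient_id"]
    return {name: pid.isin(pats).to_numpy() for name, pats in patient_sets.items()}


@dataclass
class ExperimentResult:
    selection: SelectionResult
    tree: DecisionTreeClassifier
    report: EvalReport
    single_feature_accuracies: dict[str, float]
    plan: SplitPlan
    test_hash: str


def test_set_hash(table: pd.DataFrame, test_mask: np.ndarray) -> str:
    sub = table.loc[test_mask]
    seg = sub["segment_idx"] if "segment_idx" in sub.columns else sub.index
    ids = sorted(f"{p}:{s}" for p, s in zip(sub["patient_id"], seg))
    return hashlib.sha256("|".join(ids).encode()).hexdigest()


def run_experiment(
    table: pd.DataFrame,
    features: list[str],
    split_seed: int = 0,
    gate: float = 0.6,
    tree_config: TreeConfig = TreeConfig(),
    single_feature_baselines: bool = True,
    plan: SplitPlan | None = None,
) -> ExperimentResult:
    """Full protocol on a segment feature table of one circadian window.

    Builds the patient-grouped split, runs correlation-gated greedy
    selection on the folds, retrains the final tree on all non-test
    patients, and evaluates exactly once on the held-out test set.  The
    test-segment id hash is taken before selection and re-checked right
    before the single final evaluation.  Single-feature baselines reuse
    the same split and retraining protocol.
    """
    pat_label = table.groupby("patient_id", sort=True)["label"].first()
    if plan is None:
        plan = make_split_plan(
            list(pat_label.index), list(pat_label.values), seed=split_seed
        )

    pid = table["patient_id"]
    test_mask = pid.isin(plan.test_patients).to_numpy()
    hash_before = test_set_hash(table, test_mask)

    folds = [
        (
            pid.isin(fold["train"]).to_numpy(),
            pid.isin(fold["validation"]).to_numpy(),
        )
        for fold in plan.folds
    ]

    selection = greedy_forward_select(
        table.loc[~test_mask].reset_index(drop=True),
        features,
        [(tr[~test_mask], va[~test_mask]) for tr, va in folds],
        lambda tbl, feats, tr, va: fold_validation_accuracy(
            tbl, feats, tr, va, tree_config
        ),
        gate=gate,
    )
    if not selection.selected:
        raise ValueError("selection returned an empty feature set")

    # final model: retrain on train+validation (all non-test patients)
    tree = train_tree(table, selection.selected, ~test_mask, tree_config)

    assert test_set_hash(table, test_mask) == hash_before, (
        "test set was modified during selection/training"
    )
    report = evaluate(tree, table, selection.selected, test_mask)

    singles: dict[str, float] = {}
    if single_feature_baselines:
        for f in features:
            try:
                t1 = train_tree(table, [f], ~test_mask, tree_config)
                singles[f] = evaluate(t1, table, [f], test_mask).accuracy
            except ValueError:
                singles[f] = float("nan")

    return ExperimentResult(
        selection=selection,
        tree=tree,
        report=report,
        single_feature_accuracies=singles,
        plan=plan,
        test_hash=hash_before,
    )
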