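"""Split plans, tree training, evaluation metrics, majority voting,
rank-sum feature tests."""

import numpy as np
import pandas as pd
import pytest

from afhf.classify import (
    EvalReport,
    TreeConfig,
    evaluate,
    make_split_plan,
    majority_call,
    patients_correct_from_accuracies,
    run_experiment,
    train_tree,
    wilcoxon_feature_test,
)
from afhf.cohort import synthetic_feature_table
from afhf.rr_core import LABEL_NEGATIVE, LABEL_POSITIVE
from oracles import confusion_recount, ranksum_exact_p


def _patients(n_per_class):
    pats = [f"h{i}" for i in range(n_per_class)] + [
        f"c{i}" for i in range(n_per_class)
    ]
    labs = [LABEL_POSITIVE] * n_per_class + [LABEL_NEGATIVE] * n_per_class
    return pats, labs


class TestSplitPlan:
    def test_study_size_gives_32_8_12(self):
        pats, labs = _patients(26)
        plan = make_split_plan(pats, labs, seed=0)
        assert len(plan.test_patients) == 12
        for fold in plan.folds:
            assert len(fold["train"]) == 32
            assert len(fold["validation"]) == 8

    def test_class_balance_everywhere(self):
        pats, labs = _patients(26)
        lab_of = dict(zip(pats, labs))
        plan = make_split_plan(pats, labs, seed=1)
        count = lambda ps: sum(lab_of[p] == LABEL_POSITIVE for p in ps)
        assert count(plan.test_patients) == 6
        for fold in plan.folds:
            assert count(fold["validation"]) == 4
            assert count(fold["train"]) == 16

    def test_same_seed_identical(self):
        pats, labs = _patients(26)
        assert make_split_plan(pats, labs, 7) == make_split_plan(pats, labs, 7)

    def test_validation_folds_partition_non_test(self):
        pats, labs = _patients(26)
        plan = make_split_plan(pats, labs, seed=2)
        non_test = set(pats) - set(plan.test_patients)
        val_union = [p for f in plan.folds for p in f["validation"]]
        assert sorted(val_union) == sorted(non_test)  # each exactly once
        for fold in plan.folds:
            assert set(fold["train"]).isdisjoint(fold["validation"])
            assert set(fold["train"]) | set(fold["validation"]) == non_test

    def test_too_small_cohort_raises(self):
        pats, labs = _patients(4)
        with pytest.raises(ValueError, match="folds"):
            make_split_plan(pats, labs, seed=0)


def _toy_table(n=60, seed=0, sep=3.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    return pd.DataFrame(
        {
            "patient_id": [f"p{i % 10}" for i in range(n)],
            "segment_idx": np.arange(n),
            "label": [LABEL_POSITIVE] * half + [LABEL_NEGATIVE] * (n - half),
            "x": np.concatenate(
                [rng.standard_normal(half) + sep, rng.standard_normal(n - half)]
            ),
        }
    )


class TestTrainTree:
    def test_separable_feature_classifies_perfectly(self):
        tbl = _toy_table(sep=10.0)
        tree = train_tree(tbl, ["x"], config=TreeConfig(min_samples_leaf=1))
        rep = evaluate(tree, tbl, ["x"])
        assert rep.accuracy == 100.0

    def test_single_class_raises(self):
        tbl = _toy_table()
        tbl["label"] = LABEL_POSITIVE
        with pytest.raises(ValueError):
            train_tree(tbl, ["x"])

    def test_balanced_duplication_invariance(self):
        tbl = _toy_table(sep=2.0)
        doubled = pd.concat([tbl, tbl], ignore_index=True)
        t1 = train_tree(tbl, ["x"])
        t2 = train_tree(doubled, ["x"], config=TreeConfig(min_samples_leaf=10))
        x = np.linspace(-3, 6, 50).reshape(-1, 1)
        assert np.array_equal(t1.predict(x), t2.predict(x))

    def test_uniform_priors_help_minority_sensitivity(self):
        # 90/10 imbalance with overlapping classes: inverse-frequency
        # weighting must raise minority-class (positive) sensitivity
        # relative to frequency priors, on average over seeds
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_pos, n_neg = 30, 270
            tbl = pd.DataFrame(
                {
                    "patient_id": "p",
                    "label": [LABEL_POSITIVE] * n_pos + [LABEL_NEGATIVE] * n_neg,
                    "x": np.concatenate(
                        [rng.standard_normal(n_pos) + 1.0, rng.standard_normal(n_neg)]
                    ),
                }
            )
            y = (tbl["label"] == LABEL_POSITIVE).to_numpy(int)
            x = tbl[["x"]].to_numpy()
            from sklearn.tree import DecisionTreeClassifier

            uniform = DecisionTreeClassifier(
                class_weight="balanced", min_samples_leaf=20, random_state=0
            ).fit(x, y)
            freq = DecisionTreeClassifier(
                min_samples_leaf=20, random_state=0
            ).fit(x, y)
            rng2 = np.random.default_rng(1000 + seed)
            xt = np.concatenate(
                [rng2.standard_normal(200) + 1.0]
            ).reshape(-1, 1)
            sens_u = uniform.predict(xt).mean()
            sens_f = freq.predict(xt).mean()
            if sens_u > sens_f:
                wins += 1
        assert wins >= 8


class TestEvaluate:
    def test_all_correct_gives_perfect_metrics(self):
        tbl = _toy_table(sep=10.0)
        tree = train_tree(tbl, ["x"], config=TreeConfig(min_samples_leaf=1))
        rep = evaluate(tree, tbl, ["x"])
        assert (
            rep.accuracy,
            rep.sensitivity,
            rep.specificity,
            rep.ppv,
        ) == (100.0, 100.0, 100.0, 100.0)

    def test_metrics_match_recount_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            tp, fp, tn, fn = confusion_recount(y, pred)
            rep = EvalReport(
                tp=tp, fp=fp, tn=tn, fn=fn, per_patient={}, tie_patients=[]
            )
            assert rep.n_segments == n
            if tp + fn:
                assert rep.sensitivity == pytest.approx(100 * tp / (tp + fn))
            if tn + fp:
                assert rep.specificity == pytest.approx(100 * tn / (tn + fp))
            if tp + fp:
                assert rep.ppv == pytest.approx(100 * tp / (tp + fp))
            assert rep.accuracy == pytest.approx(100 * (tp + tn) / n)

    def test_printed_per_patient_accuracies_give_10_of_12(self):
        """The study's worked example: twelve held-out patients with
        published per-patient segment accuracies; the 50% majority rule
        calls 10/12 correctly, missing the two AF-HF patients at 43.80%
        and 17.81%."""
        accs = {
            "1": (LABEL_POSITIVE, 76.19),
            "2": (LABEL_POSITIVE, 56.10),
            "3": (LABEL_POSITIVE, 57.14),
            "4": (LABEL_POSITIVE, 81.43),
            "5": (LABEL_POSITIVE, 43.80),
            "6": (LABEL_POSITIVE, 17.81),
            "7": (LABEL_NEGATIVE, 85.39),
            "8": (LABEL_NEGATIVE, 92.13),
            "9": (LABEL_NEGATIVE, 96.34),
            "10": (LABEL_NEGATIVE, 97.06),
            "11": (LABEL_NEGATIVE, 93.59),
            "12": (LABEL_NEGATIVE, 85.19),
        }
        correct = patients_correct_from_accuracies(accs)
        assert sum(correct.values()) == 10
        assert not correct["5"] and not correct["6"]
        assert all(correct[p] for p in map(str, [1, 2, 3, 4, 7, 8, 9, 10, 11, 12]))

    def test_tie_vote_goes_to_positive(self):
        assert majority_call(5, 10) == LABEL_POSITIVE
        assert majority_call(4, 10) == LABEL_NEGATIVE
        accs = {"a": (LABEL_POSITIVE, 50.0), "b": (LABEL_NEGATIVE, 50.0)}
        correct = patients_correct_from_accuracies(accs)
        assert correct["a"] and not correct["b"]

    def test_majority_vote_amplifies_segment_accuracy(self):
        # iid Bernoulli(p > 0.5) per-segment correctness: patient-level
        # majority accuracy must exceed segment-level accuracy
        rng = np.random.default_rng(3)
        p = 0.65
        n_pat, n_seg = 200, 41
        correct = rng.random((n_pat, n_seg)) < p
        seg_acc = correct.mean()
        pat_acc = (correct.mean(axis=1) > 0.5).mean()
        assert pat_acc > seg_acc


class TestWilcoxon:
    def test_identical_distributions_near_half(self, small_cohort_table):
        tbl = small_cohort_table.copy()
        rng = np.random.default_rng(0)
        tbl["noise"] = rng.standard_normal(len(tbl))
        p, flag = wilcoxon_feature_test(tbl, "noise")
        assert 0.05 < p < 0.95
        assert not flag

    def test_fully_tied_data_degenerate(self):
        tbl = pd.DataFrame(
            {
                "label": [LABEL_POSITIVE] * 5 + [LABEL_NEGATIVE] * 5,
                "f": [3.0] * 10,
            }
        )
        p, flag = wilcoxon_feature_test(tbl, "f")
        assert p == 0.5 and flag

    def test_complete_separation_extreme_p(self):
        rng = np.random.default_rng(1)
        tbl = pd.DataFrame(
            {
                "label": [LABEL_POSITIVE] * 20 + [LABEL_NEGATIVE] * 20,
                "f": np.concatenate(
                    [rng.uniform(0, 1, 20), rng.uniform(5, 6, 20)]
                ),
            }
        )
        p, _ = wilcoxon_feature_test(tbl, "f", direction="less")
        assert p < 1e-6

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for n1, n2 in [(4, 5), (6, 6), (8, 7)]:
            pos = rng.standard_normal(n1) - 0.5
            neg = rng.standard_normal(n2)
            tbl = pd.DataFrame(
                {
                    "label": [LABEL_POSITIVE] * n1 + [LABEL_NEGATIVE] * n2,
                    "f": np.concatenate([pos, neg]),
                }
            )
            p, _ = wilcoxon_feature_test(tbl, "f", direction="less")
            assert p == pytest.approx(ranksum_exact_p(pos, neg), rel=1e-9)


class TestRunExperiment:
    def test_strong_effect_beats_single_features(self, small_cohort_table):
        from afhf.features import FEATURE_NAMES

        res = run_experiment(
            small_cohort_table.reset_index(drop=True),
            list(FEATURE_NAMES),
            split_seed=0,
        )
        best_single = np.nanmax(list(res.single_feature_accuracies.values()))
        assert res.report.accuracy >= best_single - 2.0
        assert res.report.patient_accuracy >= 80.0

    def test_no_leakage_hash_unchanged(self, small_cohort_table):
        from afhf.features import FEATURE_NAMES
        from afhf.classify import test_set_hash

        tbl = small_cohort_table.reset_index(drop=True)
        res = run_experiment(tbl, list(FEATURE_NAMES), split_seed=1,
                             single_feature_baselines=False)
        mask = tbl["patient_id"].isin(res.plan.test_patients).to_numpy()
        assert test_set_hash(tbl, mask) == res.test_hash
        # no test patient appears in any fold
        for fold in res.plan.folds:
            assert not set(fold["train"]) & set(res.plan.test_patients)
            assert not set(fold["validation"]) & set(res.plan.test_patients)
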