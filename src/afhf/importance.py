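"""Exact Shapley feature importance of a fitted decision tree.

The explained quantity is the tree's positive-class (AF-HF)
probability.  For an explicand x and a background sample Z, the value
of a feature coalition S is the interventional expectation

    v(S) = mean_z f(x_S, z_{S-bar})

i.e. the tree evaluated with the coalition's features taken from x and
the rest from each background row.  Shapley values are computed exactly
by enumerating all coalitions of the features the tree actually splits
on (features the tree never uses receive exactly zero), which is cheap
because selected feature sets are small.  Randomness is confined to the
per-run data subsample, so the reported SD measures sampling
variability, not estimator noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier


@dataclass
class ImportanceReport:
    """Mean |Shapley value| per feature with resampling SD."""

    features: list[str]  # ordered by importance, descending
    mean_importance: dict[str, float]
    sd_importance: dict[str, float]
    n_runs: int
    n_samples: int
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "features": self.features,
                    "mean_importance": self.mean_importance,
                    "sd_importance": self.sd_importance,
                    "n_runs": self.n_runs,
                    "n_samples": self.n_samples,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "mean_importance": [self.mean_importance[f] for f in self.features],
                "sd_importance": [self.sd_importance[f] for f in self.features],
            }
        )


def _positive_score(tree: DecisionTreeClassifier, x: np.ndarray) -> np.ndarray:
    return tree.predict_proba(x)[:, list(tree.classes_).index(1)]


def tree_shapley_values(
    tree: DecisionTreeClassifier,
    explicands: np.ndarray,
    background: np.ndarray,
) -> np.ndarray:
    """Exact interventional Shapley values, one row per explicand.

    Enumerates every coalition of the features used by the tree; v(S)
    is averaged over the background sample.  Unused features get 0.
    Satisfies local accuracy: the values of one explicand sum to its
    positive-class score minus the background mean score.
    """
    explicands = np.asarray(explicands, dtype=float)
    background = np.asarray(background, dtype=float)
    n_e, d = explicands.shape
    n_b = background.shape[0]

    used = sorted(set(tree.tree_.feature[tree.tree_.feature >= 0]))
    k = len(used)
    phi = np.zeros((n_e, d))
    if k == 0:
        return phi

    # v(S) for every coalition S of used features, every explicand
    coalitions: list[tuple[int, ...]] = []
    for size in range(k + 1):
        coalitions.extend(combinations(range(k), size))
    v = {}
    for S in coalitions:
        hybrid = np.repeat(background[None, :, :], n_e, axis=0)  # (n_e, n_b, d)
        for j in S:
            hybrid[:, :, used[j]] = explicands[:, None, used[j]]
        scores = _positive_score(tree, hybrid.reshape(n_e * n_b, d))
        v[S] = scores.reshape(n_e, n_b).mean(axis=1)

    fact_w = {s: 1.0 / (k * comb(k - 1, s)) for s in range(k)}
    for j in range(k):
        acc = np.zeros(n_e)
        for S in coalitions:
            if j in S:
                continue
            S_with = tuple(sorted(S + (j,)))
            acc += fact_w[len(S)] * (v[S_with] - v[S])
        phi[:, used[j]] = acc
    return phi


def shapley_importance(
    tree: DecisionTreeClassifier,
    table: pd.DataFrame,
    features: list[str],
    n_runs: int = 1000,
    n_samples: int = 100,
    seed: int = 0,
    replace: bool = True,
) -> ImportanceReport:
    """Resampled Shapley importance: per run, draw ``n_samples`` segments
    (with replacement) as both explicand and background set, compute
    exact Shapley values, and take the mean |value| per feature; report
    mean and SD over ``n_runs`` runs."""
    x_all = table[features].dropna().to_numpy(dtype=float)
    if len(x_all) == 0:
        raise ValueError("no complete segments to explain")
    if not replace and n_samples > len(x_all):
        raise ValueError("n_samples exceeds dataset size with replacement off")
    rng = np.random.default_rng(seed)
    per_run = np.empty((n_runs, len(features)))
    for r in range(n_runs):
        idx = (
            rng.choice(len(x_all), size=n_samples, replace=True)
            if replace
            else rng.choice(len(x_all), size=n_samples, replace=False)
        )
        sample = x_all[idx]
        phi = tree_shapley_values(tree, sample, sample)
        per_run[r] = np.abs(phi).mean(axis=0)

    mean = per_run.mean(axis=0)
    sd = per_run.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(len(features))
    order = np.argsort(-mean, kind="stable")
    ordered = [features[i] for i in order]
    return ImportanceReport(
        features=ordered,
        mean_importance={f: float(mean[i]) for i, f in zip(order, ordered)},
        sd_importance={f: float(sd[i]) for i, f in zip(order, ordered)},
        n_runs=n_runs,
        n_samples=n_samples,
        seed=seed,
    )
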