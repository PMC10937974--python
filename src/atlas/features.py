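"""Gene filtering, importance ranking, and the feature-count selection rule.

Training genes are filtered by completeness and median expression (drop any
gene with a missing value, then the lowest-decile medians). A fitted
ensemble ranks the surviving features by total split gain; models are then
retrained on the top-k features over a grid of k, and the final feature
count is the smallest k whose mean CV accuracy falls within the 95%
confidence interval of the best k's accuracy — the plateau rule that fixed
500 site / 200 lineage features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import t as student_t
from sklearn.model_selection import StratifiedKFold

from .classify import SEX_FEATURE, _argmax_call, _predict_probs, _sanitize, fit_multiclass

__all__ = [
    "FeatureCurve",
    "filter_genes",
    "rank_features",
    "build_feature_curve",
    "select_feature_count",
]

LOW_MEDIAN_FRACTION = 0.10


def filter_genes(matrix: pd.DataFrame, fraction: float = LOW_MEDIAN_FRACTION) -> list[str]:
    """Retained gene ids after the completeness and low-median filters.

    Drops genes with any missing value; of the G remaining, drops the
    floor(fraction * G) genes with the lowest median expression across
    samples, ties broken lexicographically by gene id (the lexicographically
    smallest tied gene is dropped first). Deterministic in the matrix.
    """
    if matrix.empty:
        raise ValueError("empty expression matrix")
    complete = matrix.dropna(axis=0)
    medians = complete.median(axis=1)
    n_drop = int(np.floor(fraction * len(complete)))
    order = sorted(complete.index, key=lambda g: (medians[g], g))
    dropped = set(order[:n_drop])
    return [g for g in complete.index if g not in dropped]


def rank_features(booster: xgb.Booster, feature_names: list[str]) -> pd.DataFrame:
    """Features ordered most-to-least important by total split gain.

    Features never used in any split get importance exactly 0 and rank
    after all used features; ties break by feature id.
    """
    try:
        gain = booster.get_score(importance_type="total_gain")
    except Exception as exc:  # unfitted booster has no trees
        raise ValueError(f"cannot rank features of an unfitted model: {exc}") from exc
    importance = {f: float(gain.get(_sanitize(f), 0.0)) for f in feature_names}
    if len(importance) != len(feature_names):
        raise ValueError("duplicate feature names")
    ordered = sorted(feature_names, key=lambda f: (-importance[f], f))
    return pd.DataFrame(
        {"feature": ordered, "importance": [importance[f] for f in ordered]}
    )


@dataclass
class FeatureCurve:
    """Per feature-count k: the 5 fold CV accuracies and their mean."""

    fold_accuracies: pd.DataFrame  # index = k (increasing), columns = folds

    def __post_init__(self) -> None:
        k = self.fold_accuracies.index
        if not (np.diff(k) > 0).all():
            raise ValueError("k values must be strictly increasing")
        vals = self.fold_accuracies.to_numpy(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def means(self) -> pd.Series:
        return self.fold_accuracies.mean(axis=1)


def build_feature_curve(
    ranked: pd.DataFrame,
    X: pd.DataFrame,
    labels,
    k_grid,
    n_trees: int,
    cv_seed: int = 0,
) -> FeatureCurve:
    """Retrain on the top-k ranked features for every k in the grid.

    The same 5-fold stratified partition and the frozen tree count are
    reused across the whole sweep, so the curve varies only with k. The sex
    flag, when ranked, always counts toward k like any other feature.
    """
    ranked_feats = list(ranked["feature"])
    k_grid = sorted(set(int(k) for k in k_grid))
    if k_grid[-1] > len(ranked_feats) or k_grid[0] < 1:
        raise ValueError("k grid outside [1, number of ranked features]")
    labels = np.asarray(list(labels))
    classes = sorted(pd.unique(labels))
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=cv_seed)
    folds = list(skf.split(X, labels))
    table = pd.DataFrame(index=k_grid, columns=[f"fold{i}" for i in range(5)],
                         dtype=float)
    for k in k_grid:
        feats = ranked_feats[:k]
        for i, (tr, te) in enumerate(folds):
            booster = fit_multiclass(
                X.iloc[tr][feats], labels[tr], classes, n_trees, seed=cv_seed
            )
            probs = _predict_probs(booster, X.iloc[te][feats], classes)
            calls = probs.apply(_argmax_call, axis=1)
            table.loc[k, f"fold{i}"] = float((calls == labels[te]).mean())
    return FeatureCurve(fold_accuracies=table)


def select_feature_count(curve: FeatureCurve) -> int:
    """Smallest k whose mean accuracy falls within the best k's 95% CI.

    The best k maximizes mean CV accuracy; its CI is
    mean +/- t(0.975, df = folds-1) * sd / sqrt(folds) over the fold
    accuracies, and the chosen k is the smallest whose mean is at or above
    that interval's lower bound.
    """
    table = curve.fold_accuracies
    n_folds = table.shape[1]
    if n_folds < 2:
        raise ValueError("need >= 2 folds to form a confidence interval")
    means = curve.means
    best_k = means.index[int(np.argmax(means.to_numpy()))]
    best_folds = table.loc[best_k].to_numpy(float)
    sd = best_folds.std(ddof=1)
    lower = means[best_k] - student_t.ppf(0.975, df=n_folds - 1) * sd / np.sqrt(n_folds)
    eligible = means.index[means.to_numpy() >= lower]
    return int(eligible[0])
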