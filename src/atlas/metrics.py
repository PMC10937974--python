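"""Multiclass evaluation: accuracy, confusion, one-vs-all macro
sensitivity/specificity, Hand-Till multiclass AUC, binary rank AUC, and
confidence-stratified accuracy.

Macro averages and Hand-Till pairs are computed over classes actually
present in the truth labels; rank ties use the midrank convention
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "EvalReport",
    "confusion_and_accuracy",
    "macro_ova_sens_spec",
    "hand_till_auc",
    "binary_auc",
    "confidence_stratified_accuracy",
]


@dataclass
class EvalReport:
    accuracy: float
    confusion: pd.DataFrame
    per_class_sensitivity: dict[str, float] = field(default_factory=dict)
    per_class_specificity: dict[str, float] = field(default_factory=dict)
    macro_sensitivity: float = float("nan")
    macro_specificity: float = float("nan")
    auc: float = float("nan")
    strata: dict = field(default_factory=dict)


def confusion_and_accuracy(calls, truths, vocabulary) -> EvalReport:
    """Class x class count matrix (rows = truth) and overall accuracy."""
    calls = list(calls)
    truths = list(truths)
    if len(calls) != len(truths):
        raise ValueError("calls and truths differ in length")
    if not calls:
        raise ValueError("empty input")
    vocab = list(vocabulary)
    bad = sorted({x for x in calls + truths if x not in vocab})
    if bad:
        raise ValueError(f"labels outside vocabulary: {bad}")
    conf = pd.DataFrame(0, index=vocab, columns=vocab, dtype=int)
    for t, c in zip(truths, calls):
        conf.loc[t, c] += 1
    acc = float(np.trace(conf.to_numpy()) / len(truths))
    return EvalReport(accuracy=acc, confusion=conf)


def macro_ova_sens_spec(confusion: pd.DataFrame) -> EvalReport:
    """One-vs-all sensitivity/specificity per class, macro-averaged.

    Classes with zero truth samples are excluded from the macro means.
    """
    mat = confusion.to_numpy(float)
    if mat.sum() == 0:
        raise ValueError("all-zero confusion matrix")
    total = mat.sum()
    sens: dict[str, float] = {}
    spec: dict[str, float] = {}
    for i, cls in enumerate(confusion.index):
        tp = mat[i, i]
        fn = mat[i, :].sum() - tp
        fp = mat[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn > 0:
            sens[cls] = tp / (tp + fn)
        spec[cls] = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    present = list(sens)
    rep = EvalReport(
        accuracy=float(np.trace(mat) / total),
        confusion=confusion,
        per_class_sensitivity=sens,
        per_class_specificity={c: spec[c] for c in confusion.index},
        macro_sensitivity=float(np.mean([sens[c] for c in present])),
        macro_specificity=float(np.mean([spec[c] for c in present])),
    )
    return rep


def _pairwise_auc(scores_i: np.ndarray, scores_j: np.ndarray) -> float:
    """P(random i-sample scores higher than random j-sample), ties 1/2."""
    pooled = np.concatenate([scores_i, scores_j])
    ranks = rankdata(pooled)
    n_i, n_j = len(scores_i), len(scores_j)
    r_i = ranks[:n_i].sum()
    return (r_i - n_i * (n_i + 1) / 2.0) / (n_i * n_j)


def hand_till_auc(probs: pd.DataFrame, truths) -> float:
    """Hand & Till M statistic: mean of all pairwise one-vs-one rank AUCs.

    For each unordered class pair (i, j), A_hat(i|j) ranks class-i against
    class-j samples on the P(i) column; the pair's value is the average of
    A_hat(i|j) and A_hat(j|i), and M averages over all pairs of classes
    present in the truth labels.
    """
    truths = np.asarray(list(truths))
    present = sorted(pd.unique(truths))
    if len(present) < 2:
        raise ValueError("need >= 2 truth classes for multiclass AUC")
    missing = [c for c in present if c not in probs.columns]
    if missing:
        raise ValueError(f"probability columns missing for classes: {missing}")
    terms = []
    for a_idx in range(len(present)):
        for b_idx in range(a_idx + 1, len(present)):
            a, b = present[a_idx], present[b_idx]
            mask_a = truths == a
            mask_b = truths == b
            a_given_b = _pairwise_auc(
                probs.loc[mask_a, a].to_numpy(), probs.loc[mask_b, a].to_numpy()
            )
            b_given_a = _pairwise_auc(
                probs.loc[mask_b, b].to_numpy(), probs.loc[mask_a, b].to_numpy()
            )
            terms.append(0.5 * (a_given_b + b_given_a))
    return float(np.mean(terms))


def binary_auc(scores, labels) -> float:
    """Mann-Whitney rank AUC of ``scores`` for the positive class, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return float(_pairwise_auc(scores[labels], scores[~labels]))


def confidence_stratified_accuracy(
    calls, truths, confidences, threshold: float = 0.99
) -> dict[str, dict[str, float | None]]:
    """Accuracy and coverage above / below a confidence threshold.

    An empty stratum reports accuracy ``None`` (undefined), never 0.
    """
    calls = np.asarray(list(calls))
    truths = np.asarray(list(truths))
    conf = np.asarray(confidences, float)
    if not (len(calls) == len(truths) == len(conf)):
        raise ValueError("inputs differ in length")
    n = len(calls)
    out = {}
    for name, mask in (("high", conf >= threshold), ("low", conf < threshold)):
        cov = float(mask.sum() / n)
        acc = float((calls[mask] == truths[mask]).mean()) if mask.any() else None
        out[name] = {"coverage": cov, "accuracy": acc, "n": int(mask.sum())}
    return out
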