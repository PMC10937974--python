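"""Scores derived from the lineage probability vector.

The differentiation score is the maximum of a sample's lineage
probabilities: a confidently single-lineage tumor scores near 1, while a
de-differentiated/anaplastic tumor spreads probability across lineages and
scores low. The adenocarcinoma-SCC delta and single named lineage scores
support subtype discrimination, including zero-shot scoring of tumor types
absent from training; the ROC optimal cut turns a continuous score into two
groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RocCut",
    "differentiation_score",
    "adeno_scc_delta",
    "lineage_score",
    "optimal_roc_cut",
]

ADENO = "Adenocarcinoma"
SCC = "Squamous Cell Carcinoma"


@dataclass(frozen=True)
class RocCut:
    """Threshold minimizing the distance from the ROC curve to (1, 1)."""

    threshold: float
    sensitivity: float
    specificity: float
    distance: float


def _as_probs(lineage_probs) -> pd.Series:
    probs = pd.Series(lineage_probs, dtype=float)
    if probs.empty:
        raise ValueError("empty probability vector")
    return probs


def differentiation_score(lineage_probs) -> float:
    """Maximum lineage probability; low values mean de-differentiation."""
    return float(_as_probs(lineage_probs).max())


def adeno_scc_delta(lineage_probs) -> float:
    """P(adenocarcinoma) - P(squamous cell carcinoma), in [-1, 1]."""
    probs = _as_probs(lineage_probs)
    for cls in (ADENO, SCC):
        if cls not in probs.index:
            raise ValueError(f"class {cls!r} missing from the lineage vocabulary")
    return float(probs[ADENO] - probs[SCC])


def lineage_score(lineage_probs, cls: str) -> float:
    """A single named lineage probability (e.g. the sarcoma score)."""
    probs = _as_probs(lineage_probs)
    if cls not in probs.index:
        raise ValueError(f"unknown lineage class {cls!r}")
    return float(probs[cls])


def optimal_roc_cut(scores, labels) -> RocCut:
    """Cut a continuous score at the ROC point nearest (sens=1, spec=1).

    Candidate thresholds sit midway between consecutive distinct sorted
    scores, plus -inf and +inf; the high group is score >= threshold and is
    predicted positive. Distance ties resolve toward higher specificity,
    then lower threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both label classes must be present")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("need >= 2 distinct scores")
    thresholds = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best: RocCut | None = None
    for thr in thresholds:
        high = scores >= thr
        sens = (high & labels).sum() / n_pos
        spec = (~high & ~labels).sum() / n_neg
        dist = float(np.hypot(1.0 - sens, 1.0 - spec))
        cand = RocCut(float(thr), float(sens), float(spec), dist)
        if (
            best is None
            or cand.distance < best.distance - 1e-12
            or (
                abs(cand.distance - best.distance) <= 1e-12
                and (cand.specificity, -cand.threshold)
                > (best.specificity, -best.threshold)
            )
        ):
            best = cand
    assert best is not None
    return best
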