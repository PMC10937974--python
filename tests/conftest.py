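"""Shared fixtures.

The "standard cohort" is the fully-crossed 12-site x 4-lineage design
(100 samples/cell for training, 30/cell held out, marker effect 2.0
nat-log, noise sd 1.0) that the parameter-recovery and robustness
experiments run on; it is expensive, so it and the models trained on it are
session-scoped. Small cohorts serve the per-module tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from atlas import classify, normalize, synth

STANDARD_SEED = 7
STANDARD_TEST_SEED = 1234


@pytest.fixture(scope="session")
def standard_cohort():
    cfg = synth.standard_cohort_config(n_per_cell=100, seed=STANDARD_SEED)
    expr, annot = synth.generate_cohort(cfg)
    test_cfg = synth.standard_cohort_config(n_per_cell=30, seed=STANDARD_SEED)
    test_expr, test_annot = synth.generate_cohort(test_cfg, seed=STANDARD_TEST_SEED)
    return cfg, expr, annot, test_expr, test_annot


@pytest.fixture(scope="session")
def standard_normalized(standard_cohort):
    _, expr, _, test_expr, _ = standard_cohort
    norm, _ = normalize.normalize_matrix(expr)
    test_norm, _ = normalize.normalize_matrix(test_expr)
    return norm, test_norm


@pytest.fixture(scope="session")
def standard_model(standard_cohort, standard_normalized):
    _, _, annot, _, _ = standard_cohort
    norm, _ = standard_normalized
    return classify.train_atlas(
        norm, annot,
        classify.TrainConfig(site_trees=60, lineage_trees=60, seed=STANDARD_SEED),
    )


@pytest.fixture(scope="session")
def raw_model(standard_cohort):
    """Same design trained on raw expression: the no-normalization arm."""
    _, expr, annot, _, _ = standard_cohort
    return classify.train_atlas(
        expr, annot,
        classify.TrainConfig(site_trees=60, lineage_trees=60, seed=STANDARD_SEED),
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synth.standard_cohort_config(
        n_per_cell=20, seed=5, n_sites=3, n_lineages=2, n_genes=80
    )
    expr, annot = synth.generate_cohort(cfg)
    return cfg, expr, annot


@pytest.fixture(scope="session")
def small_model(small_cohort):
    cfg, expr, annot = small_cohort
    norm, _ = normalize.normalize_matrix(expr)
    model = classify.train_atlas(
        norm, annot, classify.TrainConfig(site_trees=25, lineage_trees=25, seed=5)
    )
    return model, norm, annot
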