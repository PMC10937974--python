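"""Twin-model training, kNN imputation against a brute-force oracle,
prediction contracts, axis independence, and per-class attribution."""

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from atlas import classify, normalize, synth


def brute_force_impute(sample: pd.Series, reference: pd.DataFrame, k=5) -> pd.Series:
    """Independent oracle: explicit loops over references and features."""
    x = sample.reindex(reference.columns)
    observed = [c for c in reference.columns if not np.isnan(x[c])]
    dists = []
    for rid in reference.index:
        sq = [(x[c] - reference.loc[rid, c]) ** 2 for c in observed]
        dists.append((np.sqrt(sum(sq) / len(sq)), str(rid), rid))
    dists.sort(key=lambda t: (t[0], t[1]))
    nearest = [t[2] for t in dists[:k]]
    out = x.copy()
    for c in reference.columns:
        if np.isnan(x[c]):
            out[c] = reference.loc[nearest, c].mean()
    return out


class TestTuneTreeCount:
    def test_separable_toy_ties_to_smallest(self):
        rng = np.random.default_rng(0)
        y = np.array(["a", "b"])[rng.integers(0, 2, 60)]
        X = pd.DataFrame({"g0": (y == "a") * 10.0,
                          "g1": rng.normal(0, 1, 60)})
        best, table = classify.tune_tree_count(X, y, tree_grid=[5, 10, 20], cv_seed=1)
        assert (table.mean(axis=1) == 1.0).all()
        assert best == 5

    def test_length_one_grid(self):
        rng = np.random.default_rng(1)
        y = np.array(["a", "b"])[rng.integers(0, 2, 40)]
        X = pd.DataFrame(rng.normal(0, 1, (40, 3)))
        best, _ = classify.tune_tree_count(X, y, tree_grid=[7], cv_seed=1)
        assert best == 7

    def test_small_class_rejected(self):
        y = ["a"] * 30 + ["b"] * 3
        X = pd.DataFrame(np.random.default_rng(2).normal(0, 1, (33, 3)))
        with pytest.raises(ValueError, match="stratification"):
            classify.tune_tree_count(X, y, cv_seed=1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify.tune_tree_count(pd.DataFrame({"g": [1.0] * 10}),
                                     ["a"] * 5 + ["b"] * 5, tree_grid=[])


class TestImputeMissing:
    @pytest.fixture(scope="class")
    def panel(self):
        # 8-reference fixture, printed values
        data = {
            "f1": [0.1, 0.9, 0.5, -0.3, 1.2, 0.0, 0.4, -1.0],
            "f2": [1.0, 1.1, -0.2, 0.8, 0.3, -0.9, 0.6, 0.2],
            "f3": [-0.5, 0.2, 0.7, 1.5, -1.1, 0.4, 0.0, 0.9],
            "f4": [0.3, -0.7, 1.0, 0.1, 0.5, 1.3, -0.4, 0.6],
        }
        extra = {f"f{i}": np.linspace(-1, 1, 8) * (0.1 * i) for i in range(5, 13)}
        return pd.DataFrame({**data, **extra},
                            index=[f"R{i}" for i in range(8)])

    def test_matches_brute_force_oracle(self, panel):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = pd.Series(rng.normal(0, 1, panel.shape[1]), index=panel.columns)
            x.iloc[rng.choice(panel.shape[1], 2, replace=False)] = np.nan
            got = classify.impute_missing(x, panel, k=5)
            want = brute_force_impute(x, panel, k=5)
            pd.testing.assert_series_equal(got, want, check_names=False)

    def test_unanimous_neighbors(self):
        ref = pd.DataFrame(
            {"a": np.arange(10.0), "b": np.arange(10.0) * 2,
             **{f"p{i}": np.random.default_rng(i).normal(0, 1, 10)
                for i in range(10)},
             "target": [7.0] * 10},
        )
        x = ref.iloc[0].copy()
        x["target"] = np.nan
        got = classify.impute_missing(x, ref, k=5)
        assert got["target"] == 7.0

    def test_no_missing_returned_unchanged(self):
        ref = pd.DataFrame(np.random.default_rng(4).normal(0, 1, (6, 12)),
                           columns=[f"f{i}" for i in range(12)])
        x = pd.Series(np.arange(12.0), index=ref.columns)
        pd.testing.assert_series_equal(
            classify.impute_missing(x, ref, k=5), x, check_names=False
        )

    def test_too_few_references_rejected(self, panel):
        x = pd.Series(np.nan, index=panel.columns)
        x.iloc[:10] = 0.5
        with pytest.raises(ValueError, match="< k"):
            classify.impute_missing(x, panel.iloc[:3], k=5)

    def test_insufficient_overlap_rejected(self, panel):
        x = pd.Series(np.nan, index=panel.columns)
        x.iloc[:3] = 0.5
        with pytest.raises(ValueError, match="non-missing"):
            classify.impute_missing(x, panel, k=5)


class TestTrainPredict:
    def test_probabilities_sum_to_one(self, small_model):
        model, norm, annot = small_model
        preds = classify.predict_matrix(model, norm, sex=annot["sex"])
        site_cols = [c for c in preds.columns if c.startswith("site:")]
        lin_cols = [c for c in preds.columns if c.startswith("lineage:")]
        np.testing.assert_allclose(preds[site_cols].sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(preds[lin_cols].sum(axis=1), 1.0, atol=1e-6)

    def test_training_samples_recovered(self, small_model):
        model, norm, annot = small_model
        preds = classify.predict_matrix(model, norm, sex=annot["sex"])
        assert (preds["site_call"] == annot["site"]).mean() > 0.98
        assert (preds["lineage_call"] == annot["lineage"]).mean() > 0.98

    def test_sample_order_invariance(self, small_model):
        model, norm, annot = small_model
        cols = list(norm.columns)
        shuffled = norm[cols[::-1]]
        p1 = classify.predict_matrix(model, norm, sex=annot["sex"])
        p2 = classify.predict_matrix(model, shuffled, sex=annot["sex"])
        pd.testing.assert_frame_equal(p1, p2.loc[p1.index])

    def test_seed_determinism_and_manifest(self, small_cohort):
        cfg, expr, annot = small_cohort
        norm, _ = normalize.normalize_matrix(expr)
        tc = classify.TrainConfig(site_trees=10, lineage_trees=10, seed=9)
        m1 = classify.train_atlas(norm, annot, tc)
        m2 = classify.train_atlas(norm, annot, tc)
        assert m1.training_manifest["hash"] == m2.training_manifest["hash"]
        p1 = classify.predict_matrix(m1, norm)
        p2 = classify.predict_matrix(m2, norm)
        pd.testing.assert_frame_equal(p1, p2)

    def test_axis_independence_site_unaffected_by_lineage_shuffle(self, small_cohort):
        cfg, expr, annot = small_cohort
        norm, _ = normalize.normalize_matrix(expr)
        tc = classify.TrainConfig(site_trees=10, lineage_trees=10, seed=9)
        m1 = classify.train_atlas(norm, annot, tc)
        shuffled = annot.copy()
        shuffled["lineage"] = (
            annot["lineage"].sample(frac=1, random_state=0).to_numpy()
        )
        m2 = classify.train_atlas(norm, shuffled, tc)
        p1 = classify.predict_matrix(m1, norm)
        p2 = classify.predict_matrix(m2, norm)
        site_cols = [c for c in p1.columns if c.startswith("site")]
        assert p1[site_cols].equals(p2[site_cols])
        # and the shuffled lineage model collapses toward chance
        acc = (p2["lineage_call"] == annot["lineage"]).mean()
        assert acc < 0.75

    def test_sex_missing_mode_on_sex_balanced_sites(self, small_model):
        model, norm, annot = small_model
        with_sex = classify.predict_matrix(model, norm, sex=annot["sex"])
        masked = classify.predict_matrix(model, norm, sex=None)
        agree = (with_sex["site_call"] == masked["site_call"]).mean()
        assert agree >= 0.99

    def test_single_class_axis_rejected(self, small_cohort):
        cfg, expr, annot = small_cohort
        norm, _ = normalize.normalize_matrix(expr)
        mono = annot.copy()
        mono["site"] = "Lung"
        with pytest.raises(ValueError, match="2 classes"):
            classify.train_atlas(norm, mono,
                                 classify.TrainConfig(site_trees=5,
                                                      lineage_trees=5))

    def test_unknown_features_rejected(self, small_cohort):
        cfg, expr, annot = small_cohort
        norm, _ = normalize.normalize_matrix(expr)
        with pytest.raises(ValueError, match="absent"):
            classify.train_atlas(
                norm, annot,
                classify.TrainConfig(site_features=["NOT_A_GENE"],
                                     site_trees=5, lineage_trees=5),
            )


class TestFeatureAttribution:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(6)
        n = 150
        y = np.array(["a", "b"])[rng.integers(0, 2, n)]
        X = pd.DataFrame(rng.normal(0, 1, (n, 5)),
                         columns=[f"g{i}" for i in range(5)])
        X["driver"] = (y == "a") * 4.0 + rng.normal(0, 0.1, n)
        X["flat"] = 0.0
        booster = classify.fit_multiclass(X, y, ["a", "b"], 20, seed=6)
        return booster, X

    def test_driver_top_ranked_for_its_class(self, fitted):
        booster, X = fitted
        att = classify.feature_attribution(booster, X, "a", ["a", "b"])
        assert att["feature"].iloc[0] == "driver"

    def test_unused_feature_attribution_zero(self, fitted):
        booster, X = fitted
        att = classify.feature_attribution(booster, X, "a", ["a", "b"], top_n=None)
        assert att.set_index("feature").loc["flat", "median_attribution"] == 0.0

    def test_additivity_to_margin(self, fitted):
        booster, X = fitted
        dm = xgb.DMatrix(X.to_numpy(float),
                         feature_names=list(X.columns), missing=np.nan)
        contribs = booster.predict(dm, pred_contribs=True, strict_shape=True)
        margins = booster.predict(dm, output_margin=True, strict_shape=True)
        np.testing.assert_allclose(contribs.sum(axis=2), margins, atol=1e-4)

    def test_unknown_class_rejected(self, fitted):
        booster, X = fitted
        with pytest.raises(ValueError, match="unknown class"):
            classify.feature_attribution(booster, X, "z", ["a", "b"])
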