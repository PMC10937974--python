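"""Twin multiclass gradient-boosted models: site of origin and lineage.

Two independent XGBoost ensembles are trained on the same normalized
expression: a site-of-origin model (up to 22 classes, with the binary sex
flag as an extra feature) and a lineage model (8 histologic classes, genes
only). Each emits a softmax probability vector summing to one; the class
call is the argmax. The only tuned hyperparameter is the number of trees,
chosen by 5-fold stratified cross-validation; tree depth 6, learning rate
0.3 and no subsampling are fixed.

At prediction time, model genes absent from a sample are filled by
k-nearest-neighbor imputation (k=5) against the normalized training panel;
an unknown sex is passed to the booster as missing and handled by its
native missing-value branches.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from . import scores as _scores

__all__ = [
    "BOOSTER_PARAMS",
    "DEFAULT_TREE_GRID",
    "TrainConfig",
    "AtlasModel",
    "fit_multiclass",
    "tune_tree_count",
    "train_atlas",
    "impute_missing",
    "predict_matrix",
    "feature_attribution",
]

SEX_FEATURE = "sex_male"
SEX_CODE = {"female": 0.0, "male": 1.0, "missing": np.nan}

#: Fixed booster settings; only the number of boosting rounds is ever tuned.
BOOSTER_PARAMS = {
    "max_depth": 6,
    "eta": 0.3,
    "subsample": 1.0,
    "objective": "multi:softprob",
    "tree_method": "hist",
    "nthread": 1,
}

DEFAULT_TREE_GRID = (25, 50, 100, 200, 400, 800)


def _sanitize(name) -> str:
    # xgboost forbids [, ] and < in feature names
    return str(name).replace("[", "(").replace("]", ")").replace("<", "lt")


def fit_multiclass(
    X: pd.DataFrame, labels, classes: list[str], n_trees: int, seed: int = 0
) -> xgb.Booster:
    """Fit one softprob ensemble; rows of ``X`` are samples."""
    codes = np.asarray([classes.index(l) for l in labels])
    dtrain = xgb.DMatrix(
        X.to_numpy(float),
        label=codes,
        feature_names=[_sanitize(c) for c in X.columns],
        missing=np.nan,
    )
    params = dict(BOOSTER_PARAMS, num_class=len(classes), seed=seed)
    return xgb.train(params, dtrain, num_boost_round=n_trees)


def _predict_probs(
    booster: xgb.Booster, X: pd.DataFrame, classes: list[str]
) -> pd.DataFrame:
    dm = xgb.DMatrix(
        X.to_numpy(float),
        feature_names=[_sanitize(c) for c in X.columns],
        missing=np.nan,
    )
    probs = booster.predict(dm)
    return pd.DataFrame(probs, index=X.index, columns=classes)


def _argmax_call(prob_row: pd.Series) -> str:
    """Argmax class; exact ties go to the alphabetically first class."""
    top = prob_row.max()
    return sorted(prob_row.index[prob_row == top])[0]


def tune_tree_count(
    X: pd.DataFrame, labels, tree_grid=DEFAULT_TREE_GRID, cv_seed: int = 0
) -> tuple[int, pd.DataFrame]:
    """5-fold stratified CV over the tree grid; ties favor fewer trees.

    Returns the chosen count and the fold-accuracy table (rows = tree
    counts, columns = folds).
    """
    tree_grid = list(tree_grid)
    if not tree_grid:
        raise ValueError("empty tree grid")
    labels = np.asarray(list(labels))
    classes = sorted(pd.unique(labels))
    counts = pd.Series(labels).value_counts()
    if counts.min() < 5:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} samples; "
            "5-fold stratification needs >= 5 per class"
        )
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=cv_seed)
    folds = list(skf.split(X, labels))
    table = pd.DataFrame(
        index=sorted(tree_grid), columns=[f"fold{i}" for i in range(5)], dtype=float
    )
    for n_trees in table.index:
        for i, (tr, te) in enumerate(folds):
            booster = fit_multiclass(
                X.iloc[tr], labels[tr], classes, n_trees, seed=cv_seed
            )
            probs = _predict_probs(booster, X.iloc[te], classes)
            calls = probs.apply(_argmax_call, axis=1)
            table.loc[n_trees, f"fold{i}"] = float((calls == labels[te]).mean())
    means = table.mean(axis=1)
    best = int(means.index[np.argmax(means.to_numpy())])  # first max = fewest trees
    return best, table


@dataclass
class TrainConfig:
    """Training-time choices; ``*_trees=None`` triggers CV tuning."""

    site_features: list[str] | None = None
    lineage_features: list[str] | None = None
    site_trees: int | None = None
    lineage_trees: int | None = None
    tree_grid: tuple = DEFAULT_TREE_GRID
    seed: int = 0


@dataclass
class AtlasModel:
    """Paired site and lineage ensembles plus everything prediction needs."""

    site_booster: xgb.Booster
    lineage_booster: xgb.Booster
    site_classes: list[str]
    lineage_classes: list[str]
    site_features: list[str]  # genes + sex flag, model order
    lineage_features: list[str]
    imputation_reference: pd.DataFrame  # training samples x union of model genes
    training_manifest: dict = field(default_factory=dict)

    @property
    def gene_features(self) -> list[str]:
        genes = [f for f in self.site_features if f != SEX_FEATURE]
        seen = set(genes)
        genes += [f for f in self.lineage_features if f not in seen]
        return genes

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.site_booster.save_model(path / "site_model.json")
        self.lineage_booster.save_model(path / "lineage_model.json")
        self.imputation_reference.to_csv(path / "imputation_reference.tsv", sep="\t")
        manifest = dict(
            self.training_manifest,
            site_classes=self.site_classes,
            lineage_classes=self.lineage_classes,
            site_features=self.site_features,
            lineage_features=self.lineage_features,
        )
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AtlasModel":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        site = xgb.Booster()
        site.load_model(path / "site_model.json")
        lineage = xgb.Booster()
        lineage.load_model(path / "lineage_model.json")
        ref = pd.read_csv(path / "imputation_reference.tsv", sep="\t", index_col=0)
        keys = ("site_classes", "lineage_classes", "site_features", "lineage_features")
        return cls(
            site_booster=site,
            lineage_booster=lineage,
            imputation_reference=ref,
            training_manifest={k: v for k, v in manifest.items() if k not in keys},
            **{k: manifest[k] for k in keys},
        )


def _manifest_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def train_atlas(
    normalized: pd.DataFrame, annotation: pd.DataFrame, config: TrainConfig
) -> AtlasModel:
    """Train the two ensembles independently on a normalized gene x sample
    matrix. The site model sees the genes plus the sex flag; the lineage
    model sees genes only; neither ever sees the other's labels.
    Identical inputs and seed give an identical manifest and predictions.
    """
    samples = list(normalized.columns)
    annotation = annotation.loc[samples]
    site_labels = annotation["site"].astype(str)
    lineage_labels = annotation["lineage"].astype(str)
    site_classes = sorted(site_labels.unique())
    lineage_classes = sorted(lineage_labels.unique())
    if len(site_classes) < 2 or len(lineage_classes) < 2:
        raise ValueError("each label axis needs >= 2 classes")

    site_genes = [f for f in (config.site_features or list(normalized.index))
                  if f != SEX_FEATURE]
    lineage_genes = list(config.lineage_features or normalized.index)
    for feats in (site_genes, lineage_genes):
        missing = [f for f in feats if f not in normalized.index]
        if missing:
            raise ValueError(f"features absent from matrix: {missing[:5]}")

    X = normalized.T  # samples x genes
    sex = annotation["sex"].map(SEX_CODE).astype(float)
    X_site = X[site_genes].copy()
    X_site[SEX_FEATURE] = sex
    X_lineage = X[lineage_genes]

    # The two axes are trained from disjoint seed streams so that a change
    # confined to one axis cannot perturb the other.
    site_seed = (config.seed * 2 + 1) % (2**31)
    lineage_seed = (config.seed * 2 + 2) % (2**31)

    if config.site_trees is None:
        site_trees, _ = tune_tree_count(X_site, site_labels, config.tree_grid,
                                        cv_seed=site_seed)
    else:
        site_trees = config.site_trees
    if config.lineage_trees is None:
        lineage_trees, _ = tune_tree_count(X_lineage, lineage_labels,
                                           config.tree_grid, cv_seed=lineage_seed)
    else:
        lineage_trees = config.lineage_trees

    site_booster = fit_multiclass(X_site, site_labels, site_classes,
                                  site_trees, seed=site_seed)
    lineage_booster = fit_multiclass(X_lineage, lineage_labels, lineage_classes,
                                     lineage_trees, seed=lineage_seed)

    union_genes = list(dict.fromkeys(site_genes + lineage_genes))
    reference = X[union_genes]

    manifest = {
        "seed": config.seed,
        "site_trees": int(site_trees),
        "lineage_trees": int(lineage_trees),
        "n_training_samples": len(samples),
        "booster_params": {k: v for k, v in BOOSTER_PARAMS.items()},
    }
    manifest["hash"] = _manifest_hash(
        {
            **manifest,
            "site_features": site_genes + [SEX_FEATURE],
            "lineage_features": lineage_genes,
            "samples": samples,
        }
    )
    return AtlasModel(
        site_booster=site_booster,
        lineage_booster=lineage_booster,
        site_classes=site_classes,
        lineage_classes=lineage_classes,
        site_features=site_genes + [SEX_FEATURE],
        lineage_features=lineage_genes,
        imputation_reference=reference,
        training_manifest=manifest,
    )


def impute_missing(
    sample: pd.Series, reference: pd.DataFrame, k: int = 5
) -> pd.Series:
    """Fill missing features with the mean over the k nearest references.

    Distance is Euclidean over the features non-missing in the query,
    rescaled by the square root of the number used (so queries with
    different missingness are comparable); distance ties break by reference
    sample id. Requires >= 10 shared non-missing features and >= k
    reference samples.
    """
    if len(reference) < k:
        raise ValueError(f"reference panel has {len(reference)} < k={k} samples")
    x = sample.reindex(reference.columns).to_numpy(float)
    observed = ~np.isnan(x)
    if observed.sum() < 10:
        raise ValueError(
            f"only {int(observed.sum())} non-missing model features in sample; "
            "need >= 10 for imputation"
        )
    if observed.all():
        return sample.reindex(reference.columns)
    ref = reference.to_numpy(float)
    diffs = ref[:, observed] - x[observed]
    dists = np.sqrt(np.nanmean(diffs**2, axis=1))
    order = sorted(range(len(reference)),
                   key=lambda i: (dists[i], str(reference.index[i])))
    nearest = ref[order[:k], :]
    filled = x.copy()
    missing = ~observed
    filled[missing] = np.nanmean(nearest[:, missing], axis=0)
    return pd.Series(filled, index=reference.columns, name=sample.name)


def predict_matrix(
    model: AtlasModel,
    normalized: pd.DataFrame,
    sex: pd.Series | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """Predict every column of a normalized gene x sample matrix.

    Genes are matched by symbol; model genes absent from the input become
    missing and are kNN-imputed against the training panel. ``sex=None``
    (or an entry outside {female, male}) is passed to the site booster as
    missing. Returns one row per sample with both probability vectors,
    argmax calls, confidences, and the differentiation score.
    """
    genes = model.gene_features
    X = normalized.reindex(genes).T  # samples x union genes, NaN where absent
    if X.isna().to_numpy().any():
        rows = []
        for sid in X.index:
            rows.append(impute_missing(X.loc[sid], model.imputation_reference, k=k))
        X = pd.DataFrame(rows, index=X.index)

    site_genes = [f for f in model.site_features if f != SEX_FEATURE]
    X_site = X[site_genes].copy()
    if sex is None:
        sex_codes = pd.Series(np.nan, index=X.index)
    else:
        sex_codes = sex.reindex(X.index).map(SEX_CODE).astype(float)
    X_site[SEX_FEATURE] = sex_codes
    X_lineage = X[model.lineage_features]

    site_probs = _predict_probs(model.site_booster, X_site, model.site_classes)
    lineage_probs = _predict_probs(
        model.lineage_booster, X_lineage, model.lineage_classes
    )

    out = pd.concat(
        [site_probs.add_prefix("site:"), lineage_probs.add_prefix("lineage:")],
        axis=1,
    )
    out["site_call"] = site_probs.apply(_argmax_call, axis=1)
    out["lineage_call"] = lineage_probs.apply(_argmax_call, axis=1)
    out["site_confidence"] = site_probs.max(axis=1)
    out["lineage_confidence"] = lineage_probs.max(axis=1)
    out["differentiation_score"] = [
        _scores.differentiation_score(lineage_probs.loc[s]) for s in out.index
    ]
    out.index.name = "sample_id"
    return out


def feature_attribution(
    booster: xgb.Booster,
    X: pd.DataFrame,
    cls: str,
    classes: list[str],
    top_n: int | None = 10,
) -> pd.DataFrame:
    """Per-class additive (TreeSHAP) feature attributions, median-reduced.

    For every sample the attributions across features plus the bias term sum
    exactly to the class's margin; features are returned ordered by the
    absolute median attribution over samples.
    """
    if cls not in classes:
        raise ValueError(f"unknown class {cls!r}")
    if len(X) < 1:
        raise ValueError("need >= 1 sample")
    dm = xgb.DMatrix(
        X.to_numpy(float),
        feature_names=[_sanitize(c) for c in X.columns],
        missing=np.nan,
    )
    contribs = booster.predict(dm, pred_contribs=True, strict_shape=True)
    # strict_shape: (n_samples, n_classes, n_features + 1); last column = bias
    class_contribs = contribs[:, classes.index(cls), :-1]
    med = np.median(class_contribs, axis=0)
    out = pd.DataFrame(
        {"feature": list(X.columns), "median_attribution": med}
    ).sort_values(
        "median_attribution", key=lambda s: -s.abs(), kind="stable"
    ).reset_index(drop=True)
    return out.head(top_n) if top_n is not None else out
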