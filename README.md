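# atlas

Platform-independent tumor **site-of-origin** and **lineage** classification
from single-sample RNA expression, with a lineage **differentiation score**
linking de-differentiation to subtype discrimination and survival.

## What it does

Metastatic tumors — most acutely, cancers of unknown primary — often cannot
be assigned a tissue of origin or a histologic lineage from morphology alone.
`atlas` classifies a single expression profile along two independent axes
with paired multiclass gradient-boosted tree ensembles:

- a **site model** over organ-site classes (plus a binary sex flag), and
- a **lineage model** over 8 histologic lineage classes (adenocarcinoma,
  squamous cell carcinoma, sarcoma, melanoma, glioma, germ cell tumor,
  lymphoid/myeloid neoplasm, neuroepithelial cancer).

Each model emits a calibrated-scale probability vector summing to one; the
class call is the argmax. Because every sample is re-normalized on its own —
a per-sample Yeo-Johnson transform with maximum-likelihood λ, followed by
within-sample z-scoring — predictions are robust to the input's
normalization scheme (RSEM/FPKM/TPM/CPM/microarray), with no cross-sample
batch correction.

The maximum of the lineage probabilities, D = max_k P(lineage = k) ∈ (0, 1],
is the **differentiation score**: confidently single-lineage tumors score
near 1, de-differentiated/anaplastic tumors spread probability across
lineages and score low. Derived scores (the adenocarcinoma−SCC delta, named
lineage scores such as the sarcoma score, and ROC optimal-cut grouping)
support subtype discrimination — including zero-shot scoring of tumor types
absent from training — and Kaplan-Meier/log-rank and Cox analyses link the
score to survival under a fixed 5-year censoring rule.

A seeded synthetic-cohort generator (site/lineage/sex marker architecture,
platform distortions, purity admixture, de-differentiation mixtures,
survival with differentiation-dependent hazard) makes every stage testable
at desk scale with no downloads. See `docs/methods.md` for the model,
assumptions, and limitations.

## Worked example

```python
import numpy as np
from atlas import synth, normalize, classify

cfg = synth.standard_cohort_config(n_per_cell=40, seed=0, n_sites=6,
                                   n_lineages=3, n_genes=200)
expr, annot = synth.generate_cohort(cfg)
norm, lambdas = normalize.normalize_matrix(expr)
model = classify.train_atlas(
    norm, annot, classify.TrainConfig(site_trees=50, lineage_trees=50, seed=0)
)

test_cfg = synth.standard_cohort_config(n_per_cell=10, seed=0, n_sites=6,
                                        n_lineages=3, n_genes=200)
test_expr, test_annot = synth.generate_cohort(test_cfg, seed=99)
test_norm, _ = normalize.normalize_matrix(test_expr)
preds = classify.predict_matrix(model, test_norm, sex=test_annot["sex"])

print(f"held-out site accuracy:    "
      f"{(preds['site_call'] == test_annot['site']).mean():.3f}")
print(f"held-out lineage accuracy: "
      f"{(preds['lineage_call'] == test_annot['lineage']).mean():.3f}")
```

prints

```
held-out site accuracy:    0.978
held-out lineage accuracy: 0.989
```

i.e. on a 6-site x 3-lineage synthetic cohort the held-out site call is
right 97.8% of the time and the lineage call 98.9%. Each row of `preds`
carries the full probability vectors, calls, confidences, and the
differentiation score; the first held-out sample, for instance, is called
`Bladder` at probability 0.995 and `Adenocarcinoma` at 0.999, giving a
differentiation score of 0.999 (a highly differentiated tumor).

The same pipeline is available from the shell:

```bash
atlas simulate --config cohort.yaml --seed 4 --out sim/
atlas train    --expr sim/expression.tsv --meta sim/annotation.csv \
               --config train.yaml --seed 4 --out model/
atlas predict  --model model/ --expr sim/expression.tsv \
               --meta sim/annotation.csv --out preds.tsv
atlas evaluate --preds preds.tsv --meta sim/annotation.csv --out report.json
atlas survival --preds preds.tsv --meta meta_surv.csv \
               --group-by differentiation-cut --out surv.json
```

Every command writes a `run_manifest.json` recording the command, config and
input hashes, seeds, and package version; `--sex-missing` on `predict`
masks sex to exercise the unknown-sex mode.

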