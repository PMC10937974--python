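"""Seeded synthetic tumor-expression cohorts.

The generator emulates the statistical structure the classification pipeline
assumes: multi-class expression archetypes with site- and lineage-specific
marker genes, sex-linked genes, per-dataset platform distortions,
tumor-purity admixture with a normal-tissue profile, de-differentiation
mixtures toward a class-neutral (anaplastic) background, and survival times
whose hazard depends on the true degree of differentiation.

Expression is generated on the natural-log scale and exponentiated, giving
positive right-skewed values resembling per-sample-normalized RNA-seq.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SITES",
    "DEFAULT_LINEAGES",
    "CohortConfig",
    "PlatformEffect",
    "standard_cohort_config",
    "generate_cohort",
    "apply_platform_effect",
    "lineage_archetypes",
    "anaplastic_background",
    "normal_profile",
    "mix_purity",
    "mix_dedifferentiation",
    "generate_survival",
]

#: Synthetic organ-site vocabulary (the full 22-class vocabulary is configurable).
DEFAULT_SITES = [
    "Bladder", "Brain", "Breast", "Colorectal", "Kidney", "Liver",
    "Lung", "Ovary", "Pancreas", "Prostate", "Skin", "Thyroid",
]

#: The eight histologic lineage classes.
DEFAULT_LINEAGES = [
    "Adenocarcinoma",
    "Germ Cell Tumor",
    "Glioma",
    "Lymphoid/Myeloid Neoplasm",
    "Melanoma",
    "Neuroepithelial Cancer",
    "Sarcoma",
    "Squamous Cell Carcinoma",
]


@dataclass(frozen=True)
class PlatformEffect:
    """A per-dataset distortion emulating heterogeneous normalization schemes.

    kind
        One of ``scale`` (per-sample multiplicative factor around
        ``magnitude``), ``log1p`` (x -> ln(1+x), magnitude ignored),
        ``library_size`` (rescale each sample to a drawn total around
        ``magnitude``), or ``gene_subset`` (set a drawn fraction
        ``magnitude`` of genes to missing in every sample).
    """

    kind: str
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"scale", "log1p", "library_size", "gene_subset"}:
            raise ValueError(f"unknown platform effect kind: {self.kind!r}")
        if not np.isfinite(self.magnitude) or self.magnitude <= 0:
            raise ValueError("magnitude must be a positive finite scalar")
        if self.kind == "gene_subset" and not self.magnitude < 1:
            raise ValueError("gene_subset magnitude is a fraction in (0, 1)")


@dataclass
class CohortConfig:
    """Design of a synthetic cohort.

    ``site_lineage_table`` maps allowed (site, lineage) combinations to
    per-combination sample counts; every lineage must appear under at least
    one site. Marker sets for distinct classes are disjoint by construction.
    ``marker_effect`` is a natural-log fold change; ``noise_sd`` a log-scale
    Gaussian standard deviation.
    """

    site_lineage_table: dict[tuple[str, str], int]
    n_genes: int = 500
    n_markers_per_site: int = 6
    n_markers_per_lineage: int = 6
    marker_effect: float = 2.0
    noise_sd: float = 1.0
    n_sex_genes: int = 5
    seed: int = 0

    sites: list[str] = field(init=False)
    lineages: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.site_lineage_table:
            raise ValueError("site_lineage_table is empty")
        if any(c < 1 for c in self.site_lineage_table.values()):
            raise ValueError("all per-cell sample counts must be >= 1")
        for name in ("n_genes", "n_markers_per_site", "n_markers_per_lineage"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.sites = sorted({s for s, _ in self.site_lineage_table})
        self.lineages = sorted({l for _, l in self.site_lineage_table})
        budget = (
            len(self.sites) * self.n_markers_per_site
            + len(self.lineages) * self.n_markers_per_lineage
            + self.n_sex_genes
        )
        if budget > self.n_genes:
            raise ValueError(
                f"marker budget ({budget} genes) exceeds n_genes ({self.n_genes})"
            )

    # -- deterministic marker layout -------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def site_markers(self, site: str) -> list[str]:
        i = self.sites.index(site)
        m = self.n_markers_per_site
        return self.gene_ids[i * m : (i + 1) * m]

    def lineage_markers(self, lineage: str) -> list[str]:
        off = len(self.sites) * self.n_markers_per_site
        i = self.lineages.index(lineage)
        m = self.n_markers_per_lineage
        return self.gene_ids[off + i * m : off + (i + 1) * m]

    @property
    def sex_genes(self) -> list[str]:
        off = (
            len(self.sites) * self.n_markers_per_site
            + len(self.lineages) * self.n_markers_per_lineage
        )
        return self.gene_ids[off : off + self.n_sex_genes]

    def baseline_log_mean(self) -> np.ndarray:
        """Per-gene baseline mu_g ~ N(2, 1), fixed by the config seed."""
        rng = np.random.default_rng([self.seed, 0xA71])
        return rng.normal(2.0, 1.0, size=self.n_genes)


def standard_cohort_config(
    n_per_cell: int = 100,
    seed: int = 0,
    n_sites: int = 12,
    n_lineages: int = 4,
    n_genes: int = 500,
    **kwargs,
) -> CohortConfig:
    """Fully-crossed site x lineage design used throughout the test bench."""
    sites = DEFAULT_SITES[:n_sites]
    lineages = DEFAULT_LINEAGES[:n_lineages]
    table = {(s, l): n_per_cell for s in sites for l in lineages}
    return CohortConfig(site_lineage_table=table, n_genes=n_genes, seed=seed, **kwargs)


def _log_profile_mean(config: CohortConfig, site: str | None, lineage: str | None,
                      male: bool = False) -> np.ndarray:
    mu = config.baseline_log_mean().copy()
    idx = {g: i for i, g in enumerate(config.gene_ids)}
    if site is not None:
        for g in config.site_markers(site):
            mu[idx[g]] += config.marker_effect
    if lineage is not None:
        for g in config.lineage_markers(lineage):
            mu[idx[g]] += config.marker_effect
    if male:
        for g in config.sex_genes:
            mu[idx[g]] += config.marker_effect
    return mu


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort: (gene x sample expression matrix, sample annotation).

    Expression of sample s at gene g is
    ``exp(mu_g + site_effect + lineage_effect + sex_effect + N(0, noise_sd))``.
    Identical config and seed give byte-identical output.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 0x5A3])
    cells = sorted(config.site_lineage_table.items())
    n_samples = sum(c for _, c in cells)
    width = len(str(n_samples))

    base = config.baseline_log_mean()
    idx = {g: i for i, g in enumerate(config.gene_ids)}
    site_eff = {
        s: np.isin(np.arange(config.n_genes),
                   [idx[g] for g in config.site_markers(s)]) * config.marker_effect
        for s in config.sites
    }
    lin_eff = {
        l: np.isin(np.arange(config.n_genes),
                   [idx[g] for g in config.lineage_markers(l)]) * config.marker_effect
        for l in config.lineages
    }
    sex_eff = (
        np.isin(np.arange(config.n_genes), [idx[g] for g in config.sex_genes])
        * config.marker_effect
    )

    records = []
    log_expr = np.empty((config.n_genes, n_samples))
    col = 0
    for (site, lineage), count in cells:
        for _ in range(count):
            sex = "male" if rng.random() < 0.5 else "female"
            mu = base + site_eff[site] + lin_eff[lineage]
            if sex == "male":
                mu = mu + sex_eff
            log_expr[:, col] = mu + rng.normal(0.0, config.noise_sd, config.n_genes)
            records.append(
                {
                    "sample_id": f"S{col + 1:0{width}d}",
                    "site": site,
                    "lineage": lineage,
                    "sex": sex,
                    "specimen_type": "primary",
                    "dataset_id": "synthetic",
                    "purity": 1.0,
                    "dediff_alpha": 0.0,
                }
            )
            col += 1

    annot = pd.DataFrame.from_records(records).set_index("sample_id")
    expr = pd.DataFrame(np.exp(log_expr), index=config.gene_ids, columns=annot.index)
    expr.index.name = "gene_id"
    return expr, annot


def apply_platform_effect(
    matrix: pd.DataFrame, effect: PlatformEffect, seed: int = 0
) -> pd.DataFrame:
    """Apply a platform distortion; monotone kinds preserve within-sample ranks."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression matrix must be non-negative")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    n_genes, n_samples = out.shape
    if effect.kind == "scale":
        factors = effect.magnitude * np.exp2(rng.uniform(-1.0, 1.0, n_samples))
        out = out * factors
    elif effect.kind == "log1p":
        out = np.log1p(out)
    elif effect.kind == "library_size":
        totals = effect.magnitude * np.exp2(rng.uniform(-1.0, 1.0, n_samples))
        current = out.sum(axis=0).replace(0.0, np.nan)
        out = out * (totals / current)
    elif effect.kind == "gene_subset":
        n_drop = int(np.floor(effect.magnitude * n_genes))
        dropped = rng.choice(n_genes, size=n_drop, replace=False)
        out.iloc[dropped, :] = np.nan
    return out


def lineage_archetypes(config: CohortConfig) -> pd.DataFrame:
    """Linear-scale mean expression profile of each lineage (no site effect)."""
    cols = {
        l: np.exp(_log_profile_mean(config, None, l)) for l in config.lineages
    }
    return pd.DataFrame(cols, index=config.gene_ids)


def anaplastic_background(config: CohortConfig) -> pd.Series:
    """Class-neutral profile: unweighted mean of the lineage archetypes."""
    return lineage_archetypes(config).mean(axis=1)


def normal_profile(config: CohortConfig) -> pd.Series:
    """Contaminating normal-tissue profile: the marker-free baseline."""
    return pd.Series(
        np.exp(config.baseline_log_mean()), index=config.gene_ids, name="normal"
    )


def _check_aligned(a: pd.Series | pd.DataFrame, b: pd.Series) -> None:
    if not a.index.equals(b.index):
        raise ValueError("gene sets of the two profiles do not match")


def mix_purity(tumor, normal: pd.Series, purity: float):
    """Convex admixture purity*tumor + (1-purity)*normal on the linear scale.

    ``tumor`` may be a single profile (Series) or a gene x sample matrix.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must be in [0, 1]")
    _check_aligned(tumor, normal)
    if isinstance(tumor, pd.DataFrame):
        return tumor.mul(purity).add((1.0 - purity) * normal, axis=0)
    return purity * tumor + (1.0 - purity) * normal


def mix_dedifferentiation(profile, background: pd.Series, alpha: float):
    """Convex mixture (1-alpha)*profile + alpha*anaplastic background."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    _check_aligned(profile, background)
    if isinstance(profile, pd.DataFrame):
        return profile.mul(1.0 - alpha).add(alpha * background, axis=0)
    return (1.0 - alpha) * profile + alpha * background


def generate_survival(
    annotation: pd.DataFrame,
    beta: float,
    baseline_rate: float,
    censor_rate: float,
    seed: int = 0,
    differentiation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Attach exponential survival whose hazard depends on differentiation.

    Event times are exponential with rate
    ``baseline_rate * exp(beta * (1 - true_differentiation))``; censoring is
    an independent exponential with rate ``censor_rate``. The true
    differentiation defaults to ``1 - dediff_alpha`` from the annotation.
    """
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("baseline_rate and censor_rate must be positive")
    if differentiation is None:
        diff = 1.0 - annotation["dediff_alpha"].to_numpy(float)
    else:
        diff = np.asarray(differentiation, float)
        if diff.shape != (len(annotation),):
            raise ValueError("differentiation length does not match annotation")
    rng = np.random.default_rng(seed)
    rate = baseline_rate * np.exp(beta * (1.0 - diff))
    event_t = rng.exponential(1.0 / rate)
    censor_t = rng.exponential(1.0 / censor_rate, size=len(annotation))
    out = annotation.copy()
    out["time"] = np.minimum(event_t, censor_t)
    out["event"] = (event_t <= censor_t).astype(int)
    return out
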