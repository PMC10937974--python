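"""Platform-independent single-sample normalization.

Expression cohorts arrive on wildly heterogeneous per-sample scales (RSEM,
FPKM, TPM, CPM, microarray intensities). Each sample is therefore
re-normalized independently: a Yeo-Johnson power transform with the power
parameter fitted by maximum likelihood on that sample alone, followed by
within-sample standardization. No cross-sample batch correction is applied,
and no statistic is ever shared between columns.

Gene-wise z-scored input defeats single-sample normalization and is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "LambdaEstimate",
    "NormalizedProfile",
    "yeo_johnson_transform",
    "yeo_johnson_loglik",
    "fit_lambda",
    "normalize_sample",
    "normalize_matrix",
]

LAMBDA_BOUNDS = (-5.0, 5.0)


@dataclass(frozen=True)
class LambdaEstimate:
    """Fitted Yeo-Johnson power parameter and its profile log-likelihood."""

    lam: float
    loglik: float


@dataclass(frozen=True)
class NormalizedProfile:
    """Per-gene transformed-and-standardized scores for one sample.

    Over the non-missing entries the values have mean 0 and sd 1; missing
    entries propagate as NaN.
    """

    values: pd.Series
    lam: float
    loglik: float


def yeo_johnson_transform(values, lam: float) -> np.ndarray:
    """Elementwise Yeo-Johnson transform.

    y >= 0: ((y+1)^lam - 1)/lam, or ln(y+1) when lam = 0;
    y <  0: -(((1-y)^(2-lam)) - 1)/(2-lam), or -ln(1-y) when lam = 2.
    Missing values (NaN) pass through.
    """
    if not np.isfinite(lam):
        raise ValueError("lambda must be finite")
    y = np.asarray(values, dtype=float)
    out = np.full(y.shape, np.nan)
    pos = y >= 0
    neg = y < 0
    # expm1/log1p forms are exact rearrangements of the power branches and
    # remain stable as lam -> 0 or lam -> 2.
    if lam != 0.0:
        out[pos] = np.expm1(lam * np.log1p(y[pos])) / lam
    else:
        out[pos] = np.log1p(y[pos])
    if lam != 2.0:
        out[neg] = -np.expm1((2.0 - lam) * np.log1p(-y[neg])) / (2.0 - lam)
    else:
        out[neg] = -np.log1p(-y[neg])
    return out


def yeo_johnson_loglik(values: np.ndarray, lam: float) -> float:
    """Gaussian profile log-likelihood of the transformed data at ``lam``.

    Includes the Jacobian term (lam - 1) * sum(sign(y) * ln(1 + |y|)).
    ``values`` must be free of missing entries.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    psi = yeo_johnson_transform(y, lam)
    var = psi.var()
    if not np.isfinite(var) or var <= 0:
        return -np.inf
    jac = (lam - 1.0) * np.sum(np.sign(y) * np.log1p(np.abs(y)))
    return -0.5 * n * np.log(var) + jac


def fit_lambda(values, bounds: tuple[float, float] = LAMBDA_BOUNDS,
               xatol: float = 1e-4) -> LambdaEstimate:
    """Maximum-likelihood Yeo-Johnson power parameter for one sample.

    Bounded scalar optimization of the profile likelihood over ``bounds``.
    Requires >= 10 non-missing values with nonzero variance.
    """
    y = np.asarray(values, dtype=float)
    y = y[~np.isnan(y)]
    if y.size < 10:
        raise ValueError(f"need >= 10 non-missing values, got {y.size}")
    if np.ptp(y) == 0:
        raise ValueError("cannot fit lambda on a constant vector")
    res = minimize_scalar(
        lambda lam: -yeo_johnson_loglik(y, lam),
        bounds=bounds,
        method="bounded",
        options={"xatol": xatol},
    )
    return LambdaEstimate(lam=float(res.x), loglik=float(-res.fun))


def normalize_sample(values) -> NormalizedProfile:
    """Transform one sample with its own MLE lambda, then z-score it.

    The lambda fit and the moments use only the sample's non-missing
    entries; missing entries propagate to the output.
    """
    ser = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) \
        else values.astype(float)
    est = fit_lambda(ser.to_numpy())
    psi = yeo_johnson_transform(ser.to_numpy(), est.lam)
    finite = ~np.isnan(psi)
    mu = psi[finite].mean()
    sd = psi[finite].std()
    if sd == 0:
        raise ValueError("transformed sample has zero variance")
    out = pd.Series((psi - mu) / sd, index=ser.index, name=ser.name)
    return NormalizedProfile(values=out, lam=est.lam, loglik=est.loglik)


def _looks_gene_zscored(matrix: pd.DataFrame) -> bool:
    """Heuristic: a gene row with negative values and near-zero mean across
    samples suggests the input was already gene-wise z-scored."""
    if matrix.shape[1] < 3:
        return False
    vals = matrix.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(vals, axis=1)
        row_sd = np.nanstd(vals, axis=1)
        has_neg = np.nanmin(vals, axis=1) < 0
    suspicious = has_neg & (np.abs(row_mean) < 0.05 * np.maximum(row_sd, 1e-12))
    return bool(suspicious.mean() > 0.5)


def normalize_matrix(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Normalize every column independently.

    Returns the normalized matrix and the per-sample fitted lambda. A column
    that cannot be normalized is reported with its sample id.
    """
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if _looks_gene_zscored(matrix):
        warnings.warn(
            "input looks gene-wise z-scored (negative values, near-zero gene "
            "means); single-sample normalization assumes raw per-sample scales",
            UserWarning,
            stacklevel=2,
        )
    cols = {}
    lambdas: dict[str, float] = {}
    failures = []
    for sample in matrix.columns:
        try:
            prof = normalize_sample(matrix[sample])
        except ValueError as exc:
            failures.append(f"{sample}: {exc}")
            continue
        cols[sample] = prof.values
        lambdas[sample] = prof.lam
    if failures:
        raise ValueError(
            "normalization failed for samples: " + "; ".join(failures)
        )
    out = pd.DataFrame(cols, index=matrix.index)
    out.index.name = matrix.index.name
    return out, lambdas
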