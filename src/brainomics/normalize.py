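"""Count normalization: median-of-ratios size factors, a log-like
variance-stabilizing transform, covariate residualization and row z-scoring.

The canonical pipeline order is counts -> size factors -> log-like
transform -> residualize against PRUA; ``NormalizedMatrix.flags`` records
the transforms actually applied, in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "size_factors",
    "scaled_counts",
    "log_like_transform",
    "residualize",
    "zscore_rows",
    "normalize_pipeline",
]


@dataclass
class NormalizedMatrix:
    """Gene x sample real-valued expression with its provenance."""

    values: pd.DataFrame  # genes x samples
    size_factors: pd.Series
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if np.any(self.size_factors.to_numpy() <= 0):
            raise ValueError("size factors must be positive")
        if not self.values.columns.equals(self.size_factors.index):
            raise ValueError("size factor index must match sample columns")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    factor_j = median over genes g (restricted to genes whose geometric
    mean across samples is nonzero) of count_gj / geomean_g. Factors are
    returned raw (not renormalized to geometric mean 1).
    """
    K = cm.values.astype(float)
    with np.errstate(divide="ignore"):
        logK = np.log(K)
    log_geomean = logK.mean(axis=1)  # -inf for any gene with a zero
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; size factors are "
            "undefined (filter all-zero-containing genes or add samples)"
        )
    ratios = logK[usable] - log_geomean[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def log_like_transform(
    cm: CountMatrix, factors: pd.Series, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """log2(count / size_factor + pseudocount) per cell.

    This is the log-like variance-stabilizing step: monotone in counts and
    approximately variance-stabilizing at moderate expression.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    sf = factors.reindex(cm.sample_ids)
    if sf.isna().any() or np.any(sf.to_numpy() <= 0):
        raise ValueError("size factors must be positive and cover all samples")
    vals = np.log2(cm.values / sf.to_numpy()[None, :] + pseudocount)
    df = pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids)
    return NormalizedMatrix(df, sf, flags=("log_like",))


def scaled_counts(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Size-factor-scaled counts on the linear scale (count / size_factor).

    The proportion-prediction formula (observed index / purified index) is
    scale-dependent and only valid on a linear expression scale, so the
    in-silico mixing benchmark uses these values; the log-like transform is
    for indices compared across patients, PCA and clustering.
    """
    if factors is None:
        factors = size_factors(cm)
    sf = factors.reindex(cm.sample_ids).to_numpy(float)
    return pd.DataFrame(
        cm.values / sf[None, :], index=cm.gene_ids, columns=cm.sample_ids
    )


def residualize(norm: NormalizedMatrix, covariate: pd.Series) -> NormalizedMatrix:
    """Remove the linear effect of a per-sample covariate from every gene.

    Per gene, expression is OLS-regressed on the covariate (with
    intercept); values are replaced by residuals re-centered at the gene's
    mean so indices stay on the expression scale. The result is exactly
    uncorrelated with the covariate.
    """
    c = covariate.reindex(norm.sample_ids).to_numpy(float)
    if np.any(~np.isfinite(c)):
        raise ValueError("covariate missing for some samples")
    cc = c - c.mean()
    denom = np.dot(cc, cc)
    if denom == 0:
        raise ValueError("constant covariate: residualization undefined")
    Y = norm.values.to_numpy()
    gene_means = Y.mean(axis=1, keepdims=True)
    beta = (Y - gene_means) @ cc / denom  # per-gene slope
    resid = Y - beta[:, None] * cc[None, :]  # residual + gene mean
    df = pd.DataFrame(resid, index=norm.gene_ids, columns=norm.sample_ids)
    return NormalizedMatrix(df, norm.size_factors, flags=norm.flags + ("residualized",))


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Per-row z-score using population (n-denominator) SD.

    Rows with zero SD are set to all-zero and returned in the flagged
    index rather than raising.
    """
    X = matrix.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population SD (ddof=0)
    degenerate = sd[:, 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[degenerate, :] = 0.0
    out = pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return out, matrix.index[degenerate]


def normalize_pipeline(
    cm: CountMatrix,
    covariate: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """Canonical path: size factors -> log-like transform -> residualize.

    ``covariate`` is typically the sample table's PRUA column; pass None to
    skip residualization (some analyses want the uncorrected values).
    """
    sf = size_factors(cm)
    norm = log_like_transform(cm, sf, pseudocount=pseudocount)
    if covariate is not None:
        norm = residualize(norm, covariate)
    return norm
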