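"""Covariate-adjusted differential expression by negative-binomial
likelihood-ratio tests, plus cross-disorder concordance statistics.

This is a deliberately simplified DESeq2-style stand-in: per-gene NB
log-linear models (log link, size factors as offsets) are fit by IRLS at a
fixed method-of-moments dispersion, and the case/control factor is tested
by a 1-df likelihood-ratio chi-square of the full design
(~ covariates + Disorder) against the reduced design (~ covariates). There
is no Cox-Reid dispersion adjustment, no Cook's-distance outlier handling
and no fold-change shrinkage; downstream stages consume only
(baseMean, log2FC, p, padj), which this model reproduces in distribution.

The IRLS fitter is batched across genes: every gene shares the design
matrix, so each iteration solves one stacked weighted least-squares system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .io import CountMatrix, SampleTable
from .normalize import size_factors as compute_size_factors
from .stats import bh_adjust, overlap_test, spearman

__all__ = [
    "DesignSpec",
    "estimate_dispersions",
    "nb_lrt",
    "filter_and_adjust",
    "crossdisorder_concordance",
    "DE_COLUMNS",
]

DE_COLUMNS = ("baseMean", "log2FC", "dispersion", "pvalue", "padj", "converged")

_ETA_CLIP = 30.0  # keep exp(eta) finite during IRLS
_MAX_ITER = 100
_LL_TOL = 1e-8


@dataclass(frozen=True)
class DesignSpec:
    """Full vs reduced model specification.

    The reduced model (~ covariates) is nested in the full model
    (~ covariates + factor); the LRT degrees of freedom is 1 because the
    factor is coded as a two-level contrast.
    """

    covariates: tuple[str, ...] = ("age", "pH", "PMI", "PRUA")
    factor: str = "diagnosis"


# ---------------------------------------------------------------------------
# batched GLM machinery


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log-likelihood; alpha=0 rows use the Poisson limit."""
    mu = np.maximum(mu, 1e-12)
    out = np.empty(Y.shape[0])
    pois = alpha <= 0
    if pois.any():
        Yp, Mp = Y[pois], mu[pois]
        out[pois] = np.sum(Yp * np.log(Mp) - Mp - gammaln(Yp + 1), axis=1)
    if (~pois).any():
        Yn, Mn = Y[~pois], mu[~pois]
        r = 1.0 / alpha[~pois][:, None]
        out[~pois] = np.sum(
            gammaln(Yn + r)
            - gammaln(r)
            - gammaln(Yn + 1)
            + r * np.log(r / (r + Mn))
            + Yn * np.log(Mn / (r + Mn)),
            axis=1,
        )
    return out


def _fit_glm_batch(Y, X, offset, alpha):
    """Fit one NB (or Poisson) log-linear GLM per row of ``Y`` by IRLS.

    Y: genes x samples counts; X: samples x p design (shared);
    offset: per-sample log size factors; alpha: per-gene dispersion.
    Returns (beta, loglik, converged).
    """
    G, n = Y.shape
    p = X.shape[1]
    a = alpha[:, None]
    # init from a log-linear least squares on log(y + 0.5)
    z0 = np.log(Y + 0.5) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # G x p
    eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = _nb_loglik(Y, mu, alpha)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        m = mu[idx]
        w = m / (1.0 + a[idx] * m)  # IRLS weights for log link, fixed alpha
        z = (eta[idx] - offset[None, :]) + (Y[idx] - m) / m
        A = np.einsum("ni,gn,nj->gij", X, w, X)
        b = np.einsum("ni,gn,gn->gi", X, w, z)
        A += np.eye(p)[None, :, :] * 1e-10  # ridge jitter against singular steps
        try:
            new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.stack(
                [np.linalg.lstsq(A[g], b[g], rcond=None)[0] for g in range(idx.size)]
            )
        bad = ~np.all(np.isfinite(new_beta), axis=1)
        new_beta[bad] = beta[idx][bad]
        new_eta = np.clip(new_beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        new_mu = np.exp(new_eta)
        new_ll = _nb_loglik(Y[idx], new_mu, alpha[idx])
        # step-halve genes whose likelihood worsened
        worse = new_ll < ll[idx] - 1e-12
        for _half in range(10):
            if not worse.any():
                break
            w_idx = idx[worse]
            new_beta[worse] = 0.5 * (new_beta[worse] + beta[w_idx])
            new_eta[worse] = np.clip(
                new_beta[worse] @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP
            )
            new_mu[worse] = np.exp(new_eta[worse])
            new_ll[worse] = _nb_loglik(Y[w_idx], new_mu[worse], alpha[w_idx])
            worse = new_ll < ll[idx] - 1e-12
        done = np.abs(new_ll - ll[idx]) < _LL_TOL
        beta[idx] = new_beta
        eta[idx] = new_eta
        mu[idx] = new_mu
        ll[idx] = new_ll
        converged[idx[done]] = True
        active[idx[done]] = False
    return beta, ll, converged


def _design_matrix(samples: pd.DataFrame, covariates, factor_col=None, case=None):
    cols = ["intercept"]
    mats = [np.ones(len(samples))]
    for c in covariates:
        mats.append(samples[c].to_numpy(float))
        cols.append(c)
    if factor_col is not None:
        mats.append((samples[factor_col] == case).to_numpy(float))
        cols.append(f"{factor_col}[{case}]")
    X = np.column_stack(mats)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns via QR
        _, R = np.linalg.qr(X)
        bad = [cols[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")
    return X, cols


# ---------------------------------------------------------------------------
# public operations


def estimate_dispersions(
    counts: CountMatrix,
    groups: pd.Series | None = None,
    factors: pd.Series | None = None,
    shrink: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion alpha, variance = mu + alpha * mu^2.

    Method-of-moments on size-factor-normalized counts,
    alpha_hat = max(0, (s^2 - mean) / mean^2), computed within each level of
    ``groups`` (so planted group differences do not inflate alpha) and
    pooled by residual degrees of freedom. The raw estimates are then shrunk
    by weight ``shrink`` toward a fitted a0 + a1/mean trend, the usual
    mean-dispersion relationship of RNA-seq counts.

    All-zero genes have undefined dispersion and come back as NaN.
    """
    if factors is None:
        factors = compute_size_factors(counts)
    Q = counts.values / factors.reindex(counts.sample_ids).to_numpy()[None, :]
    if groups is None:
        groups = pd.Series("all", index=counts.sample_ids)
    else:
        groups = groups.reindex(counts.sample_ids)

    num = np.zeros(Q.shape[0])
    den = 0.0
    overall_mean = Q.mean(axis=1)
    for level in groups.unique():
        sel = (groups == level).to_numpy()
        if sel.sum() < 2:
            continue
        q = Q[:, sel]
        mu = q.mean(axis=1)
        s2 = q.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), np.nan)
        w = sel.sum() - 1
        num += np.where(np.isnan(a), 0.0, a) * w
        den += w
    if den == 0:
        raise ValueError("need >= 2 samples in at least one group")
    raw = num / den
    raw[overall_mean == 0] = np.nan

    ok = np.isfinite(raw) & (overall_mean > 0)
    if shrink > 0 and ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / overall_mean[ok]])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        trend = np.maximum(0.0, coef[0] + coef[1] / np.maximum(overall_mean, 1e-8))
        est = (1.0 - shrink) * raw + shrink * trend
        est[~np.isfinite(raw)] = np.nan
    else:
        est = raw
    return pd.Series(est, index=counts.gene_ids, name="dispersion")


def nb_lrt(
    counts: CountMatrix,
    samples: SampleTable,
    design: DesignSpec = DesignSpec(),
    contrast: tuple[str, str] = ("SZ", "CTL"),
    dispersions: pd.Series | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of ``contrast`` (case, control).

    Fits the full model ~ covariates + Disorder and the reduced model
    ~ covariates by maximum likelihood at fixed per-gene dispersion, with
    log size factors as offsets. The LRT statistic 2(l_full - l_reduced) is
    referred to chi-square(1); log2FC comes from the Disorder coefficient
    (case relative to control). Genes whose optimizer did not converge are
    flagged and excluded from FDR adjustment downstream.

    Returns a DETable DataFrame indexed by gene with columns
    baseMean, log2FC, dispersion, pvalue, padj (NaN until
    :func:`filter_and_adjust`), converged.
    """
    case, control = contrast
    meta = samples.table
    present = set(meta[design.factor])
    if case not in present or control not in present:
        raise ValueError(f"contrast levels {contrast} not both present")
    keep = meta[design.factor].isin([case, control])
    meta = meta.loc[keep]
    sub = CountMatrix(counts.counts.loc[:, meta.index])
    for c in design.covariates:
        if meta[c].isna().any():
            raise ValueError(f"covariate {c} has missing values")

    if factors is None:
        factors = compute_size_factors(sub)
    factors = factors.reindex(meta.index)
    if dispersions is None:
        dispersions = estimate_dispersions(sub, groups=meta[design.factor], factors=factors)
    disp = dispersions.reindex(sub.gene_ids).to_numpy(float)

    Y = sub.values.astype(float)
    offset = np.log(factors.to_numpy(float))
    base_mean = (Y / np.exp(offset)[None, :]).mean(axis=1)

    X_full, cols = _design_matrix(meta, design.covariates, design.factor, case)
    X_red, _ = _design_matrix(meta, design.covariates)
    coef_idx = len(cols) - 1

    testable = np.isfinite(disp) & (Y.sum(axis=1) > 0)
    G = Y.shape[0]
    log2fc = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    stat_out = np.full(G, np.nan)
    conv = np.zeros(G, dtype=bool)

    if testable.any():
        Yt = Y[testable]
        at = disp[testable]
        beta_f, ll_f, conv_f = _fit_glm_batch(Yt, X_full, offset, at)
        beta_r, ll_r, conv_r = _fit_glm_batch(Yt, X_red, offset, at)
        stat = 2.0 * (ll_f - ll_r)
        ok = conv_f & conv_r & (stat > -1e-6)
        stat = np.maximum(stat, 0.0)
        log2fc[testable] = beta_f[:, coef_idx] / np.log(2.0)
        stat_out[testable] = stat
        pval[testable] = sps.chi2.sf(stat, df=1)
        conv[testable] = ok

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "dispersion": disp,
            "lrt_stat": stat_out,
            "pvalue": pval,
            "padj": np.nan,
            "converged": conv,
        },
        index=sub.gene_ids,
    )


def filter_and_adjust(de: pd.DataFrame, min_base_mean: float = 10.0) -> pd.DataFrame:
    """Independent filtering + BH adjustment.

    Genes below the baseMean floor, or flagged non-convergent, are excluded
    from the multiple-testing adjustment (padj left missing); the rest get
    Benjamini-Hochberg adjusted p-values.
    """
    out = de.copy()
    eligible = (
        (out["baseMean"] >= min_base_mean)
        & out["converged"].astype(bool)
        & out["pvalue"].notna()
    )
    out["padj"] = np.nan
    if eligible.any():
        out.loc[eligible, "padj"] = bh_adjust(out.loc[eligible, "pvalue"].to_numpy())
    return out


def crossdisorder_concordance(
    de_a: pd.DataFrame, de_b: pd.DataFrame, p_threshold: float = 0.05
):
    """Concordance of two case-control comparisons over their shared genes.

    Returns a dict with the Spearman rho of log2 fold changes, the counts
    of genes under the uncorrected p threshold in each table and in both,
    and the Fisher exact test of the overlap against the shared universe.
    """
    shared = de_a.index.intersection(de_b.index)
    shared = shared[
        de_a.loc[shared, "log2FC"].notna() & de_b.loc[shared, "log2FC"].notna()
    ]
    if len(shared) == 0:
        raise ValueError("no shared genes between the two DE tables")
    rho, rho_p = spearman(
        de_a.loc[shared, "log2FC"].to_numpy(), de_b.loc[shared, "log2FC"].to_numpy()
    )
    sig_a = set(shared[de_a.loc[shared, "pvalue"] < p_threshold])
    sig_b = set(shared[de_b.loc[shared, "pvalue"] < p_threshold])
    both = sig_a & sig_b
    ov = overlap_test(len(both), len(sig_a), len(sig_b), len(shared), method="fisher")
    return {
        "rho": rho,
        "rho_p": rho_p,
        "n_shared": len(shared),
        "n_sig_a": len(sig_a),
        "n_sig_b": len(sig_b),
        "n_sig_both": len(both),
        "overlap_test": ov,
    }
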