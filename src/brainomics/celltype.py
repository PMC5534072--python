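"""Marker-gene cell-type composition analysis.

A cell-type *index* for a sample is the median normalized expression of
that cell type's marker genes; under the proportionality assumption the
predicted cell proportion is simply observed index / purified-tissue
index. The module provides the in-silico mixing benchmark (hypergeometric
count down-sampling of purified profiles), the size-matched and
expression-matched null resampling schemes, the fold-change-vs-specificity
correlation, and a constrained least-squares deconvolution cross-check.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .normalize import NormalizedMatrix
from .stats import spearman

__all__ = [
    "compute_index",
    "downsample_counts",
    "mix_in_silico",
    "predict_proportion",
    "null_index_mse",
    "expression_matched_candidates",
    "matched_null_fold_change",
    "specificity_correlation",
    "ls_deconvolve",
]


def _as_frame(norm) -> pd.DataFrame:
    return norm.values if isinstance(norm, NormalizedMatrix) else norm


def compute_index(norm, signature: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Per-sample cell-type indices: median normalized marker expression.

    Markers absent from the matrix are dropped with a warning; a cell type
    with no surviving marker is an error. Returns samples x cell types.
    """
    values = _as_frame(norm)
    out = {}
    for cell_type, markers in signature.items():
        markers = list(markers)
        present = [g for g in markers if g in values.index]
        if not present:
            raise ValueError(f"no markers of cell type {cell_type!r} in the matrix")
        if len(present) < len(markers):
            warnings.warn(
                f"{cell_type}: {len(markers) - len(present)} marker(s) absent, dropped",
                stacklevel=2,
            )
        out[cell_type] = values.loc[present].median(axis=0)
    return pd.DataFrame(out)


def downsample_counts(counts_vec, target_total: int, rng) -> np.ndarray:
    """Randomly down-sample a count vector to exactly ``target_total`` reads.

    Sampling is without replacement across reads (multivariate
    hypergeometric), so the output is elementwise <= the input and sums to
    the target exactly.
    """
    vec = np.asarray(counts_vec)
    if np.any(vec < 0) or not np.issubdtype(vec.dtype, np.integer):
        vec = vec.astype(np.int64)
        if np.any(vec < 0):
            raise ValueError("counts must be non-negative integers")
    total = int(vec.sum())
    if not (0 <= target_total <= total):
        raise ValueError(f"target {target_total} outside [0, {total}]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    out = rng.multivariate_hypergeometric(vec, int(target_total), method="marginals")
    assert out.sum() == target_total and np.all(out <= vec)
    return out


def mix_in_silico(
    pure_vectors: Mapping[str, np.ndarray],
    weights: Mapping[str, float],
    rng,
) -> tuple[np.ndarray, dict[str, int]]:
    """Construct a pseudo-bulk mixture from purified count vectors.

    Each purified vector (all sharing gene order and, by the benchmark's
    construction, an equal total) is down-sampled to round(weight * total)
    reads and the results are summed gene-wise. Returns the mixed counts
    and the per-cell-type read targets actually used.
    """
    names = list(pure_vectors)
    w = np.array([weights[c] for c in names], float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be >= 0 and sum to 1")
    lengths = {len(pure_vectors[c]) for c in names}
    if len(lengths) != 1:
        raise ValueError("purified vectors must share gene order/length")
    totals = {c: int(np.sum(pure_vectors[c])) for c in names}
    common_total = totals[names[0]]
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    targets = {c: int(round(weights[c] * common_total)) for c in names}
    mixed = np.zeros(lengths.pop(), dtype=np.int64)
    for c in names:
        if targets[c] > 0:
            mixed += downsample_counts(pure_vectors[c], targets[c], rng)
    return mixed, targets


def predict_proportion(observed_index: float, purified_index: float):
    """Predicted cell proportion = observed index / purified-tissue index.

    Returns ``(estimate, clamped)`` where clamped is the estimate truncated
    to [0, 1]; the raw ratio is kept for diagnostics.
    """
    if purified_index <= 0:
        raise ValueError("purified index must be positive")
    est = observed_index / purified_index
    return est, float(np.clip(est, 0.0, 1.0))


def _index_predictions(values, pure_values, gene_sets: Mapping[str, Sequence[str]]):
    """Predicted proportions (mixtures x cell types) for given marker sets."""
    preds = {}
    for cell_type, genes in gene_sets.items():
        sub = values.loc[list(genes)]
        obs = sub.median(axis=0)
        pure = pure_values.loc[list(genes), cell_type].median()
        if pure <= 0:
            raise ValueError(f"non-positive purified index for {cell_type}")
        preds[cell_type] = obs / pure
    return pd.DataFrame(preds)


def null_index_mse(
    norm_mixes,
    pure_norm: pd.DataFrame,
    true_weights: pd.DataFrame,
    signature: Mapping[str, Sequence[str]],
    n_null: int = 1000,
    rng=None,
):
    """Compare marker-index mixing-weight prediction against random gene sets.

    ``norm_mixes``: normalized expression of the in-silico mixtures (genes x
    mixtures); ``pure_norm``: normalized expression of the purified samples
    (genes x cell types) on the same normalization; ``true_weights``:
    mixtures x cell types. The observed MSE is the mean squared
    (predicted - true) proportion over all mixtures and cell types. Each of
    ``n_null`` replicates swaps every marker set for a size-matched uniform
    draw from the expressed genes and recomputes the MSE. Empirical
    p = (1 + #{null <= observed}) / (n_null + 1).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    values = _as_frame(norm_mixes)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sig = {c: [g for g in genes if g in values.index] for c, genes in signature.items()}
    for c, genes in sig.items():
        if not genes:
            raise ValueError(f"no markers of {c!r} present")

    expressed = values.index[(values.to_numpy() > 0).any(axis=1)]
    sizes = {c: len(g) for c, g in sig.items()}
    if max(sizes.values()) > len(expressed):
        raise ValueError("fewer expressed genes than the marker set size")

    def mse(gene_sets):
        pred = _index_predictions(values, pure_norm, gene_sets)
        pred = pred[true_weights.columns]
        return float(((pred.to_numpy() - true_weights.to_numpy()) ** 2).mean())

    observed = mse(sig)
    null_mses = np.empty(n_null)
    expressed_arr = np.asarray(expressed)
    for i in range(n_null):
        draw = {
            c: expressed_arr[rng.choice(len(expressed_arr), size=sizes[c], replace=False)]
            for c in sig
        }
        null_mses[i] = mse(draw)
    p = (1 + int(np.sum(null_mses <= observed))) / (n_null + 1)
    return observed, null_mses, p


def expression_matched_candidates(
    de: pd.DataFrame,
    members: Sequence[str],
    expr_tol: float = 0.05,
    widen_on_failure: bool = True,
):
    """Per-member candidate pools for expression-matched null sampling.

    Candidates for a member are the non-member genes whose baseMean lies
    within relative tolerance ``expr_tol`` of the member's. If a member has
    no candidate the tolerance is doubled with a warning (or an error is
    raised when ``widen_on_failure`` is False). Returns ``(pool,
    candidate_index_arrays)`` with indices into ``pool``.
    """
    bm = de["baseMean"]
    lfc = de["log2FC"]
    pool = de.index.difference(pd.Index(list(members)))
    pool = pool[lfc.loc[pool].notna() & bm.loc[pool].notna()]
    pool_bm = bm.loc[pool].to_numpy()
    candidates = []
    for g in members:
        tol = expr_tol
        while True:
            lo, hi = bm[g] * (1 - tol), bm[g] * (1 + tol)
            idx = np.flatnonzero((pool_bm >= lo) & (pool_bm <= hi))
            if idx.size > 0:
                break
            if not widen_on_failure:
                raise ValueError(
                    f"gene {g}: no expression-matched candidate within {tol:.0%}"
                )
            tol *= 2
            warnings.warn(
                f"gene {g}: widening expression-match tolerance to {tol:.0%}",
                stacklevel=2,
            )
        candidates.append(idx)
    return pool, candidates


def matched_null_fold_change(
    de: pd.DataFrame,
    gene_set: Sequence[str],
    n_null: int = 1000,
    expr_tol: float = 0.05,
    rng=None,
    widen_on_failure: bool = True,
):
    """Empirical test of a gene set's median fold change against
    expression-matched null sets.

    Each null set replaces every member with a random gene whose baseMean is
    within relative tolerance ``expr_tol`` (default 5%) of that member's,
    drawn without replacement within the null set and excluding the set
    itself. The statistic is the median log2FC; the p-value is two-sided
    empirical with the add-one correction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    members = [g for g in gene_set if g in de.index]
    if len(members) == 0:
        raise ValueError("no gene-set member has a DE record")
    lfc = de["log2FC"]
    pool, candidates = expression_matched_candidates(
        de, members, expr_tol, widen_on_failure
    )
    observed = float(np.nanmedian(lfc.loc[members].to_numpy()))
    pool_lfc = lfc.loc[pool].to_numpy()
    null_medians = np.empty(n_null)
    for i in range(n_null):
        used: set[int] = set()
        picked = np.empty(len(members), dtype=np.int64)
        for j, idx in enumerate(candidates):
            free = idx[~np.isin(idx, list(used))] if used else idx
            choice = int(rng.choice(free if free.size else idx))
            used.add(choice)
            picked[j] = choice
        null_medians[i] = np.median(pool_lfc[picked])
    p_low = (1 + int(np.sum(null_medians <= observed))) / (n_null + 1)
    p_high = (1 + int(np.sum(null_medians >= observed))) / (n_null + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return observed, null_medians, p


def specificity_correlation(
    de: pd.DataFrame,
    profile_means: pd.DataFrame,
    cell_type: str,
    pseudocount: float = 1e-3,
):
    """Spearman correlation between case/control log2FC and cell-type
    specificity.

    Specificity of a gene = log2(mean expression in ``cell_type`` / mean
    over the other cell types), from a purified-profile table (genes x
    cell types). A pseudocount guards zero denominators.
    """
    if cell_type not in profile_means.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    shared = de.index.intersection(profile_means.index)
    shared = shared[de.loc[shared, "log2FC"].notna()]
    if len(shared) < 10:
        raise ValueError("need >= 10 shared genes")
    own = profile_means.loc[shared, cell_type].to_numpy(float)
    others = profile_means.loc[shared].drop(columns=[cell_type]).mean(axis=1).to_numpy()
    spec = np.log2((own + pseudocount) / (others + pseudocount))
    return spearman(spec, de.loc[shared, "log2FC"].to_numpy())


def ls_deconvolve(
    mixture_norm: pd.DataFrame, reference_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Constrained least squares deconvolution (deconRNAseq-style).

    Solves min ||x - S w||^2 subject to w >= 0, sum(w) = 1 per sample, via
    non-negative least squares with the sum constraint appended as a
    heavily weighted row. Returns samples x cell types weights.
    """
    shared = mixture_norm.index.intersection(reference_profiles.index)
    S = reference_profiles.loc[shared].to_numpy(float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError("reference profiles are rank-deficient on shared genes")
    lam = 1e4 * max(1.0, float(np.abs(S).max()))
    S_aug = np.vstack([S, lam * np.ones(S.shape[1])])
    out = {}
    for sample in mixture_norm.columns:
        x = mixture_norm.loc[shared, sample].to_numpy(float)
        w, _ = nnls(S_aug, np.concatenate([x, [lam]]))
        total = w.sum()
        out[sample] = w / total if total > 0 else w
    return pd.DataFrame(out, index=reference_profiles.columns).T
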