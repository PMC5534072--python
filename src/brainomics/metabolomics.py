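"""Metabolite-level statistics: per-comparison rank-sum tests with FDR,
top-metabolite clustering, and metabolite-ratio vs gene-expression
correlations (the GABA:glutamate vs GAD1/GAD2 style analysis).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MetaboliteMatrix, SampleTable
from .normalize import NormalizedMatrix, zscore_rows
from .stats import bh_adjust, rank_sum_test, spearman, ward_cluster

__all__ = ["metab_diff", "top_k_clustering", "ratio_correlation"]


def average_technical_replicates(
    mm: MetaboliteMatrix, subject_of: Mapping[str, str]
) -> MetaboliteMatrix:
    """Collapse technical replicate columns to per-subject means.

    ``subject_of`` maps each replicate sample id to its subject id; the
    result has one column per subject, averaging avoids pseudo-replication
    in the group tests.
    """
    groups = pd.Series({s: subject_of[s] for s in mm.sample_ids})
    collapsed = mm.abundances.T.groupby(groups).mean().T
    return MetaboliteMatrix(collapsed)


def metab_diff(
    mm: MetaboliteMatrix,
    samples: SampleTable,
    comparison: tuple[str, str],
    test: str = "ranksum",
) -> pd.DataFrame:
    """Two-sided per-metabolite group test with BH FDR across metabolites.

    ``comparison`` is a (case, control) diagnosis pair. The default test is
    the Wilcoxon rank-sum, so results are invariant to monotone rescaling
    of each metabolite; a Welch t-test is available via ``test='ttest'``.
    Constant metabolites get p = 1 and are flagged.
    """
    case, control = comparison
    meta = samples.table.reindex(mm.sample_ids)
    ix_case = meta.index[meta["diagnosis"] == case]
    ix_ctrl = meta.index[meta["diagnosis"] == control]
    if len(ix_case) < 3 or len(ix_ctrl) < 3:
        raise ValueError("need >= 3 samples per group")
    rows = []
    for met in mm.metabolite_ids:
        x = mm.abundances.loc[met, ix_case].to_numpy(float)
        y = mm.abundances.loc[met, ix_ctrl].to_numpy(float)
        if np.ptp(np.concatenate([x, y])) == 0:
            rows.append((met, np.nan, 1.0, np.median(x), np.median(y), True))
            continue
        if test == "ranksum":
            res = rank_sum_test(x, y, tail="two-sided")
            stat, p = res.statistic, res.p_value
        elif test == "ttest":
            from scipy import stats as sps

            stat, p = sps.ttest_ind(x, y, equal_var=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append((met, float(stat), float(p), np.median(x), np.median(y), False))
    out = pd.DataFrame(
        rows,
        columns=["metabolite", "statistic", "pvalue", "median_case", "median_ctrl", "constant"],
    ).set_index("metabolite")
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def top_k_clustering(
    mm: MetaboliteMatrix,
    results: Mapping[str, pd.DataFrame],
    k: int = 10,
    n_clusters: int = 2,
    log_transform: bool = True,
):
    """Cluster samples on the union of each comparison's top-k metabolites.

    Per comparison, the k most significant metabolites are selected (ties
    broken lexicographically by metabolite id); the union is deduplicated.
    Abundances are log-transformed (log2(x+1)) by default, z-scored per
    metabolite, and samples are Ward/Euclidean clustered.

    Returns ``(selected_ids, labels, linkage)``.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 comparisons")
    selected: list[str] = []
    for name in results:
        tab = results[name]
        if len(tab) < k:
            warnings.warn(
                f"{name}: only {len(tab)} metabolites (< k={k}); taking all",
                stacklevel=2,
            )
        # deterministic tie-break: p ascending, then metabolite id
        order = tab.assign(_id=tab.index).sort_values(["pvalue", "_id"], kind="stable")
        for met in order.index[:k]:
            if met not in selected:
                selected.append(met)
    X = mm.abundances.loc[selected]
    if log_transform:
        X = np.log2(X + 1.0)
    Z, _ = zscore_rows(X)
    linkage, labels = ward_cluster(Z.T.to_numpy(), k=n_clusters)
    return selected, pd.Series(labels, index=mm.sample_ids), linkage


def ratio_correlation(
    mm: MetaboliteMatrix,
    numerator_id: str,
    denominator_id: str,
    norm: NormalizedMatrix | pd.DataFrame,
    gene_ids: Sequence[str],
):
    """Spearman correlation of a metabolite abundance ratio with mean gene
    expression across shared samples.

    Samples with a zero denominator abundance are dropped with a warning.
    Returns (rho, p); (nan, nan) when the predictor is constant.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    missing = [g for g in gene_ids if g not in values.index]
    if missing:
        raise ValueError(f"genes not in expression matrix: {missing}")
    shared = mm.abundances.columns.intersection(values.columns)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    num = mm.abundances.loc[numerator_id, shared].to_numpy(float)
    den = mm.abundances.loc[denominator_id, shared].to_numpy(float)
    keep = den > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} sample(s) with zero denominator",
            stacklevel=2,
        )
    ratio = num[keep] / den[keep]
    predictor = values.loc[list(gene_ids), shared].mean(axis=0).to_numpy()[keep]
    return spearman(ratio, predictor)
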