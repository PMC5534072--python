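"""Threshold-free integrated pathway enrichment.

Per omics layer, a pathway's member features are tested for lower p-value
ranks than the non-member background with a one-tailed Wilcoxon rank-sum
test; the gene-layer and metabolite-layer p-values are then combined with
Fisher's method (chi-square with 4 df). Only pathways with more than five
measured genes and at least one measured metabolite enter the analysis,
and BH adjustment is applied across the surviving pathways' combined
p-values.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Pathway
from .stats import bh_adjust, rank_sum_test

__all__ = ["rank_wilcox_enrich", "fisher_combine", "integrated_enrichment"]

_TINY_P = np.nextafter(0.0, 1.0)


def rank_wilcox_enrich(feature_p: pd.Series, members: Iterable[str]) -> float:
    """One-tailed Wilcoxon test that member features have lower p-values
    than the non-member background.

    Rank-based, hence invariant to any strictly monotone transform of the
    feature p-values. Features without a defined p are ignored.
    """
    p = feature_p.dropna()
    members = set(members) & set(p.index)
    if not members:
        raise ValueError("no pathway member has a defined p-value")
    background = p.index.difference(pd.Index(members))
    if len(background) == 0:
        raise ValueError("pathway covers every measured feature: no background")
    res = rank_sum_test(
        p.loc[list(members)].to_numpy(),
        p.loc[background].to_numpy(),
        tail="lower",
    )
    return res.p_value


def fisher_combine(p_a: float, p_b: float) -> float:
    """Fisher's method for two independent p-values.

    X = -2(ln p_a + ln p_b) ~ chi-square(4) under the joint null; returns
    the upper tail at X. Zero inputs are clamped to the smallest positive
    float with a warning.
    """
    ps = []
    for p in (p_a, p_b):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0.0:
            warnings.warn("p=0 clamped to the smallest positive float", stacklevel=2)
            p = _TINY_P
        ps.append(p)
    X = -2.0 * (math.log(ps[0]) + math.log(ps[1]))
    # clamp underflow so the result stays in (0, 1]
    return max(float(sps.chi2.sf(X, df=4)), _TINY_P)


def integrated_enrichment(
    de: pd.DataFrame,
    metab_p: pd.Series,
    pathways: Sequence[Pathway],
    min_genes: int = 6,
    min_metabs: int = 1,
) -> pd.DataFrame:
    """Integrated gene + metabolite pathway enrichment.

    ``de`` supplies the uncorrected gene-level p-values (column ``pvalue``);
    ``metab_p`` the per-metabolite p-values. Pathways with fewer than
    ``min_genes`` measured genes (default 6, i.e. strictly more than five)
    or fewer than ``min_metabs`` measured metabolites are excluded. For
    each survivor both layers are tested with
    :func:`rank_wilcox_enrich`, combined with :func:`fisher_combine`, and
    BH-adjusted across survivors. Sorted by combined p ascending.
    """
    gene_p = de["pvalue"].dropna()
    metab_p = metab_p.dropna()
    rows = []
    for pw in pathways:
        genes = [g for g in pw.gene_members if g in gene_p.index]
        metabs = [m for m in pw.metabolite_members if m in metab_p.index]
        if len(genes) < min_genes or len(metabs) < min_metabs:
            continue
        pg = rank_wilcox_enrich(gene_p, genes)
        pm = rank_wilcox_enrich(metab_p, metabs)
        rows.append((pw.id, len(genes), len(metabs), pg, pm, fisher_combine(pg, pm)))
    out = pd.DataFrame(
        rows,
        columns=[
            "pathway",
            "n_genes_measured",
            "n_metabolites_measured",
            "p_gene",
            "p_metabolite",
            "p_combined",
        ],
    ).set_index("pathway")
    if len(out):
        out["padj_combined"] = bh_adjust(out["p_combined"].to_numpy())
        out = out.sort_values("p_combined", kind="stable")
    else:
        out["padj_combined"] = pd.Series(dtype=float)
    return out
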