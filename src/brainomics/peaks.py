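"""Consensus ChIP-peak construction and TSS proximity statistics.

Consensus peaks are the intervals of a reference (first) peak set that
overlap, by at least ``min_overlap`` bp, at least one interval in *every*
other replicate set — the chained `bedtools intersect -u` semantics that
produce a filtered reference list rather than fragment intersections. A
region-intersection mode is available behind a flag.

Distances are unstranded absolute gaps on the half-open convention: a TSS
at position t and a peak [s, e) are at distance 0 when s <= t < e, else
min(s - t, t - e).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GenomicInterval
from .stats import rank_sum_test

__all__ = [
    "consensus_peaks",
    "nearest_peak_distance",
    "proximity_sweep",
]


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        trees[iv.chrom].addi(iv.start, iv.end)
    return trees


def consensus_peaks(
    peak_sets: Sequence[Sequence[GenomicInterval]],
    min_overlap: int = 1,
    mode: str = "anchored",
) -> list[GenomicInterval]:
    """Peaks supported across all replicate sets.

    ``anchored`` (default): returns the intervals of the FIRST set that
    overlap by >= ``min_overlap`` bp with some interval in every other set,
    sorted by (chrom, start). ``region``: returns the base-level
    intersection regions common to all sets (min_overlap filters the
    resulting fragment lengths).
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1 bp")
    first = list(peak_sets[0])
    if not first:
        warnings.warn("first peak set is empty; consensus is empty", stacklevel=2)
        return []
    if mode == "anchored":
        other_trees = [_build_trees(s) for s in peak_sets[1:]]
        out = []
        for iv in first:
            ok = True
            for trees in other_trees:
                hits = trees[iv.chrom].overlap(iv.start, iv.end)
                if not any(
                    min(iv.end, h.end) - max(iv.start, h.begin) >= min_overlap
                    for h in hits
                ):
                    ok = False
                    break
            if ok:
                out.append(iv)
        return sorted(out, key=lambda i: (i.chrom, i.start, i.end))
    if mode == "region":
        merged = _merge_covered(peak_sets[0])
        for s in peak_sets[1:]:
            merged = _intersect_covered(merged, _merge_covered(s))
        return sorted(
            (
                GenomicInterval(c, s, e)
                for c, ivs in merged.items()
                for s, e in ivs
                if e - s >= min_overlap
            ),
            key=lambda i: (i.chrom, i.start, i.end),
        )
    raise ValueError(f"unknown mode {mode!r}")


def _merge_covered(intervals):
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [tuple(x) for x in merged]
    return out


def _intersect_covered(a, b):
    out = {}
    for chrom in set(a) & set(b):
        res, i, j = [], 0, 0
        A, B = a[chrom], b[chrom]
        while i < len(A) and j < len(B):
            s = max(A[i][0], B[j][0])
            e = min(A[i][1], B[j][1])
            if s < e:
                res.append((s, e))
            if A[i][1] < B[j][1]:
                i += 1
            else:
                j += 1
        if res:
            out[chrom] = res
    return out


def nearest_peak_distance(
    tss: pd.DataFrame, peaks: Sequence[GenomicInterval]
) -> pd.Series:
    """Distance in bp from each gene's TSS to the nearest peak on its
    chromosome.

    0 when the TSS lies inside a peak; genes on chromosomes without any
    peak get NaN (undefined, excluded downstream). ``tss`` is the TSSTable
    DataFrame from :func:`brainomics.io.read_tss`.
    """
    if not peaks:
        raise ValueError("empty peak list")
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in peaks:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    # sorted starts with cumulative-max ends handle overlapping peaks
    prepared = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        prepared[chrom] = (starts, ends)

    out = np.full(len(tss), np.nan)
    positions = tss["tss"].to_numpy(np.int64)
    chroms = tss["chrom"].to_numpy()
    for i, (chrom, pos) in enumerate(zip(chroms, positions)):
        if chrom not in prepared:
            continue
        starts, ends = prepared[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        dist_left = np.inf
        if idx >= 0:
            if ends[idx] > pos:  # inside some peak starting at or before pos
                out[i] = 0.0
                continue
            dist_left = pos - ends[idx]
        dist_right = starts[idx + 1] - pos if idx + 1 < len(starts) else np.inf
        out[i] = min(dist_left, dist_right)
    return pd.Series(out, index=tss.index, name="distance")


def proximity_sweep(
    de: pd.DataFrame,
    distances: pd.Series,
    thresholds: Sequence[int] = (1000, 2000, 5000, 10000, 20000, 50000),
) -> pd.DataFrame:
    """Near-vs-far rank-sum tests at increasing TSS-to-peak distance cutoffs.

    At each threshold t, "near" genes have distance <= t (ties are near) and
    "far" genes the complement among genes with a defined distance. Two
    one-tailed tests per threshold: that near genes have lower DE p-values
    (stronger differential expression), and that near genes have lower
    log2 fold changes (reduced expression in cases). Thresholds where a
    side is empty are reported with NaN p-values.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    shared = de.index.intersection(distances.index)
    d = distances.loc[shared]
    d = d[d.notna()]
    sub = de.loc[d.index]
    ok = sub["pvalue"].notna() & sub["log2FC"].notna()
    sub, d = sub.loc[ok], d.loc[ok]

    rows = []
    prev_near = -1
    for t in thresholds:
        near = d <= t
        n_near, n_far = int(near.sum()), int((~near).sum())
        assert n_near >= prev_near, "n_near must be monotone in threshold"
        prev_near = n_near
        if n_near == 0 or n_far == 0:
            rows.append((t, n_near, n_far, np.nan, np.nan))
            continue
        p_de = rank_sum_test(
            sub.loc[near, "pvalue"], sub.loc[~near, "pvalue"], tail="lower"
        ).p_value
        p_expr = rank_sum_test(
            sub.loc[near, "log2FC"], sub.loc[~near, "log2FC"], tail="lower"
        ).p_value
        rows.append((t, n_near, n_far, p_de, p_expr))
    return pd.DataFrame(
        rows, columns=["threshold", "n_near", "n_far", "p_de", "p_expr"]
    )
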