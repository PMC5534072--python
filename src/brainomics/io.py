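"""Readers and writers for the external formats the pipeline touches.

Count and metabolite matrices travel as TSV (features in rows, samples in
columns), gene sets as GMT, ChIP peaks as BED3+/narrowPeak, and TSS
annotations as either a plain TSV or gene-level GTF lines ("gtf-lite").
All genomic coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleTable",
    "MetaboliteMatrix",
    "Pathway",
    "GenomicInterval",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_metabolites",
    "write_metabolites",
    "read_sample_table",
    "write_sample_table",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "read_tss",
    "write_tss",
    "read_pathways_gmt",
    "write_pathways_gmt",
]

DIAGNOSES = ("CTL", "SZ", "BPD", "MDD")
REGIONS = ("AnCg", "DLPFC", "nAcc")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; ``payload`` keeps extra narrowPeak columns."""

    chrom: str
    start: int
    end: int
    payload: tuple = ()

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CountMatrix:
    """Integer gene x sample read counts."""

    counts: pd.DataFrame  # genes x samples, non-negative integers

    def __post_init__(self):
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be integral")
        self.counts = df.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()


@dataclass
class MetaboliteMatrix:
    """Non-negative real metabolite x sample abundances."""

    abundances: pd.DataFrame

    def __post_init__(self):
        df = self.abundances
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("metabolite and sample ids must be unique")
        if np.any(df.to_numpy() < 0):
            raise ValueError("abundances must be non-negative")
        self.abundances = df.astype(float)

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.abundances.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundances.columns


@dataclass
class SampleTable:
    """Per-sample metadata: diagnosis, region and the covariates used downstream.

    PRUA is the percentage of reads uniquely aligned, stored as a fraction
    in [0, 1]; it is the alignment-quality covariate that gets regressed out
    of normalized expression.
    """

    table: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("diagnosis", "region", "age", "pH", "PMI", "PRUA")

    def __post_init__(self):
        df = self.table
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample table")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        bad_dx = set(df["diagnosis"]) - set(DIAGNOSES)
        if bad_dx:
            raise ValueError(f"unknown diagnosis values: {sorted(bad_dx)}")
        bad_rg = set(df["region"]) - set(REGIONS)
        if bad_rg:
            raise ValueError(f"unknown region values: {sorted(bad_rg)}")
        prua = df["PRUA"].to_numpy(float)
        if np.any((prua < 0) | (prua > 1)):
            raise ValueError("PRUA must lie in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index


@dataclass(frozen=True)
class Pathway:
    """A named unit with gene members and metabolite members."""

    id: str
    name: str
    gene_members: frozenset = frozenset()
    metabolite_members: frozenset = frozenset()

    def __post_init__(self):
        if not self.gene_members and not self.metabolite_members:
            raise ValueError(f"pathway {self.id} has no members in either layer")


# ---------------------------------------------------------------------------
# TSV matrices


def _read_matrix_tsv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap for a uniform error type
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    return df


def read_counts(path) -> CountMatrix:
    """Read a gene x sample TSV of integer counts (first column = gene ids)."""
    df = _read_matrix_tsv(path)
    try:
        return CountMatrix(df)
    except ValueError as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metabolites(path) -> MetaboliteMatrix:
    return MetaboliteMatrix(_read_matrix_tsv(path))


def write_metabolites(mm: MetaboliteMatrix, path) -> None:
    mm.abundances.to_csv(path, sep="\t", index_label="metabolite_id")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleTable(df)


def write_sample_table(st: SampleTable, path) -> None:
    st.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT file into ``(name, description, members)`` records.

    Members are de-duplicated per line, first occurrence order kept.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member ({len(fields)} fields found)"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            seen: dict[str, None] = {}
            for m in members:
                if m:
                    seen.setdefault(m)
            out.append((name, desc, list(seen)))
    return out


def write_gmt(sets: Iterable[tuple[str, str, Sequence[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, desc, members in sets:
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ / narrowPeak; columns beyond the first three are kept as payload."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                out.append(GenomicInterval(fields[0], start, end, tuple(fields[3:])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), *map(str, iv.payload)]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSS tables


def read_tss(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read per-gene TSS positions.

    ``tsv``: columns gene_id, chrom, tss, strand.
    ``gtf-lite``: GTF ``gene`` feature lines; the TSS is the 5' end of the
    gene body converted to a 0-based position (start-1 on ``+``, end-1 on
    ``-``, since GTF is 1-based closed).

    Returns a DataFrame indexed by gene_id with columns chrom, tss, strand.
    Duplicate gene ids keep the first occurrence with a warning.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        need = {"gene_id", "chrom", "tss", "strand"}
        if not need.issubset(df.columns):
            raise FormatError(f"{path}: TSS TSV needs columns {sorted(need)}")
        records = df[["gene_id", "chrom", "tss", "strand"]].itertuples(index=False)
    elif dialect == "gtf-lite":
        records = list(_iter_gtf_genes(path))
    else:
        raise ValueError(f"unknown TSS dialect {dialect!r}")

    rows, seen = [], set()
    for gene_id, chrom, tss, strand in records:
        if strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {gene_id} has invalid strand {strand!r}")
        if gene_id in seen:
            warnings.warn(f"duplicate gene_id {gene_id}; keeping first", stacklevel=2)
            continue
        seen.add(gene_id)
        rows.append((gene_id, chrom, int(tss), strand))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return out.set_index("gene_id")


def _iter_gtf_genes(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: GTF line has <9 columns")
            if fields[2] != "gene":
                continue
            chrom, start, end, strand, attrs = (
                fields[0],
                int(fields[3]),
                int(fields[4]),
                fields[6],
                fields[8],
            )
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene line without gene_id")
            # GTF is 1-based closed; 0-based TSS is start-1 (+) or end-1 (-)
            tss = start - 1 if strand == "+" else end - 1
            yield gene_id, chrom, tss, strand


def write_tss(tss: pd.DataFrame, path) -> None:
    tss.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Extended GMT for gene+metabolite pathways


def read_pathways_gmt(path) -> list[Pathway]:
    """Read pathways from an extended GMT with two record types per pathway.

    The description field declares the omics layer: lines
    ``<id>\\tgenes\\tG1\\tG2...`` and ``<id>\\tmetabolites\\tM1...`` are
    joined on the pathway id. A pathway may have either or both record types.
    """
    genes: dict[str, list[str]] = {}
    metabs: dict[str, list[str]] = {}
    order: list[str] = []
    for name, desc, members in read_gmt(path):
        layer = desc.strip().lower()
        if layer == "genes":
            target = genes
        elif layer == "metabolites":
            target = metabs
        else:
            raise FormatError(
                f"{path}: pathway {name!r} has unknown layer {desc!r} "
                "(expected 'genes' or 'metabolites')"
            )
        if name not in order:
            order.append(name)
        if name in target:
            raise FormatError(f"{path}: duplicate {layer} record for pathway {name!r}")
        target[name] = members
    return [
        Pathway(
            id=pid,
            name=pid,
            gene_members=frozenset(genes.get(pid, ())),
            metabolite_members=frozenset(metabs.get(pid, ())),
        )
        for pid in order
    ]


def write_pathways_gmt(pathways: Iterable[Pathway], path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            if pw.gene_members:
                fh.write("\t".join([pw.id, "genes", *sorted(pw.gene_members)]) + "\n")
            if pw.metabolite_members:
                fh.write(
                    "\t".join([pw.id, "metabolites", *sorted(pw.metabolite_members)])
                    + "\n"
                )
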