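"""Readers and writers for the plain-text formats the pipeline touches.

All genomic inputs follow common community dialects: CpG calls come as
Bismark-coverage-style TSVs (1-based positions), intervals as BED3/BED6
(0-based half-open), GWAS summary statistics as a five-column TSV, genes
as BED6 with the gene id in the name field, and GO term membership as a
two-column ``term_id<TAB>gene_id`` map.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneRecord,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    MethylomeSample,
    ValidationError,
    merge_intervals,
)

__all__ = [
    "read_layout",
    "write_layout",
    "read_cpg_calls",
    "write_cpg_calls",
    "read_gwas_stats",
    "write_gwas_stats",
    "read_bed",
    "write_bed",
    "read_genes_bed",
    "write_genes_bed",
    "read_go_map",
    "write_go_map",
]


class ParseError(ValueError):
    """Raised for malformed rows; the message names the offending line."""


def read_layout(path: str | Path) -> GenomeLayout:
    """Read a two-column ``chrom<TAB>length`` genome layout."""
    names, lengths = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length {parts[1]!r}")
            names.append(parts[0])
            lengths.append(length)
    return GenomeLayout(tuple(names), tuple(lengths))


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


def read_cpg_calls(
    path: str | Path,
    layout: GenomeLayout,
    min_coverage: int = 1,
    sample_id: str | None = None,
    age_group: str = "none",
    scr_group: str = "none",
    has_percentage: bool = False,
) -> MethylomeSample:
    """Read Bismark-coverage-style CpG calls into a :class:`MethylomeSample`.

    Expected columns: chrom, position (1-based), methylated count,
    unmethylated count. With ``has_percentage=True`` the 6-column Bismark
    dialect ``chrom start end pct n_meth n_unmeth`` is accepted and the
    percentage is ignored (counts are always taken as authoritative).
    Loci with total coverage below ``min_coverage`` are dropped; positions
    are converted to 0-based on read.
    """
    rows = []
    if has_percentage:
        meth_col, unmeth_col, ncol = 4, 5, 6
    else:
        meth_col, unmeth_col, ncol = 2, 3, 4
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < ncol:
                raise ParseError(f"{path}:{lineno}: expected {ncol} columns, got {len(parts)}")
            chrom = parts[0]
            try:
                pos1 = int(parts[1])
                n_meth = int(parts[meth_col])
                n_unmeth = int(parts[unmeth_col])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})")
            if pos1 < 1:
                raise ParseError(f"{path}:{lineno}: position must be >= 1")
            if n_meth < 0 or n_unmeth < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            total = n_meth + n_unmeth
            if total >= min_coverage and total >= 1:
                rows.append((chrom, pos1 - 1, n_meth, total))
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_total"])
    if sample_id is None:
        sample_id = Path(path).stem
    return MethylomeSample(sample_id, calls, layout, age_group, scr_group)


def write_cpg_calls(sample: MethylomeSample, path: str | Path) -> None:
    """Write calls back to the 4-column Bismark-coverage dialect (1-based)."""
    df = sample.calls
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,
            "n_meth": df["n_meth"],
            "n_unmeth": df["n_total"] - df["n_meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


GWAS_COLUMNS = ["trait", "chrom", "pos", "b", "se", "t2"]


def read_gwas_stats(path: str | Path, layout: GenomeLayout) -> pd.DataFrame:
    """Read GWAS summary statistics: ``trait chrom pos(1-based) b se``.

    Returns a dataframe with 0-based positions and the squared t-statistic
    ``t2 = (b/se)**2`` cached, sorted by (layout chromosome order,
    position). An optional sixth p-value column is ignored; t2 is always
    recomputed from b and se.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3, 4],
        names=["trait", "chrom", "pos", "b", "se"],
        dtype={"trait": str, "chrom": str},
    )
    df["pos"] = df["pos"].astype(np.int64) - 1
    if (df["se"] <= 0).any():
        bad = int((df["se"] <= 0).sum())
        raise ValidationError(f"{bad} rows with standard error <= 0 in {path}")
    df["t2"] = (df["b"] / df["se"]) ** 2
    key = layout.sort_key(df["chrom"])
    order = np.lexsort((df["pos"].to_numpy(), key))
    return df.iloc[order].reset_index(drop=True)[GWAS_COLUMNS]


def write_gwas_stats(stats: pd.DataFrame, path: str | Path) -> None:
    out = stats[["trait", "chrom", "pos", "b", "se"]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, layout: GenomeLayout | None = None) -> IntervalSet:
    """Read a BED3+ file into a merged IntervalSet (extra columns ignored)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                intervals.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}")
    return merge_intervals(intervals, layout=layout)


def write_bed(
    intervals: IntervalSet | Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3 (or BED5 when names/scores are given)."""
    ivs = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                fields.append(str(names[i]) if names is not None else f"feature_{i}")
                fields.append(str(int(round(scores[i]))) if scores is not None else "0")
            fh.write("\t".join(fields) + "\n")


def read_genes_bed(path: str | Path, layout: GenomeLayout | None = None) -> list[GeneRecord]:
    """Read genes as BED6 with gene_id in the name field."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: genes need 6 BED columns")
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            if layout is not None and iv.end > layout.lengths.get(iv.chrom, iv.end):
                raise ValidationError(f"{path}:{lineno}: gene beyond chromosome end")
            genes.append(GeneRecord(parts[3], iv, parts[5]))
    return genes


def write_genes_bed(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def read_go_map(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column ``term_id<TAB>gene_id`` map into term -> gene list."""
    terms: dict[str, list[str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected term_id<TAB>gene_id")
            terms.setdefault(row[0], []).append(row[1])
    return terms


def write_go_map(go_map: dict[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(go_map):
            for gene in go_map[term]:
                fh.write(f"{term}\t{gene}\n")
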