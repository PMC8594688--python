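"""Domain types and interval arithmetic shared by every pipeline stage.

Coordinates are 0-based half-open everywhere inside the package; 1-based
file formats are converted on read (see :mod:`methgwas.io`). Chromosome
order is taken from the :class:`GenomeLayout`, never lexicographic — the
cyclical-permutation GWAS test needs one well-defined genome-wide ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "IntervalSet",
    "MethylomeSample",
    "GeneRecord",
    "merge_intervals",
    "intersect_bp",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths.

    The order given here fixes the global traversal order used for
    position-sorted operations (tiling, variant rotation).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        if len(names) != len(lengths):
            raise ValidationError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValidationError("chromosome names must be unique")
        if any(l <= 0 for l in lengths):
            raise ValidationError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def sort_key(self, chroms: Iterable[str]) -> np.ndarray:
        return np.array([self.chrom_index(c) for c in chroms], dtype=np.int64)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open region ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expanded(self, flank: int, chrom_length: int | None = None) -> "GenomicInterval":
        start = max(0, self.start - flank)
        end = self.end + flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        return GenomicInterval(self.chrom, start, end)


class IntervalSet:
    """A merged, sorted collection of disjoint half-open intervals.

    Internally one ``(n, 2)`` int64 array per chromosome. Abutting
    intervals are merged (half-open adjacency), so the representation is
    canonical: two sets covering the same bases compare equal.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        layout: GenomeLayout | None = None,
    ) -> None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            if layout is not None:
                length = layout.lengths.get(iv.chrom)
                if length is None:
                    raise ValidationError(f"unknown chromosome {iv.chrom!r}")
                if iv.end > length:
                    raise ValidationError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end {length}"
                    )
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self.layout = layout
        self._arrays: dict[str, np.ndarray] = {
            chrom: _merge_array(np.array(pairs, dtype=np.int64))
            for chrom, pairs in per_chrom.items()
        }

    @classmethod
    def _from_arrays(
        cls, arrays: Mapping[str, np.ndarray], layout: GenomeLayout | None = None
    ) -> "IntervalSet":
        out = cls(layout=layout)
        out._arrays = {c: np.asarray(a, dtype=np.int64) for c, a in arrays.items() if len(a)}
        return out

    def chrom_array(self, chrom: str) -> np.ndarray:
        return self._arrays.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def chroms(self) -> list[str]:
        if self.layout is not None:
            return [c for c in self.layout.chrom_names if c in self._arrays]
        return sorted(self._arrays)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for start, end in self._arrays[chrom]:
                yield GenomicInterval(chrom, int(start), int(end))

    def __len__(self) -> int:
        return sum(len(a) for a in self._arrays.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._arrays) != set(other._arrays):
            return False
        return all(
            np.array_equal(self._arrays[c], other._arrays[c]) for c in self._arrays
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_bp} bp)"

    @property
    def total_bp(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._arrays.values())
        )

    def intersect_bp(self, other: "IntervalSet") -> int:
        """Total bases shared with ``other``."""
        total = 0
        for chrom, a in self._arrays.items():
            b = other.chrom_array(chrom)
            if len(b) == 0:
                continue
            total += _intersect_bp_arrays(a, b)
        return int(total)

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        arrays = {}
        for chrom, a in self._arrays.items():
            b = other.chrom_array(chrom)
            if len(b) == 0:
                continue
            merged = _intersect_arrays(a, b)
            if len(merged):
                arrays[chrom] = merged
        return IntervalSet._from_arrays(arrays, layout=self.layout or other.layout)

    def contains_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which 0-based positions fall inside the set."""
        a = self.chrom_array(chrom)
        positions = np.asarray(positions)
        if len(a) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(a[:, 0], positions, side="right") - 1
        ok = idx >= 0
        ok[ok] &= positions[ok] < a[idx[ok], 1]
        return ok

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(iv.chrom, iv.start, iv.end) for iv in self]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _merge_array(pairs: np.ndarray) -> np.ndarray:
    """Merge overlapping/abutting [start, end) rows; returns sorted array."""
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    out: list[list[int]] = [[int(pairs[0, 0]), int(pairs[0, 1])]]
    for start, end in pairs[1:]:
        if start <= out[-1][1]:  # overlap or abut
            out[-1][1] = max(out[-1][1], int(end))
        else:
            out.append([int(start), int(end)])
    return np.array(out, dtype=np.int64)


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection of two merged arrays (two-pointer sweep)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def _intersect_bp_arrays(a: np.ndarray, b: np.ndarray) -> int:
    inter = _intersect_arrays(a, b)
    return int((inter[:, 1] - inter[:, 0]).sum()) if len(inter) else 0


def merge_intervals(
    intervals: Iterable[GenomicInterval], layout: GenomeLayout | None = None
) -> IntervalSet:
    """Minimal disjoint cover of the same bases; abutting intervals merge."""
    return IntervalSet(intervals, layout=layout)


def intersect_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Total overlapping bases between two merged interval sets."""
    return a.intersect_bp(b)


CALL_COLUMNS = ["chrom", "pos", "n_meth", "n_total"]


@dataclass
class MethylomeSample:
    """One animal's CpG methylation calls.

    ``calls`` holds columns chrom, pos (0-based), n_meth, n_total, sorted
    by (layout chromosome order, position); positions are unique per
    chromosome. ``age_group`` / ``scr_group`` carry the study's two
    contrasts (aged vs young bulls; low vs high sire conception rate).
    """

    sample_id: str
    calls: pd.DataFrame
    layout: GenomeLayout
    age_group: str = "none"
    scr_group: str = "none"

    def __post_init__(self) -> None:
        df = self.calls
        missing = [c for c in CALL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"calls missing columns {missing}")
        df = df[CALL_COLUMNS].copy()
        for col in ("pos", "n_meth", "n_total"):
            df[col] = df[col].astype(np.int64)
        if len(df):
            if (df["n_total"] < 1).any():
                raise ValidationError("n_total must be >= 1")
            if ((df["n_meth"] < 0) | (df["n_meth"] > df["n_total"])).any():
                raise ValidationError("need 0 <= n_meth <= n_total")
            key = self.layout.sort_key(df["chrom"])
            order = np.lexsort((df["pos"].to_numpy(), key))
            df = df.iloc[order].reset_index(drop=True)
            if df.duplicated(subset=["chrom", "pos"]).any():
                raise ValidationError("duplicate CpG positions within a chromosome")
        self.calls = df.reset_index(drop=True)

    @property
    def levels(self) -> np.ndarray:
        return self.calls["n_meth"].to_numpy() / self.calls["n_total"].to_numpy()

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    def global_level(self) -> float:
        """Read-pooled genome-wide methylation level."""
        tot = int(self.calls["n_total"].sum())
        if tot == 0:
            return float("nan")
        return float(self.calls["n_meth"].sum() / tot)

    def filter_coverage(self, min_coverage: int) -> "MethylomeSample":
        kept = self.calls[self.calls["n_total"] >= min_coverage].reset_index(drop=True)
        return MethylomeSample(
            self.sample_id, kept, self.layout, self.age_group, self.scr_group
        )

    def chrom_calls(self, chrom: str) -> pd.DataFrame:
        return self.calls[self.calls["chrom"] == chrom]


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its genomic span, strand and transcription start site."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    def promoter(self, upstream_bp: int = 2000) -> GenomicInterval:
        """Strand-aware promoter: ``upstream_bp`` immediately 5' of the TSS."""
        if self.strand == "+":
            start = max(0, self.interval.start - upstream_bp)
            end = max(start + 1, self.interval.start)
        else:
            start = self.interval.end
            end = self.interval.end + upstream_bp
        return GenomicInterval(self.interval.chrom, start, end)
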