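"""Synthetic WGBS methylomes, GWAS summary statistics and annotations.

The generator emulates the statistical structure of a mammalian sperm
methylome: a highly methylated background (~75% of reads methylated at a
typical CpG), short CpG-dense hypomethylated blocks (HMR scale, level
~5%, emulating CpG-island promoters/enhancers), large partially
methylated domains (PMD scale, level ~40%, >= 60 kb), and group-specific
methylation differences planted on 500-bp tiles. GWAS t-statistics are
standard normal genome-wide with an inflated mean (noncentrality delta)
inside designated feature regions. Every planted structure is returned in
a :class:`SimulatedTruth` record so downstream detection can be scored
against the exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
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
    "PlantedRegion",
    "PlantedPmd",
    "PlantedDmrTile",
    "SimulationDesign",
    "SimulatedTruth",
    "simulate_methylomes",
    "simulate_gwas",
    "simulate_gene_annotation",
    "default_layout",
]

PMD_MIN_BP = 60_000  # >= 3 detection windows of 20 kb


@dataclass(frozen=True)
class PlantedRegion:
    """An interval with a fixed true methylation level (HMR use: ~0.05)."""

    interval: GenomicInterval
    level: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValidationError("level must be in [0, 1]")


@dataclass(frozen=True)
class PlantedPmd:
    """A partially methylated domain; optionally present in only some samples.

    ``samples=None`` plants the domain in every sample; otherwise only the
    listed sample ids carry the reduced level (the rest stay at baseline),
    which is how domains "supported by at least three sperm samples" are
    expressed.
    """

    interval: GenomicInterval
    level: float = 0.40
    samples: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValidationError("level must be in [0, 1]")
        if len(self.interval) < PMD_MIN_BP:
            raise ValidationError(
                f"planted PMD must span >= {PMD_MIN_BP} bp, got {len(self.interval)}"
            )


@dataclass(frozen=True)
class PlantedDmrTile:
    """A tile with group-specific true levels (group1 vs group2)."""

    interval: GenomicInterval
    level_group1: float
    level_group2: float

    def __post_init__(self) -> None:
        for lv in (self.level_group1, self.level_group2):
            if not 0.0 <= lv <= 1.0:
                raise ValidationError("levels must be in [0, 1]")

    @property
    def true_diff(self) -> float:
        """True difference in percentage points (group1 - group2)."""
        return 100.0 * (self.level_group1 - self.level_group2)


@dataclass
class SimulationDesign:
    """All knobs of the methylome generator, with study-scale defaults.

    Defaults: 75% baseline methylation, mean coverage 10 reads/CpG, mean
    CpG spacing 100 bp in background and 30 bp inside planted
    hypomethylated blocks (CpG-island density), HMR level 5%, PMD level
    40%. Coverage is Poisson truncated at >= 1; ``coverage_dispersion``
    > 0 switches to a gamma-Poisson mixture with that squared
    coefficient of variation added (off by default).
    """

    layout: GenomeLayout
    baseline_meth: float = 0.75
    coverage_mean: float = 10.0
    coverage_dispersion: float = 0.0
    cpg_spacing_mean: float = 100.0
    hmr_cpg_spacing_mean: float = 30.0
    planted_hmrs: Sequence[PlantedRegion] = field(default_factory=tuple)
    planted_pmds: Sequence[PlantedPmd] = field(default_factory=tuple)
    planted_dmr_tiles: Sequence[PlantedDmrTile] = field(default_factory=tuple)
    n_samples_per_group: int = 3
    group_names: tuple[str, str] = ("group1", "group2")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_meth <= 1.0:
            raise ValidationError("baseline_meth must be in [0, 1]")
        if self.coverage_mean <= 0 or self.cpg_spacing_mean <= 0:
            raise ValidationError("coverage_mean and cpg_spacing_mean must be positive")
        if self.n_samples_per_group < 1:
            raise ValidationError("need at least one sample per group")
        self._check_in_layout()
        self._check_disjoint_kinds()

    def _check_in_layout(self) -> None:
        lengths = self.layout.lengths
        for coll in (self.planted_hmrs, self.planted_pmds, self.planted_dmr_tiles):
            for item in coll:
                iv = item.interval
                if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                    raise ValidationError(
                        f"planted interval {iv.chrom}:{iv.start}-{iv.end} outside layout"
                    )

    def _check_disjoint_kinds(self) -> None:
        kinds = {
            "hmr": merge_intervals(r.interval for r in self.planted_hmrs),
            "pmd": merge_intervals(r.interval for r in self.planted_pmds),
            "dmr": merge_intervals(r.interval for r in self.planted_dmr_tiles),
        }
        names = list(kinds)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if kinds[a].intersect_bp(kinds[b]) > 0:
                    raise ValidationError(
                        f"planted {a} and {b} features overlap; kinds must be disjoint"
                    )

    @property
    def sample_ids(self) -> list[str]:
        g1, g2 = self.group_names
        return [f"{g1}_{i + 1}" for i in range(self.n_samples_per_group)] + [
            f"{g2}_{i + 1}" for i in range(self.n_samples_per_group)
        ]


@dataclass(frozen=True)
class SimulatedTruth:
    """Exact planted structure, stored as given (never re-derived)."""

    hmr_intervals: IntervalSet
    pmd_intervals: IntervalSet
    dmr_tiles: tuple[PlantedDmrTile, ...]
    enriched_gwas_intervals: IntervalSet


def _draw_positions(rng: np.random.Generator, design: SimulationDesign, chrom: str) -> np.ndarray:
    """CpG positions on one chromosome: geometric spacing, denser in HMRs."""
    length = design.layout.lengths[chrom]

    def walk(start: int, end: int, mean: float) -> np.ndarray:
        span = end - start
        n_guess = max(8, int(2.0 * span / mean) + 8)
        gaps = rng.geometric(1.0 / mean, size=n_guess)
        pos = start + np.cumsum(gaps) - 1
        while len(pos) and pos[-1] < end - 1:
            extra = rng.geometric(1.0 / mean, size=n_guess)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        return pos[pos < end]

    background = walk(0, length, design.cpg_spacing_mean)
    hmr_set = merge_intervals(
        r.interval for r in design.planted_hmrs if r.interval.chrom == chrom
    )
    if len(hmr_set):
        inside = hmr_set.contains_positions(chrom, background)
        pieces = [background[~inside]]
        for iv in hmr_set:
            pieces.append(walk(iv.start, iv.end, design.hmr_cpg_spacing_mean))
        background = np.unique(np.concatenate(pieces))
    return np.asarray(np.sort(np.unique(background)), dtype=np.int64)


def _true_levels(
    design: SimulationDesign, chrom: str, positions: np.ndarray, sample_id: str, group: str
) -> np.ndarray:
    levels = np.full(len(positions), design.baseline_meth, dtype=float)
    for region in design.planted_hmrs:
        if region.interval.chrom == chrom:
            mask = (positions >= region.interval.start) & (positions < region.interval.end)
            levels[mask] = region.level
    for pmd in design.planted_pmds:
        if pmd.interval.chrom != chrom:
            continue
        if pmd.samples is not None and sample_id not in pmd.samples:
            continue
        mask = (positions >= pmd.interval.start) & (positions < pmd.interval.end)
        levels[mask] = pmd.level
    for tile in design.planted_dmr_tiles:
        if tile.interval.chrom != chrom:
            continue
        mask = (positions >= tile.interval.start) & (positions < tile.interval.end)
        levels[mask] = tile.level_group1 if group == design.group_names[0] else tile.level_group2
    return levels


def _draw_coverage(rng: np.random.Generator, design: SimulationDesign, n: int) -> np.ndarray:
    mean = design.coverage_mean
    if design.coverage_dispersion > 0:
        shape = 1.0 / design.coverage_dispersion
        lam = rng.gamma(shape, mean / shape, size=n)
        cov = rng.poisson(lam)
    else:
        cov = rng.poisson(mean, size=n)
    # zero-truncate by redrawing (keeps the conditional distribution exact)
    zero = cov == 0
    while zero.any():
        cov[zero] = rng.poisson(mean, size=int(zero.sum()))
        zero = cov == 0
    return cov.astype(np.int64)


def simulate_methylomes(
    design: SimulationDesign,
) -> tuple[list[MethylomeSample], SimulatedTruth]:
    """Simulate two groups of methylomes with planted ground truth.

    CpG positions are shared across samples (as in a real alignment, where
    every sample reports the same reference CpGs). Per CpG per sample,
    coverage is zero-truncated Poisson and the methylated count is
    binomial at the true local level. Group 1 carries the first label of
    ``design.group_names`` in both the age and SCR slots (aged/low-SCR
    analogue); group 2 the second.
    """
    root = np.random.SeedSequence(design.seed)
    pos_seed, *sample_seeds = root.spawn(1 + 2 * design.n_samples_per_group)
    pos_rng = np.random.default_rng(pos_seed)

    positions = {
        chrom: _draw_positions(pos_rng, design, chrom)
        for chrom in design.layout.chrom_names
    }

    g1, g2 = design.group_names
    samples: list[MethylomeSample] = []
    for k, sample_id in enumerate(design.sample_ids):
        group = g1 if k < design.n_samples_per_group else g2
        rng = np.random.default_rng(sample_seeds[k])
        frames = []
        for chrom in design.layout.chrom_names:
            pos = positions[chrom]
            if len(pos) == 0:
                continue
            levels = _true_levels(design, chrom, pos, sample_id, group)
            cov = _draw_coverage(rng, design, len(pos))
            meth = rng.binomial(cov, levels)
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos, "n_meth": meth, "n_total": cov}
                )
            )
        calls = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "pos", "n_meth", "n_total"])
        )
        age = "aged" if group == g1 else "young"
        scr = "low" if group == g1 else "high"
        samples.append(MethylomeSample(sample_id, calls, design.layout, age, scr))

    truth = SimulatedTruth(
        hmr_intervals=merge_intervals(
            (r.interval for r in design.planted_hmrs), layout=design.layout
        ),
        pmd_intervals=merge_intervals(
            (r.interval for r in design.planted_pmds), layout=design.layout
        ),
        dmr_tiles=tuple(design.planted_dmr_tiles),
        enriched_gwas_intervals=IntervalSet(layout=design.layout),
    )
    return samples, truth


def simulate_gwas(
    layout: GenomeLayout,
    n_variants: int,
    enriched_intervals: IntervalSet | None = None,
    delta: float = 0.0,
    seed: int = 0,
    trait: str = "trait1",
) -> tuple[pd.DataFrame, IntervalSet]:
    """Simulate GWAS summary statistics with planted signal enrichment.

    Variant positions are uniform over the genome; the t-statistic is
    N(0, 1) outside the enriched intervals and N(delta, 1) inside. The
    effect is reported as b = t with se = 1, the minimal structure the
    sum-based marker-set test consumes.
    """
    if n_variants < 1:
        raise ValidationError("n_variants must be >= 1")
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    enriched = enriched_intervals or IntervalSet(layout=layout)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    lengths = np.array(layout.chrom_lengths, dtype=float)
    counts = rng.multinomial(n_variants, lengths / lengths.sum())
    frames = []
    for chrom, length, k in zip(layout.chrom_names, layout.chrom_lengths, counts):
        if k == 0:
            continue
        if k <= length:
            pos = np.sort(rng.choice(length, size=int(k), replace=False))
        else:
            raise ValidationError(f"more variants than bases on {chrom}")
        t = rng.standard_normal(int(k))
        inside = enriched.contains_positions(chrom, pos)
        t[inside] += delta
        frames.append(
            pd.DataFrame(
                {
                    "trait": trait,
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "b": t,
                    "se": 1.0,
                }
            )
        )
    stats = pd.concat(frames, ignore_index=True)
    stats["t2"] = (stats["b"] / stats["se"]) ** 2
    key = layout.sort_key(stats["chrom"])
    order = np.lexsort((stats["pos"].to_numpy(), key))
    stats = stats.iloc[order].reset_index(drop=True)
    return stats, enriched


def simulate_gene_annotation(
    layout: GenomeLayout,
    n_genes: int,
    n_terms: int,
    genes_per_term: int,
    seed: int = 0,
    min_gene_bp: int = 2_000,
    max_gene_bp: int = 50_000,
) -> tuple[list[GeneRecord], dict[str, list[str]]]:
    """Place non-overlapping genes (2-50 kb) and sample GO-term membership.

    Genes are distributed across chromosomes in proportion to length and
    packed with random gaps; each term draws ``genes_per_term`` genes
    without replacement.
    """
    if genes_per_term > n_genes:
        raise ValidationError("genes_per_term cannot exceed n_genes")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lengths = np.array(layout.chrom_lengths, dtype=float)
    counts = rng.multinomial(n_genes, lengths / lengths.sum())

    genes: list[GeneRecord] = []
    gid = 0
    for chrom, length, k in zip(layout.chrom_names, layout.chrom_lengths, counts):
        if k == 0:
            continue
        sizes = rng.integers(min_gene_bp, max_gene_bp + 1, size=int(k))
        free = length - int(sizes.sum())
        if free < 0:
            raise ValidationError(f"cannot pack {k} genes into {chrom} ({length} bp)")
        cuts = np.sort(rng.choice(free + 1, size=int(k), replace=True))
        starts = cuts + np.concatenate([[0], np.cumsum(sizes[:-1])])
        for start, size in zip(starts, sizes):
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneRecord(
                    f"gene{gid:04d}",
                    GenomicInterval(chrom, int(start), int(start + size)),
                    strand,
                )
            )

    ids = [g.gene_id for g in genes]
    go_map = {
        f"GO:{j + 1:07d}": sorted(rng.choice(ids, size=genes_per_term, replace=False))
        for j in range(n_terms)
    }
    return genes, go_map


def default_layout(n_chroms: int = 2, chrom_bp: int = 2_000_000) -> GenomeLayout:
    """A small uniform genome layout for demonstrations and simulations."""
    return GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(n_chroms)),
        tuple(chrom_bp for _ in range(n_chroms)),
    )
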