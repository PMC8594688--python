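"""Cross-cutting analyses joining the segmentation, differential and
enrichment stages: global group comparison, genomic-element fold
enrichment, overlap of two DMR sets with a one-sided Fisher exact test,
gain-vs-loss enrichment comparison, and the candidate-gene table that
intersects shared gain-gain DMRs with suggestive GWAS hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    GeneRecord,
    GenomicInterval,
    IntervalSet,
    MethylomeSample,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapTable",
    "CandidateGene",
    "global_methylation_test",
    "element_fold_enrichment",
    "overlap_fisher",
    "gain_loss_comparison",
    "candidate_gene_table",
]


@dataclass(frozen=True)
class OverlapTable:
    """Overlap of two DMR sets over a shared tested-tile universe."""

    n_total: int
    n_a: int
    n_b: int
    n_shared: int
    expected: float
    p: float
    log10_p: float


@dataclass(frozen=True)
class CandidateGene:
    """A gene bearing a gain-gain shared DMR and a suggestive GWAS SNP."""

    gene_id: str
    dmr: GenomicInterval
    q_age: float
    diff_age: float
    q_scr: float
    diff_scr: float
    trait: str
    top_snp_pos: int
    top_snp_p: float


def global_methylation_test(
    group_a: Sequence[MethylomeSample],
    group_b: Sequence[MethylomeSample],
    min_coverage: int = 1,
    paired: bool = True,
) -> tuple[float, float, float]:
    """t-test of group methylation across common CpG loci.

    Common loci are CpGs covered at >= ``min_coverage`` in every sample
    of both groups; per locus, each group's level is its read-pooled
    proportion. The default is the paired two-sided t-test on per-locus
    differences (level_A - level_B); ``paired=False`` gives Welch's
    two-sample test across loci instead. Returns (t, p, mean_diff).
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")

    def pooled_levels(samples: Sequence[MethylomeSample]) -> pd.DataFrame:
        frames = []
        for s in samples:
            df = s.calls[s.calls["n_total"] >= min_coverage]
            frames.append(df[["chrom", "pos", "n_meth", "n_total"]])
        merged = None
        for i, f in enumerate(frames):
            f = f.set_index(["chrom", "pos"])
            merged = f if merged is None else merged.join(f, how="inner", rsuffix=f"_{i}")
        meth = merged.filter(like="n_meth").sum(axis=1)
        tot = merged.filter(like="n_total").sum(axis=1)
        return (meth / tot).rename("level")

    la = pooled_levels(group_a)
    lb = pooled_levels(group_b)
    common = la.index.intersection(lb.index)
    if len(common) < 2:
        raise ValidationError("fewer than 2 common loci between groups")
    a = la.loc[common].to_numpy()
    b = lb.loc[common].to_numpy()
    mean_diff = float(np.mean(a - b))
    if paired:
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0.0:
            return (0.0, 1.0, mean_diff) if mean_diff == 0 else (np.inf, 0.0, mean_diff)
        t, p = sps.ttest_rel(a, b)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), mean_diff


def element_fold_enrichment(
    features: IntervalSet, elements: IntervalSet, genome_bp: int
) -> float:
    """Fold enrichment of a feature set inside a genomic-element track.

    fold = (overlap_bp / feature_bp) / (element_bp / genome_bp); 1 means
    the features intersect the element no more than genome-average.
    """
    feature_bp = features.total_bp
    if feature_bp == 0:
        raise ValidationError("feature set is empty")
    element_bp = elements.total_bp
    if element_bp == 0 or genome_bp <= 0:
        raise ValidationError("element set empty or invalid genome size")
    overlap = features.intersect_bp(elements)
    if overlap == 0:
        return 0.0
    return (overlap / feature_bp) / (element_bp / genome_bp)


def overlap_fisher(n_total: int, n_a: int, n_b: int, n_shared: int) -> OverlapTable:
    """One-sided (enrichment) Fisher exact test of DMR-set overlap.

    Over ``n_total`` commonly tested tiles with ``n_a`` and ``n_b`` DMRs
    in the two sets sharing ``n_shared`` tiles, the p-value is the
    hypergeometric upper tail P(X >= n_shared) with population n_total,
    n_a successes and n_b draws, computed in log space.
    """
    if min(n_total, n_a, n_b, n_shared) < 0:
        raise ValidationError("counts must be non-negative")
    if n_shared > min(n_a, n_b) or n_a + n_b - n_shared > n_total:
        raise ValidationError("inconsistent overlap margins")
    expected = n_a * n_b / n_total if n_total else float("nan")
    if n_shared == 0:
        logp = 0.0
    else:
        logp = float(sps.hypergeom.logsf(n_shared - 1, n_total, n_a, n_b))
    return OverlapTable(
        n_total=n_total,
        n_a=n_a,
        n_b=n_b,
        n_shared=n_shared,
        expected=expected,
        p=float(np.exp(logp)),
        log10_p=logp / np.log(10.0),
    )


def gain_loss_comparison(
    enrichment_gain: Sequence[float], enrichment_loss: Sequence[float]
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of gain vs loss enrichment values.

    Inputs are matched panels of enrichment strengths (e.g. -log10
    empirical p across traits x q cutoffs). Uses the exact Mann-Whitney
    null when both panels have n <= 10, otherwise the tie-corrected
    normal approximation. Returns (W, p).
    """
    gain = np.asarray(enrichment_gain, dtype=float)
    loss = np.asarray(enrichment_loss, dtype=float)
    if len(gain) == 0 or len(loss) == 0:
        raise ValidationError("both panels must be non-empty")
    if np.isnan(gain).any() or np.isnan(loss).any():
        raise ValidationError("NaN enrichment values")
    if np.array_equal(gain, loss):
        # identical panels carry no ordering information
        return float(len(gain) * len(loss) / 2.0), 1.0
    method = "exact" if (len(gain) <= 10 and len(loss) <= 10 and
                         len(np.unique(np.concatenate([gain, loss]))) == len(gain) + len(loss)) \
        else "asymptotic"
    res = sps.mannwhitneyu(gain, loss, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _snp_pvalues(gwas: pd.DataFrame) -> np.ndarray:
    # two-sided normal p from t = b/se, equivalently chi2(1) on t^2
    return sps.chi2.sf(gwas["t2"].to_numpy(), df=1)


def candidate_gene_table(
    age_results: pd.DataFrame,
    scr_results: pd.DataFrame,
    genes: Sequence[GeneRecord],
    gwas_by_trait: dict[str, pd.DataFrame],
    q_cutoff: float = 0.01,
    diff_cutoff: float = 5.0,
    snp_threshold: float = 1e-5,
    promoter_bp: int = 2_000,
    snp_window_bp: int = 250_000,
) -> list[CandidateGene]:
    """Genes with gain-gain shared DMRs and suggestive GWAS SNPs.

    Pipeline: (1) tiles significant in both the age and SCR contrasts
    (same tile universe, keyed by chrom/start); (2) keep tiles gaining
    methylation in both (diff > +diff_cutoff twice); (3) assign tiles to
    genes whose body or strand-aware promoter (``promoter_bp`` upstream
    of the TSS) overlaps the tile; (4) per gene and trait, scan variants
    within the gene span +/- ``snp_window_bp`` and report the top SNP
    when its p-value is below ``snp_threshold``. One row per qualifying
    (gene, trait); a gene with several qualifying DMRs reports the one
    with the smallest age-contrast q.
    """
    key_cols = ["chrom", "start"]
    a = age_results.set_index(key_cols)
    s = scr_results.set_index(key_cols)
    common = a.index.intersection(s.index)
    a, s = a.loc[common], s.loc[common]

    sig = (
        (a["q"] < q_cutoff)
        & (a["diff"] > diff_cutoff)
        & (s["q"] < q_cutoff)
        & (s["diff"] > diff_cutoff)
    )
    shared = a[sig]
    if shared.empty:
        return []

    rows = []
    for (chrom, start), arow in shared.iterrows():
        tile = GenomicInterval(chrom, int(start), int(arow["end"]))
        srow = s.loc[(chrom, start)]
        for gene in genes:
            if gene.interval.chrom != chrom:
                continue
            body = gene.interval
            prom = gene.promoter(promoter_bp)
            if tile.overlaps(body) or tile.overlaps(prom):
                rows.append((gene, tile, arow, srow))

    # one DMR per gene: smallest age-contrast q
    best: dict[str, tuple] = {}
    for gene, tile, arow, srow in rows:
        cur = best.get(gene.gene_id)
        if cur is None or arow["q"] < cur[2]["q"]:
            best[gene.gene_id] = (gene, tile, arow, srow)

    table: list[CandidateGene] = []
    for gene_id in sorted(best):
        gene, tile, arow, srow = best[gene_id]
        span_lo = max(0, gene.interval.start - snp_window_bp)
        span_hi = gene.interval.end + snp_window_bp
        for trait, gwas in gwas_by_trait.items():
            if gwas is None or gwas.empty:
                logger.warning("trait %s: missing GWAS table, skipped", trait)
                continue
            sel = gwas[
                (gwas["chrom"] == gene.interval.chrom)
                & (gwas["pos"] >= span_lo)
                & (gwas["pos"] < span_hi)
            ]
            if sel.empty:
                continue
            pvals = _snp_pvalues(sel)
            k = int(np.argmin(pvals))
            if pvals[k] < snp_threshold:
                table.append(
                    CandidateGene(
                        gene_id=gene.gene_id,
                        dmr=tile,
                        q_age=float(arow["q"]),
                        diff_age=float(arow["diff"]),
                        q_scr=float(srow["q"]),
                        diff_scr=float(srow["diff"]),
                        trait=trait,
                        top_snp_pos=int(sel["pos"].to_numpy()[k]),
                        top_snp_p=float(pvals[k]),
                    )
                )
    return table
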