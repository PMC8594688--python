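"""Count-based hypergeometric enrichment of differential methylation in
GO terms, plus a plain hypergeometric gene-set test.

Window-set test: over the m tested 500-bp windows, let m_g be the number
with p < p0 genome-wide (p0 = 0.01 by default) and m_f the number mapped
to a term (a window maps to a term when it overlaps any of the term's
genes extended 10 kb on both sides). The term's statistic

    T_count = #(term windows with p < p0)

is referred to Hypergeometric(m, m_g, m_f); enrichment is the upper
tail P(X >= T_count), computed in log space, with BH adjustment across
terms. Terms with fewer than 10 annotated genes are dropped.

Gene-set test: for a query gene list against a universe, each term's
overlap is referred to the hypergeometric upper tail the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneRecord, GenomeLayout, GenomicInterval, ValidationError
from .dmr import adjust_q

__all__ = [
    "SetEnrichmentResult",
    "map_windows_to_terms",
    "count_based_test",
    "gene_set_enrichment",
    "hypergeom_upper_tail",
]


@dataclass(frozen=True)
class SetEnrichmentResult:
    term_id: str
    m: int        # tested windows genome-wide
    m_g: int      # windows with p < p0 genome-wide
    m_f: int      # tested windows mapped to the term
    t_count: int  # term windows with p < p0
    p_hyper: float
    fdr: float = float("nan")


def hypergeom_upper_tail(k: int, m: int, n_success: int, n_draw: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(m, n_success, n_draw), log-space."""
    if k <= 0:
        return 1.0
    return float(np.exp(sps.hypergeom.logsf(k - 1, m, n_success, n_draw)))


def map_windows_to_terms(
    tiles: pd.DataFrame,
    genes: Sequence[GeneRecord],
    go_map: dict[str, Sequence[str]],
    layout: GenomeLayout | None = None,
    flank: int = 10_000,
    min_genes: int = 10,
) -> dict[str, np.ndarray]:
    """Map tested windows to GO terms via flank-extended gene spans.

    ``tiles`` needs chrom/start/end columns (the tested units from
    :func:`methgwas.dmr.test_tiles`). A window belongs to a term when it
    overlaps >= 1 bp of any term gene extended by ``flank`` on both
    sides. Terms with fewer than ``min_genes`` genes present in the
    annotation are dropped; go_map entries naming unknown genes are
    skipped with a warning.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    lengths = layout.lengths if layout is not None else {}

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in tiles.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp.index.to_numpy(),
        )

    out: dict[str, np.ndarray] = {}
    for term, members in go_map.items():
        known = [gene_by_id[g] for g in members if g in gene_by_id]
        missing = len(members) - len(known)
        if missing:
            import warnings

            warnings.warn(f"term {term}: {missing} unknown gene ids skipped")
        if len(known) < min_genes:
            continue
        hit: set[int] = set()
        for gene in known:
            iv = gene.interval.expanded(flank, lengths.get(gene.interval.chrom))
            entry = by_chrom.get(iv.chrom)
            if entry is None:
                continue
            starts, ends, idx = entry
            mask = (starts < iv.end) & (ends > iv.start)
            hit.update(idx[mask].tolist())
        out[term] = np.array(sorted(hit), dtype=np.int64)
    return out


def count_based_test(
    tile_pvalues: pd.Series | np.ndarray,
    term_windows: dict[str, np.ndarray],
    p0: float = 0.01,
) -> pd.DataFrame:
    """Window-set enrichment per term; returns a dataframe sorted by p.

    ``tile_pvalues`` are the per-window p-values over the full tested
    universe (index positions must match the indices produced by
    :func:`map_windows_to_terms`). Terms with m_f = 0 are skipped.
    """
    p = pd.Series(tile_pvalues).astype(float)
    sig = p < p0
    m = int(len(p))
    m_g = int(sig.sum())
    rows = []
    for term, idx in term_windows.items():
        m_f = int(len(idx))
        if m_f == 0:
            continue
        t_count = int(sig.loc[idx].sum()) if isinstance(sig, pd.Series) else int(sig[idx].sum())
        rows.append(
            {
                "term_id": term,
                "m": m,
                "m_g": m_g,
                "m_f": m_f,
                "t_count": t_count,
                "p_hyper": hypergeom_upper_tail(t_count, m, m_g, m_f),
            }
        )
    df = pd.DataFrame(rows, columns=["term_id", "m", "m_g", "m_f", "t_count", "p_hyper"])
    if len(df):
        df["fdr"] = adjust_q(df["p_hyper"].to_numpy())
        df = df.sort_values("p_hyper", kind="stable").reset_index(drop=True)
    else:
        df["fdr"] = []
    return df


def gene_set_enrichment(
    query_genes: Sequence[str],
    universe_genes: Sequence[str],
    go_map: dict[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric gene-set enrichment of a query list against a universe.

    Per term: upper-tail hypergeometric on (|universe|, |term in
    universe|, |query|, |term in query|), BH-adjusted across terms.
    """
    query = set(query_genes)
    universe = set(universe_genes)
    if not query:
        raise ValidationError("query gene list is empty")
    if not query <= universe:
        raise ValidationError("query genes must be a subset of the universe")
    rows = []
    for term, members in go_map.items():
        in_universe = set(members) & universe
        if not in_universe:
            continue
        overlap = len(in_universe & query)
        rows.append(
            {
                "term_id": term,
                "n_universe": len(universe),
                "n_term": len(in_universe),
                "n_query": len(query),
                "n_overlap": overlap,
                "p": hypergeom_upper_tail(overlap, len(universe), len(in_universe), len(query)),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = adjust_q(df["p"].to_numpy())
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df
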