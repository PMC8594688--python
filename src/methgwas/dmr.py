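"""Tile-based differential methylation testing.

The genome is tiled into non-overlapping 500-bp windows; per tile, group
differences in methylation are tested with a binomial logistic
regression ``logit(pi_j) = b0 + b1 * g_j`` over samples j, where g is
the group indicator. With a binary covariate the alternative-model MLEs
are the pooled group proportions, so the likelihood-ratio statistic has
the closed form

    G = 2 * [ ll(M1, U1) + ll(M2, U2) - ll(M1 + M2, U1 + U2) ]

with ``ll(M, U) = M log(M/(M+U)) + U log(U/(M+U))`` on pooled
methylated/unmethylated counts; G is referred to chi-square with one
degree of freedom. p-values are adjusted by Benjamini-Hochberg and
tiles with ``q < cutoff`` and an absolute pooled-group difference above
5 percentage points are called DMRs, split into gain (group 1 higher)
and loss. The same machinery at single-CpG resolution yields DMCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import GenomeLayout, GenomicInterval, MethylomeSample, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TileTable",
    "build_tiles",
    "test_tiles",
    "adjust_q",
    "call_dmrs",
    "binomial_lrt",
]

TILE_BP = 500


@dataclass
class TileTable:
    """Per-unit (500-bp tile or single CpG) methylation counts per sample.

    ``meth``/``total`` are (n_samples, n_units) count arrays aligned with
    ``sample_ids`` and the ``units`` dataframe (chrom, start, end).
    """

    unit: str  # "tile500" or "cpg"
    units: pd.DataFrame
    sample_ids: list[str]
    meth: np.ndarray
    total: np.ndarray
    min_per_sample: int = 1

    @property
    def n_units(self) -> int:
        return len(self.units)


def build_tiles(
    samples: Sequence[MethylomeSample],
    layout: GenomeLayout,
    unit: str = "tile500",
    tile_bp: int = TILE_BP,
) -> TileTable:
    """Aggregate per-sample counts onto 500-bp tiles (or single CpGs).

    Units with no coverage in any sample are dropped; the coverage gate
    for testing (every sample covered, pooled group coverage >= 10) is
    applied later in :func:`test_tiles`, where the groups are known.
    """
    if unit not in ("tile500", "cpg"):
        raise ValidationError(f"unknown unit {unit!r}")
    for s in samples:
        unknown = set(s.calls["chrom"]) - set(layout.chrom_names)
        if unknown:
            raise ValidationError(f"sample {s.sample_id}: unknown chromosomes {unknown}")

    frames = []
    for s in samples:
        df = s.calls.copy()
        if unit == "tile500":
            df["start"] = (df["pos"] // tile_bp) * tile_bp
        else:
            df["start"] = df["pos"]
        df["sample"] = s.sample_id
        frames.append(df[["chrom", "start", "sample", "n_meth", "n_total"]])
    stacked = pd.concat(frames, ignore_index=True)
    if unit == "tile500":
        stacked = stacked.groupby(["chrom", "start", "sample"], as_index=False).sum()

    units = stacked[["chrom", "start"]].drop_duplicates()
    key = layout.sort_key(units["chrom"])
    order = np.lexsort((units["start"].to_numpy(), key))
    units = units.iloc[order].reset_index(drop=True)
    width = tile_bp if unit == "tile500" else 1
    units["end"] = np.minimum(
        units["start"] + width,
        units["chrom"].map(layout.lengths).to_numpy(dtype=np.int64),
    )

    index = {
        (c, s): i for i, (c, s) in enumerate(zip(units["chrom"], units["start"]))
    }
    sample_ids = [s.sample_id for s in samples]
    meth = np.zeros((len(sample_ids), len(units)), dtype=np.int64)
    total = np.zeros_like(meth)
    srow = {sid: i for i, sid in enumerate(sample_ids)}
    rows = stacked["sample"].map(srow).to_numpy()
    cols = np.array(
        [index[(c, s)] for c, s in zip(stacked["chrom"], stacked["start"])]
    )
    np.add.at(meth, (rows, cols), stacked["n_meth"].to_numpy())
    np.add.at(total, (rows, cols), stacked["n_total"].to_numpy())
    return TileTable(unit, units, sample_ids, meth, total)


def _binom_ll(meth: np.ndarray, unmeth: np.ndarray) -> np.ndarray:
    """Profile binomial log-likelihood at the pooled MLE (0 log 0 = 0)."""
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    tot = meth + unmeth
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(meth > 0, meth * np.log(meth / tot), 0.0) + np.where(
            unmeth > 0, unmeth * np.log(unmeth / tot), 0.0
        )
    return np.where(tot > 0, out, 0.0)


def binomial_lrt(m1: float, t1: float, m2: float, t2: float) -> float:
    """Two-group binomial likelihood-ratio statistic on pooled counts.

    Equals the deviance difference of the binary-covariate logistic GLM
    (the alternative model saturates the two group proportions).
    """
    g = 2.0 * (
        _binom_ll(m1, t1 - m1)
        + _binom_ll(m2, t2 - m2)
        - _binom_ll(m1 + m2, (t1 + t2) - (m1 + m2))
    )
    return float(max(g, 0.0))


def test_tiles(
    table: TileTable,
    group1_ids: Sequence[str],
    group2_ids: Sequence[str],
    min_group_coverage: int = 10,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Likelihood-ratio test of group methylation per unit.

    Returns a dataframe with chrom, start, end, per-group pooled counts,
    ``diff`` (group1 - group2 pooled levels, percentage points), ``p``
    (chi-square(1) upper tail of the LRT), ``q`` (BH-adjusted across the
    tested units) and ``direction``. Units failing the coverage gate
    (some sample below ``min_per_sample`` reads, or a group pooled below
    ``min_group_coverage``) are excluded and counted in the log.
    """
    if not group1_ids or not group2_ids:
        raise ValidationError("both groups must be non-empty")
    rows = {sid: i for i, sid in enumerate(table.sample_ids)}
    try:
        i1 = [rows[s] for s in group1_ids]
        i2 = [rows[s] for s in group2_ids]
    except KeyError as exc:
        raise ValidationError(f"unknown sample id {exc}") from None

    used = i1 + i2
    per_sample_ok = (table.total[used] >= table.min_per_sample).all(axis=0)
    m1 = table.meth[i1].sum(axis=0).astype(float)
    t1 = table.total[i1].sum(axis=0).astype(float)
    m2 = table.meth[i2].sum(axis=0).astype(float)
    t2 = table.total[i2].sum(axis=0).astype(float)
    keep = per_sample_ok & (t1 >= min_group_coverage) & (t2 >= min_group_coverage)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%d units excluded by the coverage gate", n_dropped)

    m1, t1, m2, t2 = m1[keep], t1[keep], m2[keep], t2[keep]
    g = 2.0 * (
        _binom_ll(m1, t1 - m1)
        + _binom_ll(m2, t2 - m2)
        - _binom_ll(m1 + m2, (t1 + t2) - (m1 + m2))
    )
    g = np.maximum(g, 0.0)
    p = sps.chi2.sf(g, df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    diff = 100.0 * (m1 / t1 - m2 / t2)

    out = table.units.loc[keep].reset_index(drop=True).copy()
    out["meth1"], out["total1"] = m1.astype(np.int64), t1.astype(np.int64)
    out["meth2"], out["total2"] = m2.astype(np.int64), t2.astype(np.int64)
    out["lrt"] = g
    out["p"] = p
    out["q"] = adjust_q(p, method=adjust)
    out["diff"] = diff
    out["direction"] = np.where(diff > 0, "gain", "loss")
    return out


def adjust_q(pvalues: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment across the tested units.

    ``bh`` is Benjamini-Hochberg step-up; ``bh_pi0`` additionally scales
    by a Storey-type estimate of the null proportion pi0 (lambda = 0.5),
    a milder correction closer in spirit to q-value estimators.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "bh_pi0":
        lam = 0.5
        pi0 = min(1.0, (p > lam).mean() / (1.0 - lam))
        return np.minimum(q * pi0, 1.0)
    raise ValidationError(f"unknown adjustment {method!r}")


def call_dmrs(
    results: pd.DataFrame, q_cutoff: float = 0.01, diff_cutoff: float = 5.0
) -> dict[str, pd.DataFrame]:
    """Call DMRs at a q cutoff and an absolute difference above 5 points.

    Returns ``{"whole", "gain", "loss"}`` dataframes; gain and loss
    partition whole exactly (both thresholds are strict, so a tile at
    exactly +/- diff_cutoff is excluded).
    """
    whole = results[(results["q"] < q_cutoff) & (results["diff"].abs() > diff_cutoff)]
    gain = whole[whole["diff"] > diff_cutoff]
    loss = whole[whole["diff"] < -diff_cutoff]
    return {"whole": whole, "gain": gain, "loss": loss}


def results_to_intervals(results: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(results["chrom"], results["start"], results["end"])
    ]
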