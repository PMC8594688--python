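"""Hypomethylated-region (HMR) detection.

HMRs are short (sub-kb to few-kb) CpG-dense regions in which most CpGs
have a methylation level below 20%; in sperm they mark promoters,
CpG islands and candidate enhancers. Detection is per group on
read-pooled counts: a 200-bp seed window whose covered CpGs are at least
80% hypomethylated is extended rightward in 50-bp steps while the whole
extended span keeps satisfying that criterion; accepted spans are trimmed
to their outermost hypomethylated CpGs, merged, and kept when they hold
at least ``min_cpgs`` covered CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GenomicInterval,
    IntervalSet,
    MethylomeSample,
    ValidationError,
    merge_intervals,
)

__all__ = [
    "HmrParams",
    "HmrRecord",
    "pool_group",
    "detect_hmrs",
    "compare_interval_sets",
]


@dataclass(frozen=True)
class HmrParams:
    """Sliding-window parameters for HMR detection.

    window/step in bp; a CpG is hypomethylated when its pooled level is
    strictly below ``hypo_level``; a span qualifies while at least
    ``hypo_fraction`` of its covered CpGs are hypomethylated.
    """

    window: int = 200
    step: int = 50
    hypo_level: float = 0.20
    hypo_fraction: float = 0.80
    min_cpgs: int = 5
    min_coverage: int = 5

    def __post_init__(self) -> None:
        if not self.window >= self.step > 0:
            raise ValidationError("need window >= step > 0")
        for frac in (self.hypo_level, self.hypo_fraction):
            if not 0.0 < frac < 1.0:
                raise ValidationError("fractions must lie in (0, 1)")


@dataclass(frozen=True)
class HmrRecord:
    interval: GenomicInterval
    n_cpgs: int
    mean_level: float  # pooled n_meth / n_total over covered CpGs inside


def pool_group(samples: list[MethylomeSample]) -> MethylomeSample:
    """Sum methylated/total counts per position across a group's samples.

    Pooling is commutative, so the result is invariant under sample order;
    positions covered by any sample appear in the pool.
    """
    if not samples:
        raise ValidationError("cannot pool an empty group")
    if len(samples) == 1:
        s = samples[0]
        return MethylomeSample("pooled", s.calls.copy(), s.layout, s.age_group, s.scr_group)
    layout = samples[0].layout
    stacked = pd.concat([s.calls for s in samples], ignore_index=True)
    pooled = (
        stacked.groupby(["chrom", "pos"], as_index=False, sort=False)[["n_meth", "n_total"]]
        .sum()
    )
    return MethylomeSample("pooled", pooled, layout)


def _qualifies(cum_cov: np.ndarray, cum_hypo: np.ndarray, positions: np.ndarray,
               start: int, end: int, hypo_fraction: float) -> tuple[bool, int, int]:
    """Check the hypo-fraction criterion for span [start, end).

    Returns (qualifies, n_cpgs, n_hypo) using prefix sums over the sorted
    CpG position array.
    """
    lo = np.searchsorted(positions, start, side="left")
    hi = np.searchsorted(positions, end, side="left")
    n = hi - lo
    h = cum_hypo[hi] - cum_hypo[lo]
    return (n >= 1 and h >= hypo_fraction * n), int(n), int(h)


def detect_hmrs(pooled: MethylomeSample, params: HmrParams = HmrParams()) -> list[HmrRecord]:
    """Detect HMRs on a read-pooled (group-level) methylome.

    CpGs below ``min_coverage`` pooled reads are ignored. Seeds are placed
    at every ``step`` offset; extension is rightward only — leftward
    growth is captured because every grid position is itself a seed.
    The failing extension step is not included. Reported boundaries are
    trimmed to the outermost hypomethylated CpGs, so coordinates are
    data-supported rather than grid-aligned.
    """
    sample = pooled.filter_coverage(params.min_coverage)
    records: list[HmrRecord] = []
    for chrom in sample.layout.chrom_names:
        df = sample.chrom_calls(chrom)
        if df.empty:
            continue
        positions = df["pos"].to_numpy()
        levels = df["n_meth"].to_numpy() / df["n_total"].to_numpy()
        hypo = levels < params.hypo_level
        if not hypo.any():
            continue
        cum_hypo = np.concatenate([[0], np.cumsum(hypo)])
        cum_cov = np.concatenate([[0], np.cumsum(np.ones_like(positions))])
        chrom_len = sample.layout.lengths[chrom]

        # candidate seed starts: grid positions whose 200-bp window holds
        # at least one hypomethylated CpG (others cannot qualify)
        hypo_pos = positions[hypo]
        grid_lo = ((hypo_pos - params.window) // params.step + 1) * params.step
        starts = set()
        for p, g in zip(hypo_pos, grid_lo):
            for s in range(max(0, int(g)), int(p) + 1, params.step):
                starts.add(s)

        # extension past the last covered CpG cannot change the criterion
        # (and trimming discards the tail), so cap the scan there
        scan_limit = min(chrom_len, int(positions[-1]) + params.step)
        spans: list[tuple[int, int]] = []
        for s in sorted(starts):
            end = s + params.window
            ok, _, _ = _qualifies(cum_cov, cum_hypo, positions, s, end, params.hypo_fraction)
            if not ok:
                continue
            while end < scan_limit:
                nxt = min(end + params.step, chrom_len)
                ok2, _, _ = _qualifies(
                    cum_cov, cum_hypo, positions, s, nxt, params.hypo_fraction
                )
                if not ok2:
                    break
                end = nxt
            # trim to outermost hypomethylated CpGs in [s, end)
            lo = np.searchsorted(positions, s, side="left")
            hi = np.searchsorted(positions, end, side="left")
            idx = np.nonzero(hypo[lo:hi])[0]
            if len(idx) == 0:
                continue
            first = int(positions[lo + idx[0]])
            last = int(positions[lo + idx[-1]])
            spans.append((first, last + 1))

        merged = merge_intervals(GenomicInterval(chrom, a, b) for a, b in spans)
        for iv in merged:
            lo = np.searchsorted(positions, iv.start, side="left")
            hi = np.searchsorted(positions, iv.end, side="left")
            n_cpgs = int(hi - lo)
            if n_cpgs < params.min_cpgs:
                continue
            meth = int(df["n_meth"].to_numpy()[lo:hi].sum())
            tot = int(df["n_total"].to_numpy()[lo:hi].sum())
            records.append(HmrRecord(iv, n_cpgs, meth / tot))
    return records


def hmr_interval_set(records: list[HmrRecord], layout=None) -> IntervalSet:
    return merge_intervals((r.interval for r in records), layout=layout)


def compare_interval_sets(
    a: IntervalSet, b: IntervalSet
) -> tuple[tuple[int, int], int, int]:
    """Venn-style comparison of two merged interval sets.

    Returns ``((shared_a, shared_b), a_specific, b_specific)`` where
    shared counts are per input-set member (an interval is shared when it
    overlaps >= 1 bp of the other set), not per base.
    """
    def split(x: IntervalSet, y: IntervalSet) -> tuple[int, int]:
        shared = specific = 0
        for iv in x:
            arr = y.chrom_array(iv.chrom)
            if len(arr):
                i = np.searchsorted(arr[:, 0], iv.end, side="left")
                hit = i > 0 and arr[i - 1, 1] > iv.start
            else:
                hit = False
            if hit:
                shared += 1
            else:
                specific += 1
        return shared, specific

    shared_a, a_specific = split(a, b)
    shared_b, b_specific = split(b, a)
    return (shared_a, shared_b), a_specific, b_specific
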