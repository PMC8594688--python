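"""Partially-methylated-domain (PMD) detection.

PMDs are large (>= 60 kb here) domains of intermediate (~40%)
methylation associated with late-replicating, inaccessible chromatin.
Detection is per sample: non-overlapping 20-kb windows are binarized
(1 when the pooled window level exceeds 60%, 0 otherwise), a two-state
Bernoulli hidden Markov model is fitted by Baum-Welch and decoded by
Viterbi, and maximal runs of the PMD state spanning at least
``min_windows`` windows become intervals. Group-level consensus keeps
bases supported by at least ``min_support`` samples and re-applies the
minimum-span filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    GenomicInterval,
    IntervalSet,
    MethylomeSample,
    ValidationError,
    merge_intervals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PmdParams",
    "WindowTrack",
    "binarize_windows",
    "decode_pmd_states",
    "consensus_pmds",
    "BernoulliHmm",
    "fit_hmm",
    "viterbi_path",
]

MISSING = -1  # symbol for windows without any covered CpG


@dataclass(frozen=True)
class PmdParams:
    window: int = 20_000
    level_threshold: float = 0.60
    min_windows: int = 3
    min_support: int = 3

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValidationError("window must be positive")
        if not 0.0 < self.level_threshold < 1.0:
            raise ValidationError("level_threshold must lie in (0, 1)")
        if self.min_windows < 1:
            raise ValidationError("min_windows must be >= 1")


@dataclass
class WindowTrack:
    """Binarized window methylation for one chromosome.

    ``symbols[i]`` is 1 when the pooled level of window i is strictly
    above the threshold, 0 when at or below it, and MISSING (-1) when the
    window holds no covered CpG. ``levels`` carries the pooled level
    (NaN for missing windows).
    """

    chrom: str
    window: int
    symbols: np.ndarray
    levels: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.symbols)


def binarize_windows(
    sample: MethylomeSample, params: PmdParams = PmdParams(), min_coverage: int = 5
) -> dict[str, WindowTrack]:
    """Tile each chromosome with non-overlapping windows and binarize.

    The window level is the read-pooled n_meth/n_total over CpGs with at
    least ``min_coverage`` reads. Windows tile from position 0; a partial
    terminal window is included.
    """
    filtered = sample.filter_coverage(min_coverage)
    tracks: dict[str, WindowTrack] = {}
    for chrom in sample.layout.chrom_names:
        length = sample.layout.lengths[chrom]
        n_windows = int(np.ceil(length / params.window))
        meth = np.zeros(n_windows)
        tot = np.zeros(n_windows)
        df = filtered.chrom_calls(chrom)
        if len(df):
            idx = df["pos"].to_numpy() // params.window
            np.add.at(meth, idx, df["n_meth"].to_numpy())
            np.add.at(tot, idx, df["n_total"].to_numpy())
        with np.errstate(invalid="ignore", divide="ignore"):
            levels = np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)
        symbols = np.full(n_windows, MISSING, dtype=np.int8)
        covered = tot > 0
        symbols[covered] = (levels[covered] > params.level_threshold).astype(np.int8)
        tracks[chrom] = WindowTrack(chrom, params.window, symbols, levels)
    return tracks


@dataclass(frozen=True)
class BernoulliHmm:
    """Two-state HMM with Bernoulli emissions on binary window symbols.

    State 0 is background (emits 1 with probability ``e_b``), state 1 is
    PMD (emits 0 with probability ``e_p``). ``trans[i, j]`` is the
    probability of moving from state i to state j; ``start`` the initial
    distribution.
    """

    e_b: float
    e_p: float
    trans: np.ndarray
    start: np.ndarray

    def emission_matrix(self) -> np.ndarray:
        # rows: state (background, pmd); columns: symbol (0, 1)
        return np.array(
            [[1.0 - self.e_b, self.e_b], [self.e_p, 1.0 - self.e_p]]
        )


def _default_init() -> BernoulliHmm:
    return BernoulliHmm(
        e_b=0.9,
        e_p=0.9,
        trans=np.array([[0.9, 0.1], [0.1, 0.9]]),
        start=np.array([0.5, 0.5]),
    )


_EPS = 1e-6


def fit_hmm(
    symbols: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    init: BernoulliHmm | None = None,
) -> BernoulliHmm:
    """Baum-Welch on a binary symbol sequence (missing already removed)."""
    obs = np.asarray(symbols, dtype=np.int64)
    model = init or _default_init()
    trans = model.trans.copy()
    start = model.start.copy()
    emis = model.emission_matrix()
    last_ll = -np.inf
    for _ in range(max_iter):
        B = emis[:, obs].T  # (T, 2) emission likelihoods
        T = len(obs)
        alpha = np.zeros((T, 2))
        scale = np.zeros(T)
        alpha[0] = start * B[0]
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for t in range(1, T):
            alpha[t] = (alpha[t - 1] @ trans) * B[t]
            scale[t] = alpha[t].sum()
            alpha[t] /= scale[t]
        beta = np.zeros((T, 2))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = trans @ (B[t + 1] * beta[t + 1])
            beta[t] /= scale[t + 1]
        ll = float(np.log(scale).sum())
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        xi_num = np.zeros((2, 2))
        for t in range(T - 1):
            x = (alpha[t][:, None] * trans) * (B[t + 1] * beta[t + 1])[None, :]
            xi_num += x / x.sum()
        start = gamma[0]
        denom = gamma[:-1].sum(axis=0)
        if T > 1 and (denom > 0).all():
            trans = xi_num / denom[:, None]
        for s in range(2):
            w = gamma[:, s].sum()
            if w > 0:
                emis[s, 0] = (gamma[:, s] * (obs == 0)).sum() / w
                emis[s, 1] = 1.0 - emis[s, 0]
        emis = np.clip(emis, _EPS, 1.0 - _EPS)
        emis /= emis.sum(axis=1, keepdims=True)
        trans = np.clip(trans, _EPS, 1.0 - _EPS)
        trans /= trans.sum(axis=1, keepdims=True)
        start = np.clip(start, _EPS, 1.0 - _EPS)
        start /= start.sum()
        if abs(ll - last_ll) < tol:
            break
        last_ll = ll
    return BernoulliHmm(e_b=float(emis[0, 1]), e_p=float(emis[1, 0]), trans=trans, start=start)


def viterbi_path(symbols: np.ndarray, model: BernoulliHmm) -> np.ndarray:
    """Most likely state path (0 = background, 1 = PMD); ties prefer background."""
    obs = np.asarray(symbols, dtype=np.int64)
    emis = np.log(model.emission_matrix())
    ltrans = np.log(model.trans)
    lstart = np.log(model.start)
    T = len(obs)
    delta = np.zeros((T, 2))
    psi = np.zeros((T, 2), dtype=np.int64)
    delta[0] = lstart + emis[:, obs[0]]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + ltrans  # (from, to)
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], [0, 1]] + emis[:, obs[t]]
    path = np.zeros(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def path_log_prob(symbols: np.ndarray, states: np.ndarray, model: BernoulliHmm) -> float:
    """Joint log-probability of (states, symbols) under the model."""
    obs = np.asarray(symbols, dtype=np.int64)
    emis = np.log(model.emission_matrix())
    lp = float(np.log(model.start[states[0]]) + emis[states[0], obs[0]])
    for t in range(1, len(obs)):
        lp += float(np.log(model.trans[states[t - 1], states[t]]) + emis[states[t], obs[t]])
    return lp


def decode_pmd_states(
    track: WindowTrack, params: PmdParams = PmdParams()
) -> list[GenomicInterval]:
    """Decode PMD intervals from one chromosome's binarized windows.

    Missing windows contribute no emission term and do not break runs:
    the HMM runs on the compressed non-missing sequence and decoded runs
    are mapped back to genomic windows, spanning any interior gaps.
    Chromosomes whose non-missing symbols are all identical cannot
    constrain a two-state model; they fall back to plain threshold runs
    (maximal all-0 stretches), with a logged notice.
    """
    present = track.symbols != MISSING
    idx = np.nonzero(present)[0]
    if len(idx) < params.min_windows:
        return []
    obs = track.symbols[idx].astype(np.int64)
    if len(np.unique(obs)) < 2:
        logger.info(
            "chromosome %s: single symbol value; falling back to threshold runs",
            track.chrom,
        )
        states = (obs == 0).astype(np.int64)
    else:
        model = fit_hmm(obs)
        states = viterbi_path(obs, model)
    return _states_to_intervals(track, idx, states, params)


def _states_to_intervals(
    track: WindowTrack, idx: np.ndarray, states: np.ndarray, params: PmdParams
) -> list[GenomicInterval]:
    intervals = []
    run_start = None
    prev = None
    for i, s in zip(idx, states):
        if s == 1:
            if run_start is None:
                run_start = i
            prev = i
        else:
            if run_start is not None:
                intervals.append((run_start, prev))
                run_start = None
    if run_start is not None:
        intervals.append((run_start, prev))
    out = []
    for first, last in intervals:
        n_span = last - first + 1  # spanned windows incl. interior missing
        if n_span < params.min_windows:
            continue
        out.append(
            GenomicInterval(
                track.chrom, int(first) * track.window, int(last + 1) * track.window
            )
        )
    return out


def detect_sample_pmds(
    sample: MethylomeSample, params: PmdParams = PmdParams(), min_coverage: int = 5
) -> IntervalSet:
    """Per-sample PMD calls across all chromosomes."""
    tracks = binarize_windows(sample, params, min_coverage=min_coverage)
    intervals = []
    for chrom in sample.layout.chrom_names:
        intervals.extend(decode_pmd_states(tracks[chrom], params))
    return merge_intervals(intervals, layout=sample.layout)


def consensus_pmds(
    per_sample: list[IntervalSet], params: PmdParams = PmdParams()
) -> IntervalSet:
    """Group consensus: bases supported by >= min_support samples.

    Support depth is computed base-wise (robust to ragged per-sample
    boundaries); the surviving runs must again span at least
    ``min_windows`` windows.
    """
    if len(per_sample) < params.min_support:
        raise ValidationError(
            f"need >= {params.min_support} samples, got {len(per_sample)}"
        )
    chroms = sorted({c for s in per_sample for c in s.chroms})
    layout = next((s.layout for s in per_sample if s.layout is not None), None)
    kept = []
    for chrom in chroms:
        deltas: dict[int, int] = {}
        for s in per_sample:
            for start, end in s.chrom_array(chrom):
                deltas[int(start)] = deltas.get(int(start), 0) + 1
                deltas[int(end)] = deltas.get(int(end), 0) - 1
        depth = 0
        run_start = None
        for pos in sorted(deltas):
            new_depth = depth + deltas[pos]
            if depth < params.min_support <= new_depth and run_start is None:
                run_start = pos
            elif run_start is not None and new_depth < params.min_support <= depth:
                if pos - run_start >= params.min_windows * params.window:
                    kept.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
            depth = new_depth
    return merge_intervals(kept, layout=layout)
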