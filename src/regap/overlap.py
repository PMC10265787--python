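"""Prior-guided overlap detection between placed reads.

Candidate pairs are restricted to reads whose prior positions differ by less
than a threshold delta_d (linear-time via sorting, instead of all-against-all).
For each candidate pair, a local alignment enumerates ALL significant overlap
configurations -- one per offset diagonal -- and the pattern most compatible
with the prior positions is selected, not the highest-scoring one.  Each
selected pattern becomes one observation y = beta_j - beta_i of the distance
between the two reads' ending bases.

The aligner scores substitutions only (short-read errors are overwhelmingly
substitutions; indel-free overlaps make each overlap configuration a single
diagonal of the DP matrix).  Up to ``max_hang`` bases may be trimmed from each
end of a diagonal, accommodating unaligned overhangs of dovetail overlaps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .preprocess import PlacedRead


@dataclass
class OverlapConfig:
    """Scoring and thresholds for overlap detection.

    ``delta_d`` fixes the candidate-pair prior-distance threshold; when None
    it is derived per pair as max(delta_d_mult * sqrt(v_i^2 + v_j^2),
    delta_d_floor) from the library insert-size SDs.
    """

    delta_d: Optional[float] = None
    delta_d_mult: float = 3.0
    delta_d_floor: float = 10.0
    match: int = 1
    mismatch: int = -2
    min_score: int = 15
    min_overlap: int = 15
    max_hang: int = 5
    dedup_window: int = 2

    def __post_init__(self):
        if self.delta_d is not None and self.delta_d <= 0:
            raise ValueError("delta_d must be positive")
        if self.min_overlap < 1 or self.min_score <= 0:
            raise ValueError("min_overlap >= 1 and min_score > 0 required")


@dataclass
class AlignmentPattern:
    """One significant overlap configuration between two reads.

    ``offset`` is the implied ending-base distance beta_j - beta_i.  Spans are
    0-based half-open on each read.  The score is re-derivable from the edit
    operations (match/mismatch over the aligned span).
    """

    offset: int
    score: int
    span_i: tuple[int, int]
    span_j: tuple[int, int]

    def edit_ops(self, seq_i: str, seq_j: str) -> str:
        a = seq_i[self.span_i[0] : self.span_i[1]]
        b = seq_j[self.span_j[0] : self.span_j[1]]
        return "".join("M" if x == y else "X" for x, y in zip(a, b))

    def rescore(self, seq_i: str, seq_j: str, cfg: OverlapConfig) -> int:
        ops = self.edit_ops(seq_i, seq_j)
        return ops.count("M") * cfg.match + ops.count("X") * cfg.mismatch


@dataclass
class OverlapObservation:
    """One detected overlap, a row of the regression model."""

    i: int
    j: int
    y: float
    score: int = 0
    weight: float = 1.0
    outlier: bool = False

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-overlap observation")


def candidate_pairs(placed: Sequence[PlacedRead], delta_d: float) -> list[tuple[int, int]]:
    """All unordered pairs with |p_i - p_j| < delta_d, by sort + sliding window."""
    order = sorted(range(len(placed)), key=lambda k: (placed[k].p, k))
    ps = [placed[k].p for k in order]
    out = []
    lo = 0
    for hi in range(len(order)):
        while ps[hi] - ps[lo] >= delta_d:
            lo += 1
        for k in range(lo, hi):
            a, b = order[k], order[hi]
            out.append((a, b) if a < b else (b, a))
    out.sort()
    return out


def _diagonal_scores(seq_i: str, seq_j: str, cfg: OverlapConfig):
    """Best trimmed segment score per offset diagonal, vectorized.

    Returns (offsets, scores, span starts/lengths) for all diagonals whose
    aligned length can reach ``min_overlap``.
    """
    a = np.frombuffer(seq_i.encode(), dtype="S1")
    b = np.frombuffer(seq_j.encode(), dtype="S1")
    L1, L2 = len(a), len(b)
    S = np.where(a[:, None] == b[None, :], cfg.match, cfg.mismatch).astype(np.int32)
    ndiag = L1 + L2 - 1
    D = np.zeros((L1, ndiag), dtype=np.int32)
    rows = np.arange(L1)[:, None]
    cols = (L1 - 1 - np.arange(L1))[:, None] + np.arange(L2)[None, :]
    D[rows, cols] = S
    P = np.zeros((L1 + 1, ndiag), dtype=np.int64)
    np.cumsum(D, axis=0, out=P[1:])
    c = np.arange(ndiag)
    d = c - (L1 - 1)  # j - i index shift of the diagonal
    i_lo = np.maximum(0, -d)
    i_hi = np.minimum(L1 - 1, L2 - 1 - d)
    length = i_hi - i_lo + 1

    h = cfg.max_hang
    best = np.full(ndiag, np.iinfo(np.int32).min, dtype=np.int64)
    best_s = np.zeros(ndiag, dtype=np.int64)
    best_e = np.zeros(ndiag, dtype=np.int64)
    for s in range(h + 1):
        for e in range(h + 1):
            ok = length - s - e >= cfg.min_overlap
            if not ok.any():
                continue
            top = np.clip(i_hi + 1 - e, 0, L1)
            bot = np.clip(i_lo + s, 0, L1)
            sc = P[top, c] - P[bot, c]
            sc = np.where(ok, sc, np.iinfo(np.int32).min)
            upd = sc > best
            best = np.where(upd, sc, best)
            best_s = np.where(upd, s, best_s)
            best_e = np.where(upd, e, best_e)
    offsets = (L2 - 1) - c
    return offsets, best, i_lo + best_s, length - best_s - best_e


def align_pair(r_i: PlacedRead, r_j: PlacedRead, cfg: OverlapConfig) -> list[AlignmentPattern]:
    """All significant overlap patterns between two reads.

    Patterns with score >= min_score and aligned length >= min_overlap, one
    per offset diagonal, deduplicated: a pattern within ``dedup_window`` bp of
    a higher-scoring pattern's offset is suppressed.  Sorted by descending
    score (ties: smaller |offset|).
    """
    if not r_i.seq or not r_j.seq:
        raise ValueError("cannot align empty sequences")
    L1, L2 = len(r_i.seq), len(r_j.seq)
    if min(L1, L2) < cfg.min_overlap:
        return []
    offsets, scores, starts, lengths = _diagonal_scores(r_i.seq, r_j.seq, cfg)
    sig = np.nonzero(scores >= cfg.min_score)[0]
    pats = []
    for k in sig:
        i0 = int(starts[k])
        ln = int(lengths[k])
        dshift = int(k) - (L1 - 1)
        pats.append(
            AlignmentPattern(
                offset=int(offsets[k]),
                score=int(scores[k]),
                span_i=(i0, i0 + ln),
                span_j=(i0 + dshift, i0 + dshift + ln),
            )
        )
    pats.sort(key=lambda p: (-p.score, abs(p.offset), p.offset))
    kept: list[AlignmentPattern] = []
    for p in pats:
        if all(abs(p.offset - q.offset) > cfg.dedup_window for q in kept):
            kept.append(p)
    return kept


def select_alignment(
    patterns: Sequence[AlignmentPattern], p_i: float, p_j: float
) -> Optional[AlignmentPattern]:
    """The pattern most compatible with the prior positions.

    argmin |offset - (p_j - p_i)|; ties go to the higher score, then to the
    smaller |offset|.  Empty input -> None.
    """
    if not patterns:
        return None
    prior = p_j - p_i
    return min(patterns, key=lambda p: (abs(p.offset - prior), -p.score, abs(p.offset)))


def pair_counts(
    placed: Sequence[PlacedRead],
    cfg: OverlapConfig,
    lib_sds: Sequence[float] = (1.0,),
) -> tuple[int, int]:
    """(all-against-all pair count C(n,2), prior-restricted candidate count).

    The first number is the denominator an all-against-all strategy would
    align; the second is what the prior restriction leaves.
    """
    n = len(placed)
    n_all = n * (n - 1) // 2
    if cfg.delta_d is not None:
        window = cfg.delta_d
    else:
        vmax = max(lib_sds)
        window = max(cfg.delta_d_mult * float(np.hypot(vmax, vmax)), cfg.delta_d_floor)
    n_cand = sum(
        1
        for i, j in candidate_pairs(placed, window)
        if abs(placed[i].p - placed[j].p) < _pair_delta_d(placed[i], placed[j], cfg, lib_sds)
    )
    return n_all, n_cand


def _pair_delta_d(r_i: PlacedRead, r_j: PlacedRead, cfg: OverlapConfig, lib_sds) -> float:
    if cfg.delta_d is not None:
        return cfg.delta_d
    vi = lib_sds[r_i.lib] if not r_i.is_pseudo else min(lib_sds)
    vj = lib_sds[r_j.lib] if not r_j.is_pseudo else min(lib_sds)
    return max(cfg.delta_d_mult * float(np.hypot(vi, vj)), cfg.delta_d_floor)


def build_observations(
    placed: Sequence[PlacedRead],
    cfg: OverlapConfig,
    lib_sds: Sequence[float] = (1.0,),
    use_weights: bool = False,
) -> list[OverlapObservation]:
    """Detect overlaps among placed reads and emit distance observations.

    With ``use_weights`` (multi-library input), each observation gets the
    initial weight (min library SD / max(SD_i, SD_j))^2; with one library all
    weights are 1.
    """
    if cfg.delta_d is not None:
        window = cfg.delta_d
    else:
        window = max(
            cfg.delta_d_mult * float(np.hypot(max(lib_sds), max(lib_sds))),
            cfg.delta_d_floor,
        )
    obs: list[OverlapObservation] = []
    vmin = min(lib_sds)
    for i, j in candidate_pairs(placed, window):
        r_i, r_j = placed[i], placed[j]
        if abs(r_i.p - r_j.p) >= _pair_delta_d(r_i, r_j, cfg, lib_sds):
            continue
        pat = select_alignment(align_pair(r_i, r_j, cfg), r_i.p, r_j.p)
        if pat is None:
            continue
        if use_weights:
            vi = lib_sds[r_i.lib] if not r_i.is_pseudo else vmin
            vj = lib_sds[r_j.lib] if not r_j.is_pseudo else vmin
            w = (vmin / max(vi, vj)) ** 2
        else:
            w = 1.0
        obs.append(OverlapObservation(i=i, j=j, y=float(pat.offset), score=pat.score, weight=w))
    return obs
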