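"""From fitted layouts to gap sequences: MSA, Bayesian consensus, anchoring.

Reads are placed at their estimated ending-base coordinates; each incoming
read is re-aligned to the running consensus within a small +/-band to absorb
residual 1-2 bp offsets (substitution-only, consistent with the short-read
error model).  Per column, the consensus base maximizes a Bayesian posterior
over {A,C,G,T} with a uniform prior and per-read error probabilities from
Phred scores (error spread evenly over the three wrong bases); posteriors are
converted back to Phred scores capped at 60.

The two pseudo reads anchor the consensus into the gap: both in one layout ->
the gap is closed with the consensus strictly between them; one pseudo read
-> the corresponding flank is extended; layouts containing neither pseudo
read are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .preprocess import PlacedRead
from .util import BASE_INDEX, BASES, phred_to_prob

PHRED_CAP = 60


@dataclass
class Layout:
    """A fitted component: reads with integer ending-base coordinates."""

    component_id: int
    members: list[tuple[PlacedRead, int]]

    def __post_init__(self):
        if not self.members:
            raise ValueError("layout needs at least one read")
        self.members.sort(key=lambda rc: (rc[1] - len(rc[0]) + 1, rc[0].read_id))

    @property
    def span(self) -> tuple[int, int]:
        """[min start, max end] of member reads on the gap axis (inclusive)."""
        lo = min(c - len(r) + 1 for r, c in self.members)
        hi = max(c for _, c in self.members)
        return lo, hi

    def contains(self, read: PlacedRead) -> bool:
        return any(r is read for r, _ in self.members)

    def coord_of(self, read: PlacedRead) -> int:
        for r, c in self.members:
            if r is read:
                return c
        raise KeyError(read.read_id)


@dataclass
class MSA:
    """Column matrix of (base, quality) votes, indexed on the gap axis."""

    start: int  # axis coordinate of column 0
    columns: list[list[tuple[str, int]]]
    placements: list[tuple[PlacedRead, int]]  # read, final start coordinate
    n_dropped: int = 0

    @property
    def width(self) -> int:
        return len(self.columns)


def build_msa(layout: Layout, band: int = 3, drop_floor: float = 0.75,
              min_realign_cols: int = 10) -> MSA:
    """Place layout reads into columns, banded-realigning each to the running
    consensus.

    Shifts within ``+/-band`` are tried; the shift maximizing matches minus
    mismatches against currently covered columns wins (ties: smaller |shift|,
    then the negative one).  A read whose best match fraction over >=
    ``min_realign_cols`` covered columns falls below ``drop_floor`` is dropped
    and counted.  Reads with a fixed anchor coordinate are never shifted.
    """
    lo, hi = layout.span
    width = hi - lo + 1 + 2 * band
    start = lo - band
    counts = np.zeros((4, width), dtype=np.int32)
    cov = np.zeros(width, dtype=np.int32)
    cur = np.full(width, -1, dtype=np.int8)  # current majority base index

    placements: list[tuple[PlacedRead, int]] = []
    dropped = 0
    votes: list[tuple[int, np.ndarray, PlacedRead]] = []

    for read, coord in layout.members:
        b_idx = np.array([BASE_INDEX.get(ch, -1) for ch in read.seq], dtype=np.int8)
        rstart = coord - len(read) + 1
        if read.anchor_coord is not None:
            shifts = [0]
        else:
            shifts = sorted(range(-band, band + 1), key=lambda s: (abs(s), s))
        best_shift, best_score, best_stats = 0, None, (0, 0)
        for s in shifts:
            c0 = rstart + s - start
            if c0 < 0 or c0 + len(read) > width:
                continue
            seg = cur[c0 : c0 + len(read)]
            valid = (seg >= 0) & (b_idx >= 0)
            matches = int(np.sum(valid & (seg == b_idx)))
            covered = int(np.sum(valid))
            score = 2 * matches - covered  # matches - mismatches
            if best_score is None or score > best_score:
                best_score, best_shift, best_stats = score, s, (matches, covered)
        matches, covered = best_stats
        if covered >= min_realign_cols and matches < drop_floor * covered:
            dropped += 1
            continue
        c0 = rstart + best_shift - start
        placements.append((read, rstart + best_shift))
        votes.append((c0, b_idx, read))
        valid = b_idx >= 0
        idx = np.nonzero(valid)[0]
        counts[b_idx[idx], c0 + idx] += 1
        cov[c0 + idx] += 1
        seg = slice(c0, c0 + len(read))
        cur[seg] = np.where(cov[seg] > 0, np.argmax(counts[:, seg], axis=0), -1)

    columns: list[list[tuple[str, int]]] = [[] for _ in range(width)]
    for c0, b_idx, read in votes:
        for k, bi in enumerate(b_idx):
            if bi >= 0:
                columns[c0 + k].append((BASES[bi], read.quals[k]))
    # trim unused band margins
    used = np.nonzero(cov > 0)[0]
    if len(used):
        first, last = int(used[0]), int(used[-1])
    else:
        first, last = 0, width - 1
    return MSA(
        start=start + first,
        columns=columns[first : last + 1],
        placements=placements,
        n_dropped=dropped,
    )


def call_consensus(msa: MSA, quality_aware: bool = True) -> tuple[str, list[int]]:
    """Consensus sequence and Phred qualities from an MSA.

    Per column the posterior over {A,C,G,T} uses a uniform prior and per-read
    error probability from its Phred score (``quality_aware``) or a flat 0.05
    (raw-count mode); the consensus base is the argmax, ties broken
    lexicographically; output Phred is -10 log10(1 - posterior) capped at 60.
    Zero-coverage columns inside the span yield 'N' with Phred 0.
    """
    seq = []
    quals = []
    for col in msa.columns:
        if not col:
            seq.append("N")
            quals.append(0)
            continue
        ll = np.zeros(4)
        for base, q in col:
            bi = BASE_INDEX.get(base, -1)
            if bi < 0:
                continue
            e = float(phred_to_prob(q)) if quality_aware else 0.05
            ll += math.log(e / 3.0)
            ll[bi] += math.log(1.0 - e) - math.log(e / 3.0)
        ll -= ll.max()
        post = np.exp(ll)
        post /= post.sum()
        bi = int(np.argmax(post))  # first max: lexicographic tie-break
        seq.append(BASES[bi])
        perr = max(1.0 - float(post[bi]), 10.0 ** (-PHRED_CAP / 10.0))
        quals.append(min(int(round(-10.0 * math.log10(perr))), PHRED_CAP))
    return "".join(seq), quals


@dataclass
class GapResult:
    """Outcome for one gap: status, consensus, and anchoring."""

    status: str  # closed | left_extended | right_extended | both_extended | unfilled
    sequence: str = ""
    qualities: list[int] = field(default_factory=list)
    filled_length: int = 0
    left_sequence: Optional[str] = None
    left_qualities: Optional[list[int]] = None
    right_sequence: Optional[str] = None
    right_qualities: Optional[list[int]] = None
    diagnostic: str = ""


def _slice(msa: MSA, seq: str, quals: list[int], lo_coord: int, hi_coord: int):
    """Restrict a called consensus to axis coordinates [lo, hi] inclusive."""
    a = max(lo_coord - msa.start, 0)
    b = min(hi_coord - msa.start + 1, msa.width)
    if b <= a:
        return "", []
    return seq[a:b], quals[a:b]


def _realigned_end(msa: MSA, read: PlacedRead, fallback: int) -> int:
    """Ending coordinate of ``read`` after banded re-alignment in the MSA.

    The re-aligned placement anchors a pseudo read more precisely than its
    fitted coordinate (residual 1-2 bp layout offsets are absorbed against
    the consensus of the overlapping reads).
    """
    for r, start in msa.placements:
        if r is read:
            return start + len(r) - 1
    return fallback


def _trim_n(seq: str, quals: list[int], from_right: bool) -> tuple[str, list[int]]:
    if from_right:
        t = seq.rstrip("N")
        return t, quals[: len(t)]
    t = seq.lstrip("N")
    k = len(seq) - len(t)
    return t, quals[k:]


def anchor_and_emit(
    layouts: Sequence[Layout],
    left_pseudo: Optional[PlacedRead],
    right_pseudo: Optional[PlacedRead],
    band: int = 3,
    quality_aware: bool = True,
) -> GapResult:
    """Anchor fitted layouts into the gap via the pseudo reads.

    Both pseudo reads in one layout -> closed, with the consensus strictly
    between their anchor points.  One pseudo read in a layout -> the
    corresponding flank is extended (both flanks may extend when the pseudo
    reads sit in different layouts).  Layouts with neither pseudo read are
    discarded.  Pseudo reads in inverted order yield ``unfilled`` with a
    diagnostic.
    """
    lay_l = next((L for L in layouts if left_pseudo is not None and L.contains(left_pseudo)), None)
    lay_r = next((L for L in layouts if right_pseudo is not None and L.contains(right_pseudo)), None)

    if lay_l is not None and lay_l is lay_r:
        msa = build_msa(lay_l, band=band)
        cseq, cquals = call_consensus(msa, quality_aware=quality_aware)
        beta_l = lay_l.coord_of(left_pseudo)  # anchored, never re-aligned
        beta_r = _realigned_end(msa, right_pseudo, lay_l.coord_of(right_pseudo))
        fill_len = beta_r - len(right_pseudo) - beta_l
        if beta_r <= beta_l or fill_len < 0:
            return GapResult(
                status="unfilled",
                diagnostic=f"pseudo reads in inverted order (left at {beta_l}, "
                f"right ends at {beta_r - len(right_pseudo)})",
            )
        seq, quals = _slice(msa, cseq, cquals, beta_l + 1, beta_r - len(right_pseudo))
        return GapResult(status="closed", sequence=seq, qualities=quals,
                         filled_length=len(seq))

    left_seq = left_quals = None
    right_seq = right_quals = None
    if lay_l is not None:
        msa = build_msa(lay_l, band=band)
        cseq, cquals = call_consensus(msa, quality_aware=quality_aware)
        beta_l = lay_l.coord_of(left_pseudo)
        _, hi = lay_l.span
        seq, quals = _slice(msa, cseq, cquals, beta_l + 1, hi)
        seq, quals = _trim_n(seq, quals, from_right=True)
        if seq:
            left_seq, left_quals = seq, quals
    if lay_r is not None:
        msa = build_msa(lay_r, band=band)
        cseq, cquals = call_consensus(msa, quality_aware=quality_aware)
        beta_r = _realigned_end(msa, right_pseudo, lay_r.coord_of(right_pseudo))
        lo, _ = lay_r.span
        seq, quals = _slice(msa, cseq, cquals, lo, beta_r - len(right_pseudo))
        seq, quals = _trim_n(seq, quals, from_right=False)
        if seq:
            right_seq, right_quals = seq, quals

    if left_seq and right_seq:
        return GapResult(
            status="both_extended",
            sequence=left_seq, qualities=left_quals,
            filled_length=len(left_seq) + len(right_seq),
            left_sequence=left_seq, left_qualities=left_quals,
            right_sequence=right_seq, right_qualities=right_quals,
        )
    if left_seq:
        return GapResult(
            status="left_extended", sequence=left_seq, qualities=left_quals,
            filled_length=len(left_seq),
            left_sequence=left_seq, left_qualities=left_quals,
        )
    if right_seq:
        return GapResult(
            status="right_extended", sequence=right_seq, qualities=right_quals,
            filled_length=len(right_seq),
            right_sequence=right_seq, right_qualities=right_quals,
        )
    return GapResult(status="unfilled", diagnostic="no layout contains a pseudo read")
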