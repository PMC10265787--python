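"""Library statistics, gap-size estimation, and gap-read collection.

The gap axis runs left to right along the genome; its origin (coordinate 0) is
the last base of the left flanking contig, so the first base inside the gap has
coordinate 1.  A read's position is the coordinate of its ending (rightmost)
base on this axis, and every collected read is oriented onto the forward gap
axis before assembly.

Prior positions: for a read recruited through an anchor on the left flank,
p = mu - d_anchor where d_anchor is the distance from the anchor's outermost
(leftmost) base to the left breakpoint; for a right-flank recruit,
p = G_hat - (mu - d_anchor) + read_length, with G_hat the estimated gap size
and d_anchor measured from the anchor's rightmost base to the right breakpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import DEFAULT_MAPQ_MIN, GapInterval, PairedAlignment
from .util import revcomp

log = logging.getLogger(__name__)


class InsufficientPairsError(ValueError):
    """Too few well-mapped pairs to estimate insert statistics."""


@dataclass
class LibraryProfile:
    """Insert-size statistics and orientation of one paired library.

    The insert size is the outer distance: leftmost base of the left read to
    the rightmost base of the right read.  ``mu`` is its mean and ``sd`` its
    standard deviation, in bp.
    """

    mu: float
    sd: float
    orientation: str = "FR"

    def __post_init__(self):
        if self.mu <= 0 or self.sd <= 0:
            raise ValueError("library mu and sd must be positive")
        if self.orientation not in ("FR", "RF"):
            raise ValueError("orientation must be FR or RF")

    @property
    def window(self) -> float:
        """Recruitment window from each breakpoint: mu + 3*sd."""
        return self.mu + 3.0 * self.sd


@dataclass
class PlacedRead:
    """A read placed on the gap axis with its prior coordinate.

    ``p`` is the prior coordinate of the read's ending base; ``anchor_coord``
    is a fixed coordinate for pseudo reads whose position is known exactly.
    """

    read_id: str
    seq: str
    quals: list[int]
    p: float
    lib: int = 0
    is_pseudo: bool = False
    anchor_coord: Optional[float] = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError("placed read has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def estimate_insert_stats(
    pairs: Iterable[PairedAlignment],
    mu: Optional[float] = None,
    sd: Optional[float] = None,
    orientation: str = "FR",
    min_pairs: int = 200,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> LibraryProfile:
    """Robustly estimate (mu, sd) from pairs with both mates uniquely mapped.

    mu = median insert, sd = 1.4826 * MAD (robust against chimeras), floored
    at 1.  User-supplied values bypass the estimator entirely.
    """
    if mu is not None and sd is not None:
        return LibraryProfile(mu=mu, sd=sd, orientation=orientation)
    inserts = []
    for pa in pairs:
        r1, r2 = pa.read1, pa.read2
        if r1 is None or r2 is None:
            continue
        if not (r1.is_unique(mapq_min) and r2.is_unique(mapq_min)):
            continue
        if r1.ref != r2.ref:
            continue
        fwd, rev = (r1, r2) if not r1.is_reverse else (r2, r1)
        if fwd.is_reverse or not rev.is_reverse:
            continue  # not FR
        if fwd.pos > rev.pos:
            continue  # outward-facing; not a proper FR pair
        inserts.append(rev.end - fwd.pos)
    if len(inserts) < min_pairs:
        raise InsufficientPairsError(
            f"only {len(inserts)} usable pairs (< {min_pairs}); "
            "supply the library mean and SD explicitly"
        )
    arr = np.asarray(inserts, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return LibraryProfile(mu=med, sd=max(1.4826 * mad, 1.0), orientation=orientation)


def spanning_gap_estimates(
    gap: GapInterval,
    pairs: Iterable[PairedAlignment],
    profile: LibraryProfile,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> list[float]:
    """Per-pair gap-size estimates mu - d_L - d_R from gap-spanning FR pairs."""
    ests: list[float] = []
    W = profile.window
    for pa in pairs:
        r1, r2 = pa.read1, pa.read2
        if r1 is None or r2 is None:
            continue
        if not (r1.is_unique(mapq_min) and r2.is_unique(mapq_min)):
            continue
        if r1.ref != gap.scaffold or r2.ref != gap.scaffold:
            continue
        fwd, rev = (r1, r2) if not r1.is_reverse else (r2, r1)
        if fwd.is_reverse or not rev.is_reverse:
            continue
        if fwd.end > gap.start or rev.pos < gap.end:
            continue  # not cleanly on the two flanks
        d_l = gap.start - fwd.pos
        d_r = rev.end - gap.end
        if d_l <= 0 or d_r <= 0 or d_l > W or d_r > W:
            continue
        ests.append(profile.mu - d_l - d_r)
    return ests


def estimate_gap_size(
    gap: GapInterval,
    pairs: Iterable[PairedAlignment],
    profile: LibraryProfile,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> int:
    """Estimate gap size from pairs spanning the gap on its two flanks.

    For each FR pair with the forward mate on the left flank and the reverse
    mate on the right flank, the gap size is mu - d_L - d_R, where d_L/d_R are
    the mates' outer distances from their breakpoints.  The median over pairs
    is returned, floored at 1; without any spanning pair the reported N-run
    length is used.
    """
    ests = spanning_gap_estimates(gap, pairs, profile, mapq_min)
    if not ests:
        return max(gap.reported_size, 1)
    return max(int(round(float(np.median(ests)))), 1)


def collect_gap_reads(
    gap: GapInterval,
    pairs: Iterable[PairedAlignment],
    profile: LibraryProfile,
    gap_size_est: int,
    lib: int = 0,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> list[PlacedRead]:
    """Collect reads inferred to originate in the gap, with prior coordinates.

    A pair is recruited when one mate (the anchor) is uniquely mapped within
    mu + 3*sd of a breakpoint and faces the gap; the other mate is collected.
    Left-flank recruits are reverse-complemented onto the forward gap axis (in
    an FR library the mate of a forward left-flank anchor was sequenced from
    the reverse strand); right-flank recruits are kept as sequenced.  Pairs
    whose anchor is multiply mapped are skipped.
    """
    W = profile.window
    mu = profile.mu
    out: list[PlacedRead] = []
    for pa in pairs:
        for anchor in pa.mates():
            if not anchor.is_unique(mapq_min) or anchor.ref != gap.scaffold:
                continue
            mate = pa.mate_of(anchor)
            if mate is None or not mate.seq:
                continue
            if not anchor.is_reverse:
                # candidate left-flank anchor, facing right into the gap
                d_anchor = gap.start - anchor.pos
                if d_anchor <= 0 or d_anchor > W:
                    continue
                p = mu - d_anchor
                seq = revcomp(mate.seq)
                quals = mate.quals[::-1]
            else:
                # candidate right-flank anchor, facing left into the gap
                d_anchor = anchor.end - gap.end
                if d_anchor <= 0 or d_anchor > W:
                    continue
                p = gap_size_est - (mu - d_anchor) + len(mate.seq)
                seq = mate.seq
                quals = list(mate.quals)
            suffix = "L" if not anchor.is_reverse else "R"
            out.append(
                PlacedRead(
                    read_id=f"{anchor.name}/{suffix}",
                    seq=seq,
                    quals=quals,
                    p=float(p),
                    lib=lib,
                )
            )
    return out


def make_pseudo_reads(
    gap: GapInterval,
    scaffolds: dict[str, str],
    gap_size_est: int,
    flank_len: int = 150,
    min_flank: int = 20,
) -> tuple[Optional[PlacedRead], Optional[PlacedRead]]:
    """Cut the two pseudo reads from the contig ends flanking the gap.

    The left pseudo read is the last ``flank_len`` bases of the left contig
    and anchors the axis origin (its ending base has coordinate 0).  The right
    pseudo read is the first ``flank_len`` bases of the right contig with
    prior ending coordinate G_hat + flank_len; it is anchored only after
    layout.  Flanks are truncated at N runs; a flank shorter than
    ``min_flank`` yields None on that side (gap unclosable from that side).
    """
    seq = scaffolds[gap.scaffold]
    left = seq[max(0, gap.start - flank_len) : gap.start]
    n_at = left.rfind("N")
    if n_at >= 0:
        left = left[n_at + 1 :]
    right = seq[gap.end : gap.end + flank_len]
    n_at = right.find("N")
    if n_at >= 0:
        right = right[:n_at]
    lp = rp = None
    if len(left) >= min_flank:
        lp = PlacedRead(
            read_id=f"{gap}/pseudoL",
            seq=left,
            quals=[40] * len(left),
            p=0.0,
            is_pseudo=True,
            anchor_coord=0.0,
        )
    if len(right) >= min_flank:
        rp = PlacedRead(
            read_id=f"{gap}/pseudoR",
            seq=right,
            quals=[40] * len(right),
            p=float(gap_size_est + len(right)),
            is_pseudo=True,
            anchor_coord=None,
        )
    return lp, rp
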