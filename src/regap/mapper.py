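"""A minimal exact-seed read mapper for small genomes.

Used by the iterative closing mode (each round needs read placements against
the updated genome) and by tests; for production-scale genomes an external
mapper's SAM/BAM is the intended input.  Seeds are non-overlapping exact
k-mers with unique genomic position; candidates are verified by full-length
substitution counting (N counts as a mismatch, so reads crossing N-runs come
out unmapped, as a real mapper behaves at gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io import AlignedRead, PairedAlignment
from .util import revcomp

_AMBIG = ("", -1)


class GenomeIndex:
    """Unique-position k-mer index over a set of scaffolds."""

    def __init__(self, scaffolds: dict[str, str], k: int = 31):
        self.k = k
        self.scaffolds = scaffolds
        self.index: dict[str, tuple[str, int]] = {}
        for sid, seq in scaffolds.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                if kmer in self.index:
                    self.index[kmer] = _AMBIG
                else:
                    self.index[kmer] = (sid, pos)

    def _candidates(self, seq: str) -> tuple[set[tuple[str, int]], bool]:
        cands: set[tuple[str, int]] = set()
        ambig = False
        k = self.k
        offs = list(range(0, max(len(seq) - k, 0) + 1, k))
        if offs and offs[-1] != len(seq) - k:
            offs.append(len(seq) - k)
        for off in offs:
            hit = self.index.get(seq[off : off + k])
            if hit is None:
                continue
            if hit == _AMBIG:
                ambig = True
                continue
            sid, pos = hit
            start = pos - off
            if 0 <= start and start + len(seq) <= len(self.scaffolds[sid]):
                cands.add((sid, start))
        return cands, ambig

    def map_read(self, seq: str, max_mismatch: Optional[int] = None):
        """Best placement of ``seq`` (either strand) or None.

        Returns (scaffold, start, is_reverse, n_mismatch, unique).
        """
        if len(seq) < self.k:
            return None
        if max_mismatch is None:
            max_mismatch = max(2, int(0.1 * len(seq)))
        hits = []
        ambig_any = False
        for is_rev, s in ((False, seq), (True, revcomp(seq))):
            cands, ambig = self._candidates(s)
            ambig_any |= ambig
            for sid, start in cands:
                ref = self.scaffolds[sid][start : start + len(s)]
                mm = sum(1 for a, b in zip(s, ref) if a != b or b == "N")
                if mm <= max_mismatch:
                    hits.append((mm, sid, start, is_rev))
        if not hits:
            return None
        hits.sort()
        mm, sid, start, is_rev = hits[0]
        unique = (len(hits) == 1 or hits[1][0] > mm) and not ambig_any
        return sid, start, is_rev, mm, unique


def map_pairs(
    scaffolds: dict[str, str],
    pairs: Sequence[tuple[str, str, list[int], str, list[int]]],
    k: int = 31,
) -> list[PairedAlignment]:
    """Map (name, seq1, quals1, seq2, quals2) records; returns paired records."""
    idx = GenomeIndex(scaffolds, k=k)
    out = []
    for name, s1, q1, s2, q2 in pairs:
        mates = []
        for first, s, q in ((True, s1, q1), (False, s2, q2)):
            hit = idx.map_read(s)
            if hit is None:
                mates.append(
                    AlignedRead(
                        name=name, ref=None, pos=-1, end=-1, mapq=0,
                        is_unmapped=True, is_reverse=False, is_read1=first,
                        seq=s, quals=list(q),
                    )
                )
            else:
                sid, start, is_rev, mm, unique = hit
                mates.append(
                    AlignedRead(
                        name=name, ref=sid, pos=start, end=start + len(s),
                        mapq=60 if unique else 0, is_unmapped=False,
                        is_reverse=is_rev, is_read1=first,
                        seq=s, quals=list(q),
                    )
                )
        out.append(PairedAlignment(read1=mates[0], read2=mates[1]))
    return out
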