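"""Reading and writing the standard formats the pipeline touches.

Coordinates are 0-based half-open everywhere in memory; SAM's 1-based POS is
converted at the boundary.  "Uniquely mapped" is operationalized as mapped with
MAPQ >= a threshold (default 20) and no XA/SA alternative-hit tags.
"""

from __future__ import annotations

import logging
import re
import textwrap
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

from .util import revcomp, qual_string

log = logging.getLogger(__name__)

DEFAULT_MAPQ_MIN = 20

_N_RUN = re.compile(r"[Nn]+")


@dataclass(frozen=True)
class GapInterval:
    """A maximal run of N in a scaffold: the target of local assembly."""

    scaffold: str
    start: int  # 0-based, first N
    end: int  # 0-based, one past last N
    left_flank_id: str = ""
    right_flank_id: str = ""

    @property
    def reported_size(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # used as gap id in reports
        return f"{self.scaffold}:{self.start}-{self.end}"


@dataclass
class AlignedRead:
    """One mate of a pair, normalized from a SAM record.

    ``seq``/``quals`` are in as-sequenced orientation (reverse-complemented
    back if the mapper stored the reference-forward sequence).
    """

    name: str
    ref: Optional[str]
    pos: int  # 0-based leftmost, -1 if unmapped
    end: int  # 0-based one-past-rightmost, -1 if unmapped
    mapq: int
    is_unmapped: bool
    is_reverse: bool
    is_read1: bool
    seq: str
    quals: list[int]
    has_alt: bool = False  # XA/SA tag present

    def is_unique(self, mapq_min: int = DEFAULT_MAPQ_MIN) -> bool:
        return (not self.is_unmapped) and self.mapq >= mapq_min and not self.has_alt


@dataclass
class PairedAlignment:
    """A mate pair; either mate may be absent (orphan) or unmapped."""

    read1: Optional[AlignedRead]
    read2: Optional[AlignedRead]

    def mates(self) -> list[AlignedRead]:
        return [r for r in (self.read1, self.read2) if r is not None]

    def mate_of(self, read: AlignedRead) -> Optional[AlignedRead]:
        return self.read2 if read is self.read1 else self.read1


def find_gaps(scaffolds: dict[str, str], min_n: int = 1) -> list[GapInterval]:
    """Locate maximal runs of >= ``min_n`` consecutive N/n per scaffold.

    Scaffolds that are entirely N are skipped with a warning (a gap needs two
    flanks).  Output is sorted by (scaffold insertion order, start).
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    gaps: list[GapInterval] = []
    for sid, seq in scaffolds.items():
        runs = [m for m in _N_RUN.finditer(seq) if m.end() - m.start() >= min_n]
        if runs and runs[0].start() == 0 and runs[0].end() == len(seq):
            log.warning("scaffold %s is all N; skipped", sid)
            continue
        for k, m in enumerate(runs):
            gaps.append(
                GapInterval(
                    scaffold=sid,
                    start=m.start(),
                    end=m.end(),
                    left_flank_id=f"{sid}.ctg{k}",
                    right_flank_id=f"{sid}.ctg{k + 1}",
                )
            )
    return gaps


def _normalize(rec: pysam.AlignedSegment) -> AlignedRead:
    seq = rec.query_sequence or ""
    quals = list(rec.query_qualities) if rec.query_qualities is not None else [30] * len(seq)
    if rec.is_reverse and not rec.is_unmapped:
        # mapper stored reference-forward sequence; restore as-sequenced
        seq = revcomp(seq)
        quals = quals[::-1]
    return AlignedRead(
        name=rec.query_name,
        ref=rec.reference_name if not rec.is_unmapped else None,
        pos=rec.reference_start if not rec.is_unmapped else -1,
        end=rec.reference_end if (not rec.is_unmapped and rec.reference_end is not None) else -1,
        mapq=rec.mapping_quality,
        is_unmapped=rec.is_unmapped,
        is_reverse=rec.is_reverse,
        is_read1=not rec.is_read2,
        seq=seq,
        quals=quals,
        has_alt=rec.has_tag("XA") or rec.has_tag("SA"),
    )


def read_alignments(path: str) -> Iterator[PairedAlignment]:
    """Yield mate-paired records from a SAM/BAM file.

    Secondary and supplementary records are dropped.  Records are grouped by
    query name; an orphan mate yields a pair with the other slot ``None``.
    """
    groups: dict[str, list[AlignedRead]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            r = _normalize(rec)
            if rec.query_name not in groups:
                groups[rec.query_name] = []
                order.append(rec.query_name)
            groups[rec.query_name].append(r)
    for name in order:
        recs = groups[name]
        r1 = next((r for r in recs if r.is_read1), None)
        r2 = next((r for r in recs if not r.is_read1), None)
        yield PairedAlignment(read1=r1, read2=r2)


def parse_sam_text(text: str) -> list[PairedAlignment]:
    """Parse in-memory SAM text into paired records (convenience wrapper)."""
    import os
    import tempfile

    fd, path = tempfile.mkstemp(suffix=".sam")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        return list(read_alignments(path))
    finally:
        os.unlink(path)


def write_fasta(scaffolds: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sid, seq in scaffolds.items():
            fh.write(f">{sid}\n")
            for line in textwrap.wrap(seq, width, break_on_hyphens=False):
                fh.write(line + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq(records: Iterable[tuple[str, str, list[int]]], path: str) -> None:
    """Write (id, sequence, integer quals) records as 4-line Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, quals in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_string(quals)}\n")


def splice_gap_results(scaffolds: dict[str, str], gaps, results) -> dict[str, str]:
    """Splice per-gap consensus results into the draft.

    ``results`` maps gap id (``str(gap)``) to a GapResult.  Closed gaps replace
    the whole N-run; extensions shorten it from the corresponding side.  All
    non-gap bases are preserved byte-for-byte.
    """
    out = dict(scaffolds)
    by_scaffold: dict[str, list] = {}
    for gap in gaps:
        by_scaffold.setdefault(gap.scaffold, []).append(gap)
    for sid, sgaps in by_scaffold.items():
        seq = out[sid]
        for gap in sorted(sgaps, key=lambda g: g.start, reverse=True):
            res = results.get(str(gap))
            if res is None or res.status == "unfilled":
                continue
            n = gap.reported_size
            if res.status == "closed":
                fill = res.sequence
            else:
                left = res.left_sequence or ""
                right = res.right_sequence or ""
                # Extensions estimated from the two sides independently must
                # never meet: truncate to leave >= 1 N, otherwise the junction
                # would duplicate sequence and poison later mapping rounds.
                budget = n - 1
                kl = min(len(left), budget - min(len(right), budget // 2)) \
                    if len(left) + len(right) > budget else len(left)
                kr = min(len(right), budget - kl)
                left, right = left[:kl], right[len(right) - kr :]
                fill = left + "N" * (n - kl - kr) + right
            seq = seq[: gap.start] + fill + seq[gap.end :]
        out[sid] = seq
    return out


def write_result_genome(
    scaffolds: dict[str, str],
    gaps,
    results,
    stats: Optional[dict] = None,
    fasta_path: Optional[str] = None,
    fastq_path: Optional[str] = None,
    report_path: Optional[str] = None,
):
    """Write the gap-filled genome, per-gap consensus FASTQ, and a TSV report.

    Returns (spliced scaffolds, report DataFrame).
    """
    import pandas as pd

    spliced = splice_gap_results(scaffolds, gaps, results)
    rows = []
    fq_records = []
    for gap in gaps:
        gid = str(gap)
        res = results.get(gid)
        st = stats.get(gid, {}) if stats else {}
        status = res.status if res is not None else "unfilled"
        filled = res.filled_length if res is not None else 0
        rows.append(
            {
                "gap": gid,
                "status": status,
                "filled_length": filled,
                "n_reads": st.get("n_reads", 0),
                "n_observations": st.get("n_observations", 0),
                "n_outliers": st.get("n_outliers", 0),
            }
        )
        if res is not None and res.sequence:
            fq_records.append((f"{gid}|{status}", res.sequence, res.qualities))
    report = pd.DataFrame(rows)
    if fasta_path:
        write_fasta(spliced, fasta_path)
    if fastq_path:
        write_fastq(fq_records, fastq_path)
    if report_path:
        report.to_csv(report_path, sep="\t", index=False)
    return spliced, report
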