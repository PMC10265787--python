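"""Synthetic genomes, drafts with N-gaps, and paired reads with ground truth.

The simulator emulates the data a gap closer sees: a reference carrying
implanted tandem repeats, a draft in which known intervals are masked by N
runs (whose reported length may deviate from the true span, mimicking
estimated gap sizes), and an FR paired-end library with truncated-normal
insert sizes, uniform substitution errors, and a fixture SAM that places each
read at its true position on the draft, with reads originating inside gaps
flagged unmapped -- what a mapper produces for reads from N-runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .preprocess import LibraryProfile
from .util import revcomp, qual_string

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class RepeatSpec:
    """A tandem repeat to implant: ``unit`` repeated ``copies`` times.

    ``copies`` may be fractional; the implanted span is
    round(copies * len(unit)) bases of the periodic extension of ``unit``.
    """

    unit: str
    copies: float
    locus: int

    def __post_init__(self):
        if not self.unit or set(self.unit) - set("ACGT"):
            raise ValueError("repeat unit must be non-empty over {A,C,G,T}")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.locus < 0:
            raise ValueError("locus must be >= 0")

    @property
    def span(self) -> int:
        return int(round(self.copies * len(self.unit)))

    @property
    def sequence(self) -> str:
        reps = -(-self.span // len(self.unit))  # ceil
        return (self.unit * reps)[: self.span]


@dataclass
class SimTruth:
    """Ground truth for a simulated scenario.

    ``read_truth`` maps read id -> (genome offset of the read's ending base,
    as-sequenced strand).  ``reported_sizes`` are the N-run lengths written
    into the draft (possibly != true interval lengths).
    """

    genome: str
    gap_intervals: list[tuple[int, int]] = field(default_factory=list)
    reported_sizes: list[int] = field(default_factory=list)
    draft: str = ""
    read_truth: dict[str, tuple[int, str]] = field(default_factory=dict)
    library: Optional[LibraryProfile] = None

    def true_gap_sequence(self, k: int) -> str:
        s, e = self.gap_intervals[k]
        return self.genome[s:e]


@dataclass
class SimReads:
    """Simulated paired reads: FASTQ-ready records plus a fixture SAM."""

    pairs: list[tuple[str, str, list[int], str, list[int]]]  # id, seq1, q1, seq2, q2
    sam_text: str
    truth: SimTruth


def simulate_genome(
    length: int,
    repeats: Sequence[RepeatSpec] = (),
    gc: float = 0.5,
    seed: int = 0,
) -> str:
    """Random genome of ``length`` bp with each repeat implanted verbatim.

    Deterministic for a fixed seed.  Implanted spans must fit inside the
    genome and must not overlap each other.
    """
    spans = sorted((r.locus, r.locus + r.span) for r in repeats)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if e1 > s2:
            raise ValueError("implanted repeat spans overlap")
    if spans and spans[-1][1] > length:
        raise ValueError("repeat span exceeds genome length")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(BASES, size=length, p=probs)
    genome = arr.tobytes().decode()
    for r in repeats:
        genome = genome[: r.locus] + r.sequence + genome[r.locus + r.span :]
    return genome


def make_draft(
    genome: str,
    gap_intervals: Sequence[tuple[int, int]],
    reported_sizes: Optional[Sequence[int]] = None,
) -> tuple[str, SimTruth]:
    """Mask intervals of the genome with N runs, recording the truth.

    ``reported_sizes`` lets the N-run length differ from the true span to
    mimic imperfectly estimated gap sizes (default: exact).  Intervals must be
    disjoint, sorted, and leave sequence on both sides.
    """
    ivs = sorted(tuple(iv) for iv in gap_intervals)
    for (s, e) in ivs:
        if not (0 < s < e < len(genome)):
            raise ValueError(f"gap interval {(s, e)} must leave flanks on both sides")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if e1 > s2:
            raise ValueError("gap intervals overlap")
    if reported_sizes is None:
        rep = [e - s for s, e in ivs]
    else:
        rep = [int(r) for r in reported_sizes]
        if len(rep) != len(ivs):
            raise ValueError("one reported size per interval required")
        if any(r < 1 for r in rep):
            raise ValueError("reported sizes must be >= 1")
    draft = []
    prev = 0
    for (s, e), r in zip(ivs, rep):
        draft.append(genome[prev:s])
        draft.append("N" * r)
        prev = e
    draft.append(genome[prev:])
    truth = SimTruth(
        genome=genome,
        gap_intervals=list(ivs),
        reported_sizes=rep,
        draft="".join(draft),
    )
    return truth.draft, truth


def _genome_to_draft_offsets(truth: SimTruth) -> list[tuple[int, int, int]]:
    """(segment start, segment end, draft shift) for inter-gap segments."""
    segs = []
    prev = 0
    shift = 0
    for (s, e), r in zip(truth.gap_intervals, truth.reported_sizes):
        segs.append((prev, s, shift))
        shift += r - (e - s)
        prev = e
    segs.append((prev, len(truth.genome), shift))
    return segs


def simulate_paired_reads(
    truth: SimTruth,
    lib: LibraryProfile,
    read_len: int = 100,
    coverage: float = 30.0,
    err_rate: float = 0.0,
    seed: int = 0,
    scaffold_id: str = "scaffold1",
) -> SimReads:
    """Simulate an inward-facing (FR) paired-end library with a fixture SAM.

    Insert sizes follow Normal(mu, sd^2) truncated to [2*read_len, mu+5*sd];
    substitution errors occur at ``err_rate`` with matching Phred qualities.
    The SAM places each read at its true position on the draft; reads whose
    true span intersects a gap are written unmapped (their mates mapped).
    """
    from scipy.stats import truncnorm

    genome = truth.genome
    G = len(genome)
    mu, sd = lib.mu, lib.sd
    if mu <= read_len:
        raise ValueError("library mean insert must exceed the read length")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    lo, hi = 2 * read_len, mu + 5 * sd
    if lo >= hi:
        raise ValueError("truncation window empty: mu too small for read length")
    n_pairs = int(round(coverage * G / (2 * read_len)))
    rng = np.random.default_rng(seed)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    inserts = np.rint(
        truncnorm.rvs(a, b, loc=mu, scale=sd, size=n_pairs, random_state=rng)
    ).astype(int)
    inserts = np.clip(inserts, lo, min(int(hi), G))
    starts = rng.integers(0, G - inserts + 1)

    q_err = max(err_rate, 1e-4)
    base_q = min(int(round(-10 * np.log10(q_err))), 40)
    segs = _genome_to_draft_offsets(truth)

    def to_draft(s: int, e: int) -> Optional[int]:
        """Draft offset of genome position s for a read spanning [s, e)."""
        for gs, ge in truth.gap_intervals:
            if s < ge and e > gs:
                return None
        for seg_s, seg_e, shift in segs:
            if seg_s <= s and e <= seg_e:
                return s + shift
        return None

    def mutate(seq: str) -> tuple[str, list[int]]:
        quals = [base_q] * len(seq)
        if err_rate <= 0:
            return seq, quals
        hits = np.nonzero(rng.random(len(seq)) < err_rate)[0]
        if len(hits) == 0:
            return seq, quals
        s = list(seq)
        for i in hits:
            s[i] = "ACGT"[(("ACGT".index(s[i]) + rng.integers(1, 4)) % 4)]
        return "".join(s), quals

    pairs = []
    sam = [
        "@HD\tVN:1.6\tSO:queryname",
        f"@SQ\tSN:{scaffold_id}\tLN:{len(truth.draft) if truth.draft else G}",
    ]
    rt = truth.read_truth
    for k in range(n_pairs):
        s = int(starts[k])
        ins = int(inserts[k])
        e = s + ins
        name = f"pair{k:07d}"
        left_true = genome[s : s + read_len]
        right_true = revcomp(genome[e - read_len : e])
        seq1, q1 = mutate(left_true)
        seq2, q2 = mutate(right_true)
        pairs.append((name, seq1, q1, seq2, q2))
        # ending base on the forward genome axis (0-based, inclusive)
        rt[name + "/1"] = (s + read_len - 1, "+")
        rt[name + "/2"] = (e - 1, "-")
        pos1 = to_draft(s, s + read_len)
        pos2 = to_draft(e - read_len, e)
        for first, seq, q, pos, other_pos, rev in (
            (True, seq1, q1, pos1, pos2, False),
            (False, seq2, q2, pos2, pos1, True),
        ):
            flag = 0x1 | (0x40 if first else 0x80)
            if pos is None:
                flag |= 0x4
                out_seq, out_q = seq, q
                p_self = other_pos if other_pos is not None else 0
            else:
                if rev:
                    flag |= 0x10
                    out_seq, out_q = revcomp(seq), q[::-1]
                else:
                    out_seq, out_q = seq, q
                p_self = pos
            if other_pos is None:
                flag |= 0x8
            elif not rev:
                flag |= 0x20  # mate on reverse strand
            cigar = "*" if pos is None else f"{read_len}M"
            mapq = 0 if pos is None else 60
            pnext = (other_pos if other_pos is not None else p_self) + 1
            tlen = 0
            sam.append(
                "\t".join(
                    [
                        name,
                        str(flag),
                        scaffold_id,
                        str(p_self + 1),
                        str(mapq),
                        cigar,
                        "=",
                        str(pnext),
                        str(tlen),
                        out_seq,
                        qual_string(out_q),
                    ]
                )
            )
    truth.library = lib
    return SimReads(pairs=pairs, sam_text="\n".join(sam) + "\n", truth=truth)


def simulate_benchmark_scenario(
    seed: int,
    length: int = 50000,
    coverage: float = 30.0,
    mu: float = 500.0,
    sd: float = 50.0,
    err_rate: float = 0.01,
    read_len: int = 100,
) -> SimReads:
    """The package's standard end-to-end benchmark: 50 kb, 10 gaps, 30x FR.

    Three of the ten gaps span implanted tandem repeats (7 bp x3, 11 bp x4,
    23 bp x2.5) whose total spans lie below the read length -- the regime a
    mu=500/sd=50 short-read library can resolve; spans beyond the read length
    additionally need tighter inserts or higher coverage.  Gap sizes range
    from 100 to 250 bp.
    """
    reps = [
        RepeatSpec("GAACCCT", 3.0, 5200),
        RepeatSpec("GATTACACGGT", 4.0, 15200),
        RepeatSpec("ACGGATTGCACCGTAAGGCTCAT", 2.5, 25200),
    ]
    genome = simulate_genome(length, reps, seed=seed * 1000 + 11)
    centers = [5230, 15230, 25230] + [2500 + 5000 * k for k in (1, 2, 4, 5, 6, 7, 9)]
    sizes = [140, 190, 120, 200, 150, 250, 100, 180, 220, 160]
    intervals = sorted((c - s // 2, c - s // 2 + s) for c, s in zip(centers, sizes))
    _, truth = make_draft(genome, intervals)
    lib = LibraryProfile(mu=mu, sd=sd)
    return simulate_paired_reads(truth, lib, read_len=read_len, coverage=coverage,
                                 err_rate=err_rate, seed=seed * 1000 + 12)


def simulate_overlap_graph(
    n: int,
    m: int,
    outlier_frac: float,
    seed: int,
    spacing: float = 10.0,
    noise_sd: float = 0.3,
    outlier_scale: float = 80.0,
    max_outliers_per_read: int = 2,
):
    """Random overlap-observation instance with known truth and gross outliers.

    Built so the Huber minimum is unique (a requirement for pointwise
    comparison against an independent convex minimizer): good observations
    carry noise well inside the quadratic zone (overlap errors of short reads
    are mostly zero), outliers hit only long-range skip observations, and the
    clean backbone keeps a strict majority across every graph cut (at most 2
    outliers cross any cut, against 4 backbone rows).  A cut crossed only by
    balanced linear-regime rows would otherwise leave a flat valley of
    minimizers; the requested outlier fraction is therefore realized only up
    to this identifiability cap.

    Returns (observations, truth coordinates).
    """
    from .overlap import OverlapObservation

    rng = np.random.default_rng(seed)
    truth = np.arange(n) * spacing

    def clean(i, j):
        return OverlapObservation(i=i, j=j,
                                  y=float(truth[j] - truth[i] + rng.normal(0, noise_sd)))

    obs = []
    for lag in (1, 1, 2):  # duplicated chain (coverage) + short skips
        obs.extend(clean(i, i + lag) for i in range(n - lag))
    extra = []
    while len(obs) + len(extra) < m:
        i = int(rng.integers(0, n - 3))
        j = min(int(i + rng.integers(3, 6)), n - 1)  # long-range skips, span 3-5
        extra.append(clean(i, j))
    k = min(int(round(outlier_frac * m)), len(extra))
    per_node = np.zeros(n, dtype=int)
    per_cut = np.zeros(n - 1, dtype=int)  # cut c separates nodes <= c from > c
    made = 0
    for idx in rng.permutation(len(extra)):
        if made == k:
            break
        o = extra[idx]
        if per_node[o.i] >= max_outliers_per_read or per_node[o.j] >= max_outliers_per_read:
            continue
        if np.any(per_cut[o.i : o.j] >= 2):
            continue
        extra[idx] = OverlapObservation(
            i=o.i, j=o.j, y=o.y + float(rng.choice([-1, 1])) * outlier_scale
        )
        per_node[o.i] += 1
        per_node[o.j] += 1
        per_cut[o.i : o.j] += 1
        made += 1
    return obs + extra, truth


def simulate_confused_chain(
    n: int,
    unit: int,
    frac_false: float,
    seed: int,
    spacing: float = 10.0,
    dup: int = 3,
    max_lag: int = 9,
    frac_two_unit: float = 0.2,
):
    """Chain layout with repeat-unit-confused false overlaps.

    Reads sit every ``spacing`` bp; each pair within ``max_lag`` neighbors is
    observed ``dup`` times (read-overlap reach and coverage).  A fraction of
    observations are false overlaps offset by +unit (or +2*unit for a smaller
    share), the one-sided error structure a tandem repeat induces when an
    alignment slips by whole units.

    Returns (observations, truth coordinates).
    """
    from .overlap import OverlapObservation

    rng = np.random.default_rng(seed)
    truth = np.arange(n) * spacing
    edges = []
    for lag in range(1, max_lag + 1):
        for i in range(n - lag):
            edges.extend([(i, i + lag)] * dup)
    m = len(edges)
    false_idx = set(map(int, rng.choice(m, size=int(round(frac_false * m)), replace=False)))
    obs = []
    for k, (i, j) in enumerate(edges):
        y = float(truth[j] - truth[i])
        if k in false_idx:
            y += (2 * unit) if rng.random() < frac_two_unit else unit
        obs.append(OverlapObservation(i=i, j=j, y=y))
    return obs, truth


def write_sim_files(sim: SimReads, prefix: str) -> dict[str, str]:
    """Write FASTQ pair files and the fixture SAM; returns the paths."""
    from .io import write_fastq

    p1, p2, ps = f"{prefix}_1.fastq", f"{prefix}_2.fastq", f"{prefix}.sam"
    write_fastq(((n + "/1", s1, q1) for n, s1, q1, _, _ in sim.pairs), p1)
    write_fastq(((n + "/2", s2, q2) for n, _, _, s2, q2 in sim.pairs), p2)
    with open(ps, "w") as fh:
        fh.write(sim.sam_text)
    return {"fastq1": p1, "fastq2": p2, "sam": ps}
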