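"""Shared fixtures: simulated gap-closing scenarios built at test time."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from regap.io import PairedAlignment, read_alignments
from regap.preprocess import LibraryProfile
from regap.simulate import RepeatSpec, SimTruth, make_draft, simulate_genome, simulate_paired_reads


@dataclass
class SimCase:
    """A simulated draft + library + parsed fixture alignments."""

    genome: str
    draft: str
    truth: SimTruth
    lib: LibraryProfile
    pairs: list[PairedAlignment]

    @property
    def scaffolds(self) -> dict[str, str]:
        return {"scaffold1": self.draft}


def build_sim_case(
    tmp_path,
    length: int,
    repeats,
    gap_intervals,
    mu: float,
    sd: float,
    read_len: int = 100,
    coverage: float = 40.0,
    err_rate: float = 0.0,
    seed: int = 1,
    reported_sizes=None,
) -> SimCase:
    genome = simulate_genome(length, repeats, seed=seed)
    draft, truth = make_draft(genome, gap_intervals, reported_sizes=reported_sizes)
    lib = LibraryProfile(mu=mu, sd=sd)
    sim = simulate_paired_reads(truth, lib, read_len=read_len, coverage=coverage,
                                err_rate=err_rate, seed=seed + 1000)
    sam = tmp_path / "fixture.sam"
    sam.write_text(sim.sam_text)
    pairs = list(read_alignments(str(sam)))
    return SimCase(genome=genome, draft=draft, truth=truth, lib=lib, pairs=pairs)


@pytest.fixture(scope="session")
def repeat_gap_case(tmp_path_factory) -> SimCase:
    """A triple 'GAACCCT' tandem repeat spanned by a gap; noiseless reads.

    The classic hard case for gap closers: the repeat copy number must be
    resolved from insert-size priors, not from alignment scores alone.
    """
    tmp = tmp_path_factory.mktemp("repeat_gap")
    rep = RepeatSpec(unit="GAACCCT", copies=3, locus=2500)
    return build_sim_case(
        tmp, length=5000, repeats=[rep], gap_intervals=[(2495, 2530)],
        mu=300, sd=10, coverage=40, err_rate=0.0, seed=1,
    )


@pytest.fixture(scope="session")
def plain_gap_case(tmp_path_factory) -> SimCase:
    """Two repeat-free gaps in a 6 kb genome; noiseless reads.

    The library (mu=400, reads of 50 bp) comfortably spans the 100/80 bp gaps,
    so gap-size estimation from spanning pairs is essentially unbiased.
    """
    tmp = tmp_path_factory.mktemp("plain_gap")
    return build_sim_case(
        tmp, length=6000, repeats=[], gap_intervals=[(1800, 1900), (4100, 4180)],
        mu=400, sd=20, read_len=50, coverage=40, err_rate=0.0, seed=3,
    )
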