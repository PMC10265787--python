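"""Overlap detection: candidate restriction, alignment patterns, selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regap.overlap import (
    AlignmentPattern,
    OverlapConfig,
    OverlapObservation,
    align_pair,
    build_observations,
    candidate_pairs,
    pair_counts,
    select_alignment,
)
from regap.preprocess import PlacedRead


def _pr(seq, p, rid="r", lib=0):
    return PlacedRead(read_id=rid, seq=seq, quals=[30] * len(seq), p=float(p), lib=lib)


def brute_force_pairs(placed, delta_d):
    return sorted(
        (i, j)
        for i, j in itertools.combinations(range(len(placed)), 2)
        if abs(placed[i].p - placed[j].p) < delta_d
    )


def brute_force_best_segment(a, b, offset_diag, cfg):
    """Naive per-diagonal best trimmed-segment score (independent oracle)."""
    # diagonal: positions (i, i+d) with d = (len(b)-1) - c ... recover pairs directly
    pairs = [(i, j) for i in range(len(a)) for j in range(len(b))
             if (len(b) - len(a)) + (i - j) == offset_diag]
    if not pairs:
        return None
    scores = [cfg.match if a[i] == b[j] else cfg.mismatch for i, j in pairs]
    n = len(scores)
    best = None
    for s in range(cfg.max_hang + 1):
        for e in range(cfg.max_hang + 1):
            if n - s - e < cfg.min_overlap:
                continue
            val = sum(scores[s : n - e])
            best = val if best is None or val > best else best
    return best


class TestCandidatePairs:
    def test_close_priors_paired(self):
        placed = [_pr("ACGTACGTACGT", 11), _pr("ACGTACGTACGT", 16)]
        assert candidate_pairs(placed, 11) == [(0, 1)]  # |11-16| = 5 < 11

    def test_equal_priors_always_paired(self):
        placed = [_pr("ACGT" * 4, 5), _pr("TTGA" * 4, 5)]
        assert candidate_pairs(placed, 0.5) == [(0, 1)]

    def test_matches_brute_force_on_nine_reads(self):
        rng = np.random.default_rng(42)
        placed = [_pr("ACGT" * 3, p) for p in rng.uniform(0, 60, size=9)]
        assert len(list(itertools.combinations(range(9), 2))) == 36
        for dd in (1.0, 11.0, 30.0, 100.0):
            assert candidate_pairs(placed, dd) == brute_force_pairs(placed, dd)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        priors=st.lists(st.floats(-500, 500), min_size=2, max_size=25),
        delta_d=st.floats(0.5, 200),
    )
    def test_equals_brute_force_property(self, priors, delta_d):
        placed = [_pr("ACGTACGT", p) for p in priors]
        assert candidate_pairs(placed, delta_d) == brute_force_pairs(placed, delta_d)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(priors=st.lists(st.floats(-100, 100), min_size=2, max_size=15))
    def test_shrinking_window_is_monotone(self, priors):
        placed = [_pr("ACGTACGT", p) for p in priors]
        small = set(candidate_pairs(placed, 10.0))
        large = set(candidate_pairs(placed, 40.0))
        assert small <= large


class TestAlignPair:
    def test_identical_reads_single_zero_offset(self):
        r = _pr("ACGTACGT", 0)
        cfg = OverlapConfig(min_score=5, min_overlap=5)
        (pat,) = align_pair(r, r, cfg)
        assert (pat.offset, pat.score) == (0, 8 * cfg.match)

    def test_disjoint_sequences_no_pattern(self):
        cfg = OverlapConfig(min_score=1, min_overlap=4)
        assert align_pair(_pr("AAAAAAAA", 0), _pr("CCCCCCCC", 0), cfg) == []

    def test_tandem_repeat_patterns_at_unit_multiples(self):
        s = "GAACCCT" * 3
        cfg = OverlapConfig(min_score=6, min_overlap=7, max_hang=0)
        pats = align_pair(_pr(s, 0), _pr(s, 0), cfg)
        assert sorted(p.offset for p in pats) == [-14, -7, 0, 7, 14]
        for p in pats:
            assert p.score == brute_force_best_segment(s, s, p.offset, cfg)

    def test_scores_match_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        bases = "ACGT"
        cfg = OverlapConfig(min_score=5, min_overlap=5, max_hang=2, dedup_window=0)
        for _ in range(20):
            a = "".join(rng.choice(list(bases), size=rng.integers(8, 20)))
            b = "".join(rng.choice(list(bases), size=rng.integers(8, 20)))
            pats = align_pair(_pr(a, 0), _pr(b, 0), cfg)
            for p in pats:
                assert p.rescore(a, b, cfg) == p.score
                d = (len(b) - len(a)) - p.offset
                pairs = [(i, i + d) for i in range(len(a)) if 0 <= i + d < len(b)]
                oracle = brute_force_best_segment(a, b, p.offset, cfg)
                assert oracle is not None and p.score == oracle

    def test_offset_bounded_by_read_lengths(self):
        rng = np.random.default_rng(3)
        cfg = OverlapConfig(min_score=3, min_overlap=3)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=12))
            b = "".join(rng.choice(list("ACGT"), size=15))
            for p in align_pair(_pr(a, 0), _pr(b, 0), cfg):
                assert abs(p.offset) < len(a) + len(b)

    def test_dedup_suppresses_nearby_weaker_offsets(self):
        s = "A" * 20  # homopolymer: every diagonal aligns
        cfg = OverlapConfig(min_score=5, min_overlap=5, dedup_window=2)
        pats = align_pair(_pr(s, 0), _pr(s, 0), cfg)
        offs = sorted(p.offset for p in pats)
        assert all(b - a > 2 for a, b in zip(offs, offs[1:]))


class TestSelectAlignment:
    def test_prior_compatible_beats_higher_score(self):
        pats = [AlignmentPattern(offset=5, score=7, span_i=(0, 7), span_j=(0, 7)),
                AlignmentPattern(offset=12, score=14, span_i=(0, 14), span_j=(0, 14))]
        sel = select_alignment(pats, p_i=0.0, p_j=5.0)
        assert sel.offset == 5  # closer to prior difference despite lower score

    def test_single_pattern_returned_regardless_of_prior(self):
        pats = [AlignmentPattern(offset=40, score=9, span_i=(0, 9), span_j=(0, 9))]
        assert select_alignment(pats, 0.0, 0.0).offset == 40

    def test_tie_broken_by_score(self):
        pats = [AlignmentPattern(offset=3, score=10, span_i=(0, 10), span_j=(0, 10)),
                AlignmentPattern(offset=-3, score=12, span_i=(0, 12), span_j=(0, 12))]
        assert select_alignment(pats, 0.0, 0.0).score == 12

    def test_empty_is_none(self):
        assert select_alignment([], 0.0, 0.0) is None


class TestBuildObservations:
    def test_no_significant_pattern_no_observation(self):
        placed = [_pr("AAAAAAAAAAAAAAAA", 0), _pr("CCCCCCCCCCCCCCCC", 1)]
        assert build_observations(placed, OverlapConfig(delta_d=10)) == []

    def test_single_library_weights_are_one(self):
        s = "ACGTTGCAGGATTACC"
        placed = [_pr(s, 0), _pr(s, 1)]
        obs = build_observations(placed, OverlapConfig(delta_d=10, min_score=10,
                                                       min_overlap=10),
                                 lib_sds=[50.0], use_weights=True)
        assert obs and all(o.weight == 1.0 for o in obs)

    def test_multi_library_weight_formula(self):
        s = "ACGTTGCAGGATTACC"
        placed = [_pr(s, 0, lib=0), _pr(s, 1, lib=1)]
        obs = build_observations(placed, OverlapConfig(delta_d=10, min_score=10,
                                                       min_overlap=10),
                                 lib_sds=[50.0, 100.0], use_weights=True)
        assert obs and all(o.weight == (50.0 / 100.0) ** 2 for o in obs)

    def test_tandem_fixture_errors_supported_on_unit_multiples(self, repeat_gap_case):
        """On a noiseless tandem-unit-7 gap, observation errors are 0 or +/-7k."""
        from regap.io import find_gaps
        from regap.preprocess import collect_gap_reads, make_pseudo_reads

        case = repeat_gap_case
        (gap,) = find_gaps(case.scaffolds)
        lp, rp = make_pseudo_reads(gap, case.scaffolds, 35)
        placed = [lp] + collect_gap_reads(gap, case.pairs, case.lib, 35) + [rp]
        obs = build_observations(placed, OverlapConfig(), lib_sds=[case.lib.sd])
        assert len(obs) > 50

        def true_coord(r):
            if r is lp:
                return 0
            if r is rp:
                return 35 + len(rp)
            at = case.genome.find(r.seq, 2000)
            return None if at < 0 else at + len(r.seq) - 1 - 2494
        errs = []
        for o in obs:
            ti, tj = true_coord(placed[o.i]), true_coord(placed[o.j])
            if ti is None or tj is None:
                continue  # read sits inside the repeat: position ambiguous
            errs.append(o.y - (tj - ti))
        assert errs
        assert all(e % 7 == 0 for e in errs)

    def test_shrinking_delta_d_never_adds_observations(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(8)]
        placed = [_pr(s, p, rid=f"r{k}") for k, (s, p) in
                  enumerate(zip(seqs, rng.uniform(0, 40, 8)))]
        small = build_observations(placed, OverlapConfig(delta_d=5, min_score=5, min_overlap=5))
        large = build_observations(placed, OverlapConfig(delta_d=50, min_score=5, min_overlap=5))
        assert {(o.i, o.j) for o in small} <= {(o.i, o.j) for o in large}

    def test_pair_counts_reports_all_against_all_denominator(self):
        placed = [_pr("ACGTACGT", p, rid=f"r{p}") for p in range(9)]
        n_all, n_cand = pair_counts(placed, OverlapConfig(delta_d=3.0))
        assert n_all == 36
        assert n_cand == len(candidate_pairs(placed, 3.0))
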