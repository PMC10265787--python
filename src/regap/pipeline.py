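"""End-to-end gap closing: collect, overlap, fit, consensus, splice, iterate.

Every gap is processed independently (results are identical regardless of
worker count or processing order); a gap raising an internal error is logged
and left unfilled.  The iterative mode re-places reads against each round's
output genome and stops early when a round closes no gap.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import GapResult, Layout, anchor_and_emit
from .io import GapInterval, PairedAlignment, find_gaps, splice_gap_results
from .layout import HuberLayoutModel, RobustConfig
from .mapper import map_pairs
from .overlap import OverlapConfig, build_observations, pair_counts
from .preprocess import (
    LibraryProfile,
    collect_gap_reads,
    make_pseudo_reads,
    spanning_gap_estimates,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a gap-closing run."""

    overlap: OverlapConfig = field(default_factory=OverlapConfig)
    robust: RobustConfig = field(default_factory=RobustConfig)
    flank_len: int = 150
    min_flank: int = 20
    mapq_min: int = 20
    band: int = 3
    quality_aware: bool = True
    use_weights: bool = False
    threads: int = 1
    iterations: int = 1
    min_n: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations >= 1 required")


def close_gap(
    gap: GapInterval,
    pairs_by_lib: Sequence[Sequence[PairedAlignment]],
    profiles: Sequence[LibraryProfile],
    scaffolds: dict[str, str],
    cfg: RunConfig,
) -> tuple[GapResult, dict]:
    """Locally assemble one gap; returns the result and per-gap statistics."""
    ests: list[float] = []
    for pairs, prof in zip(pairs_by_lib, profiles):
        ests.extend(spanning_gap_estimates(gap, pairs, prof, cfg.mapq_min))
    if ests:
        g_hat = max(int(round(float(np.median(ests)))), 1)
    else:
        g_hat = max(gap.reported_size, 1)

    lp, rp = make_pseudo_reads(gap, scaffolds, g_hat, cfg.flank_len, cfg.min_flank)
    placed = []
    if lp is not None:
        placed.append(lp)
    for lib, (pairs, prof) in enumerate(zip(pairs_by_lib, profiles)):
        placed.extend(
            collect_gap_reads(gap, pairs, prof, g_hat, lib=lib, mapq_min=cfg.mapq_min)
        )
    if rp is not None:
        placed.append(rp)

    stats = {
        "gap_size_est": g_hat,
        "n_reads": len(placed),
        "n_observations": 0,
        "n_outliers": 0,
        "n_allpairs": 0,
        "n_candidates": 0,
    }
    if lp is None and rp is None:
        return GapResult(status="unfilled", diagnostic="both flanks too short"), stats
    if len(placed) < 2:
        return GapResult(status="unfilled", diagnostic="no reads collected"), stats

    lib_sds = [p.sd for p in profiles]
    stats["n_allpairs"], stats["n_candidates"] = pair_counts(placed, cfg.overlap, lib_sds)
    obs = build_observations(placed, cfg.overlap, lib_sds, use_weights=cfg.use_weights)
    stats["n_observations"] = len(obs)

    pseudo_anchors = {}
    if lp is not None:
        pseudo_anchors[0] = 0.0  # lp is always placed first
    priors = [r.p for r in placed]
    model = HuberLayoutModel(obs, len(placed), priors=priors, pseudo_anchors=pseudo_anchors)
    res = model.fit(cfg.robust)
    stats["n_outliers"] = res.n_outliers

    layouts = [
        Layout(component_id=k, members=[(placed[i], int(res.params[i])) for i in comp])
        for k, comp in enumerate(res.components)
        if len(comp) > 0
    ]
    result = anchor_and_emit(layouts, lp, rp, band=cfg.band, quality_aware=cfg.quality_aware)
    return result, stats


def close_all_gaps(
    scaffolds: dict[str, str],
    pairs_by_lib: Sequence[Sequence[PairedAlignment]],
    profiles: Sequence[LibraryProfile],
    cfg: Optional[RunConfig] = None,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, GapResult], dict[str, dict]]:
    """Close every gap of the draft; returns (genome, report, results, stats)."""
    cfg = cfg or RunConfig()
    gaps = find_gaps(scaffolds, min_n=cfg.min_n)

    def run_one(gap):
        try:
            return close_gap(gap, pairs_by_lib, profiles, scaffolds, cfg)
        except Exception:  # noqa: BLE001 - one bad gap must not kill the run
            log.exception("gap %s failed; left unfilled", gap)
            return GapResult(status="unfilled", diagnostic="internal error"), {}

    if cfg.threads > 1 and len(gaps) > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            outcomes = list(pool.map(run_one, gaps))
    else:
        outcomes = [run_one(g) for g in gaps]

    results = {str(g): r for g, (r, _) in zip(gaps, outcomes)}
    stats = {str(g): s for g, (_, s) in zip(gaps, outcomes)}
    new_scaffolds = splice_gap_results(scaffolds, gaps, results)
    rows = [
        {
            "gap": str(g),
            "status": results[str(g)].status,
            "filled_length": results[str(g)].filled_length,
            "gap_size_est": stats[str(g)].get("gap_size_est", 0),
            "n_reads": stats[str(g)].get("n_reads", 0),
            "n_observations": stats[str(g)].get("n_observations", 0),
            "n_outliers": stats[str(g)].get("n_outliers", 0),
        }
        for g in gaps
    ]
    report = pd.DataFrame(rows)
    return new_scaffolds, report, results, stats


@dataclass
class IterationHistory:
    rounds_used: int
    closed_per_round: list[int]
    reports: list[pd.DataFrame]


def iterate(
    scaffolds: dict[str, str],
    reads_by_lib: Sequence[Sequence[tuple[str, str, list[int], str, list[int]]]],
    profiles: Sequence[LibraryProfile],
    cfg: Optional[RunConfig] = None,
    mapper_k: int = 31,
) -> tuple[dict[str, str], IterationHistory]:
    """Iterative closing: re-place reads against each round's output genome.

    Runs up to ``cfg.iterations`` rounds, stopping early when a round makes
    no progress (closes no gap and changes no base -- a round that only
    extends flanks still counts as progress, since the next round's remapping
    can recruit reads onto the new flanks).  The closed-gap count is
    non-decreasing across rounds by construction (closed gaps are spliced and
    never reopened).
    """
    cfg = cfg or RunConfig()
    genome = dict(scaffolds)
    closed_per_round: list[int] = []
    reports: list[pd.DataFrame] = []
    rounds = 0
    for _ in range(cfg.iterations):
        rounds += 1
        pairs_by_lib = [map_pairs(genome, reads, k=mapper_k) for reads in reads_by_lib]
        new_genome, report, results, _ = close_all_gaps(genome, pairs_by_lib, profiles, cfg)
        reports.append(report)
        closed = sum(1 for r in results.values() if r.status == "closed")
        closed_per_round.append(closed)
        progressed = new_genome != genome
        genome = new_genome
        if closed == 0 and not progressed:
            break
    return genome, IterationHistory(rounds_used=rounds, closed_per_round=closed_per_round,
                                    reports=reports)
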