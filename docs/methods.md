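# Methods

`regap` closes N-gaps in draft genome scaffolds by local assembly of
paired-end reads, formulated as a robust linear-regression problem.  This
note records the model, the tunable parameters and their defaults, the
numerical choices, what the synthetic-data generators emulate, and the known
limits of the approach.

## The model

For one gap, set a coordinate axis along the genome with origin at the last
base of the left flanking contig.  Every collected read `i` is a parameter
`beta_i`: the (integer) axis coordinate of its ending (rightmost) base.  A
pairwise overlap between reads `i` and `j` yields one observation

    y_ij = beta_j - beta_i + eps_ij,

so the m observations form a sparse system `Y = X beta + eps` in which each
row of `X` has exactly two non-zeros, -1 and +1 — the oriented incidence
matrix of the overlap graph.  With substitution-dominated short-read errors,
`eps` is almost always 0 for a true overlap; a false overlap (repeat- or
chimera-induced) produces a gross error, typically a whole multiple of the
repeat-unit length.  Each weakly connected component of the graph is one
contig; its incidence block has rank `n_k - 1`, so one read per component is
anchored (the left pseudo read at 0 when present, else the smallest-prior
member at its prior) by appending a single-entry row.  The anchor is exact in
any (weighted) least-squares solution because overlap residuals are invariant
to a constant shift of a component.

### Read collection and priors

Let `mu`, `v` be the library insert-size mean and SD (insert = outer
distance, leftmost base of the left read to rightmost base of the right
read).  A pair is recruited when one mate is uniquely mapped (MAPQ >= 20, no
XA/SA tag) within `mu + 3v` of a gap breakpoint, facing the gap; the other
mate is collected onto the forward gap axis (left-flank recruits are
reverse-complemented, since in an FR library the mate of a forward left-flank
anchor was sequenced from the reverse strand).  Its prior ending coordinate
is `p = mu - d_anchor` for left recruits and `p = G_hat - (mu - d_anchor) +
read_length` for right recruits, where `d_anchor` is the anchor's outer
distance from its breakpoint and `G_hat` the estimated gap size (median of
`mu - d_L - d_R` over gap-spanning pairs, falling back to the N-run length).
Two pseudo reads cut from the flanks (default 150 bp, minimum 20) enter the
assembly like ordinary reads; the left one fixes the origin, the right one is
anchored only after layout.

### Overlap detection

Only pairs with `|p_i - p_j| < delta_d` are aligned; `delta_d` defaults to
`max(3 * sqrt(v_i^2 + v_j^2), 10)` bp.  Sorting by prior makes candidate
generation linear rather than all-against-all.  The pairwise aligner scores
each offset diagonal (match +1, mismatch -2) with up to `max_hang = 5` bases
trimmable at each end, and reports *all* configurations with score >=
`min_score = 15` and aligned length >= `min_overlap = 15`, deduplicated
within 2 bp of a better-scoring offset.  Insertions/deletions are not
modelled: short-read errors are substitution-dominated, so a true overlap is
a single diagonal.  Among multiple significant patterns the one whose offset
is closest to the prior difference `p_j - p_i` is selected — not the
highest-scoring one; ties go to the higher score, then the smaller offset.
With several libraries the optional initial weight of an observation is
`(min library SD / max(SD_i, SD_j))^2`.

### Two-step robust estimation

Step 1 computes the Huber M-estimate: minimize `sum_i w0_i rho_H(y_i - x_i'
beta)` with `rho_H(e) = e^2/2` for `|e| <= c`, else `c|e| - c^2/2`, `c = 2`
bp.  Residuals are in bp and are *not* rescaled by a robust scale estimate —
the tuning constant is expressed directly in base pairs.  The minimizer is
found by IRLS: starting at OLS, repeatedly solve the weighted normal
equations `X' W X beta = X' W Y` with `W = W0 * w_H(resid)`, `w_H(e) = 1`
inside and `c/|e|` outside, until the max coordinate change is below
`alpha = 2` bp (cap 100 iterations).  Anchor rows keep weight 1 throughout.
Since the objective is convex, the iteration descends to a global minimum;
the objective path is asserted non-increasing in tests.

Step 2 flags observations with `|residual| > r_o` (default 10 bp) as
potential outliers and refits by OLS on the remaining rows.  If trimming
disconnects a component, each new component is re-anchored — at its pseudo
read when present, otherwise at its smallest-prior member's Step-1 estimate
(keeping the robust fit's geometry; these floating components are discarded
at consensus anyway) — and refit.  Coordinates are rounded to the nearest
integer, ties away from zero.

**The trim threshold and repeat units.**  Separating unit-`u` confusions into
the outlier set requires `r_o < u`; the default 10 bp presumes units larger
than 10 (such as the 69 bp showcase unit).  For known small units, set
`r_o` below the unit (the robustness-contrast demonstrations use `r_o = 5`
for a 7 bp unit).  Confusions smaller than `r_o` are never trimmed; they are
merely down-weighted in Step 1 and can bias the final OLS by a fraction of a
base — which the consensus stage absorbs (below).

### Consensus and anchoring

Reads are placed at their fitted coordinates and merged into a column matrix,
each incoming read re-aligned to the running consensus within a +/-3 bp band
(substitutions only); a read matching fewer than 75% of >= 10 covered columns
is dropped and counted.  Per column, the consensus base maximizes a Bayesian
posterior over {A,C,G,T} with uniform prior and per-read error probabilities
from Phred scores (error spread evenly over the three wrong bases); ties
break lexicographically; the output quality is `-10 log10(1 - posterior)`
capped at 60.  A raw-count mode (flat error 0.05) is available behind a
switch; quality-aware is the default.  Zero-coverage columns emit `N`/Q0.

If both pseudo reads lie in one layout the gap is closed with the consensus
strictly between them; the right pseudo read's anchor is its banded-realigned
position in the MSA rather than its raw fitted coordinate — this is what
"anchored only after layout" means here, and it absorbs the sub-`r_o`
fractional biases described above (without it, fills were occasionally 1 bp
short).  One pseudo read alone extends its flank; pseudo reads in two
disconnected layouts extend both flanks; layouts containing neither are
discarded.  Inverted pseudo order (right ending before left) yields
`unfilled` with a diagnostic.  At splice time extensions are truncated so at
least one N always remains — two independently estimated extensions that met
would duplicate junction sequence and poison later mapping rounds.

### Iteration

`iterate` re-places reads against each round's output genome (with the
built-in unique-k-mer mapper, k = 31, or an external mapper's SAM) and
reruns closing, stopping early when a round makes no progress (closes no gap
and changes no base; an extension-only round counts as progress because the
next remapping can recruit onto the new flanks).  Closed gaps are spliced
and never reopened, so the closed count is non-decreasing.

## Synthetic data: what it emulates, and what not

`simulate_genome`/`make_draft`/`simulate_paired_reads` generate a uniform
random genome with implanted tandem repeats, a draft whose N-runs may
misreport the true gap size, and an FR library with truncated-normal inserts
(`[2*read_len, mu+5v]`), uniform substitution errors with matching constant
Phred scores, and a fixture SAM that places each read at its true draft
position, reads intersecting gaps written unmapped.  Not emulated: indel and
quality-dependent errors, GC- and position-dependent coverage bias,
chimeric pairs, adapter contamination, real mapper soft-clipping near gap
edges, and genome-wide interspersed repeats.  Passing tests therefore show
the estimator and pipeline behave as designed under the stated error model;
they do not certify performance on real libraries, where the mapping stage
and heavy-tailed insert distributions add failure modes.

`simulate_overlap_graph` produces regression instances whose Huber minimum
is provably unique (clean backbone majority across every graph cut; see the
docstring) so IRLS can be compared pointwise to an independent convex
minimizer.  `simulate_confused_chain` reproduces the one-sided unit/2-unit
false-overlap structure a tandem repeat induces (residual peaks at 0 and +u).

The standard end-to-end benchmark (`simulate_benchmark_scenario`) is a 50 kb
genome with 10 gaps of 100-250 bp, three spanning tandem repeats (7 bp x3,
11 bp x4, 23 bp x2.5), at 30x coverage, mu = 500, v = 50, 1% substitution
errors.  The repeat spans are kept below the read length deliberately: with
v = 50 the prior *difference* between two reads has SD ~70 bp, so
insert-guided selection cannot discriminate unit shifts for reads wholly
inside a repeat longer than the read; such repeats (e.g. 69 bp x 2.9,
span 201) are resolvable under a tighter library — demonstrated separately
at sd = 15 and 60x, where the 2.9 copies are recovered exactly — or with
substantially higher coverage.

## Numerical choices

- Sparse normal-equation solves use LGMRES, rtol 1e-6 during IRLS with the
  previous iterate as warm start, tightened to 1e-10 for the final solve of
  each step; a direct sparse LU factorization is the fallback on
  non-convergence.
- Component splitting uses `scipy.sparse.csgraph.connected_components`.
- Duplicate (i, j) observations are kept as independent rows.
- Degenerate inputs: a component reduced to one read sits at its anchor or
  prior; an all-N scaffold is skipped with a warning; libraries with zero
  insert spread have the SD floored at 1; a flank shorter than 20 bp marks
  the gap unclosable from that side.
- Everything is deterministic given the seed; per-gap work is independent,
  so results are identical for any thread count.

## Known limitations

- Indels in reads are not modelled anywhere (aligner, MSA, consensus); data
  with appreciable indel error rates (e.g. uncorrected long reads) need an
  indel-aware front end.
- Repeat units <= `r_o` cannot be trimmed as outliers; exactness then relies
  on redundancy plus consensus-stage realignment.
- Tandem spans well beyond the read length are not resolvable at loose
  insert SDs (see above).
- The built-in mapper is exact-seed and intended for small genomes and
  testing; production use should supply SAM/BAM from a real mapper.
- Heterozygosity is not modelled: the consensus is haploid.
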