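# Methods

## Problem and approach

Ribosomal DNA arrays are tandem repeats of a large unit (~45 kb in human,
hundreds of copies) whose within-array variation defeats general-purpose
assemblers: accurate long reads are much shorter than a repeat unit, and the
units are too similar to separate. `ribomorph` assembles the distinct
full-length unit sequences — *morphs* — by combining the strengths of two
read types:

1. **Accurate long reads** (HiFi-like, ~0.2% error) are recruited with a
   related reference unit and assembled into a homopolymer-compressed
   de Bruijn unitig graph, the *allele graph*. At this error rate, k-mers
   above a solidity threshold capture essentially all true variation in the
   array, but the graph alone cannot say which alleles co-occur in one unit.
2. **Ultralong noisy reads** (ONT-like, ~5% error, tens of kb) each span one
   or more complete units. Aligned to the allele graph, a read's path phases
   the alleles it crosses. One complete traversal between consecutive visits
   of a fixed *anchor* node is a *loop*: a full repeat unit, spelled in the
   graph's (accurate) bases rather than the raw read's.

Loops are clustered by pairwise edit distance — union-find *rough clusters*
within `max_rough_diff` edits, then DBSCAN at an estimated radius ε — and
each cluster is polished into one morph with a loop-count coverage. A
*genome-wide consensus* (greedy heaviest graph walk) is also emitted; with
unit-specific allele pairings it is frequently a mosaic that exists in no
real unit, which is precisely why the per-cluster morphs are the primary
output.

## Model components and key choices

### Graph construction

Reads are homopolymer-compressed before k-mer extraction; per-position run
lengths are accumulated across supporting reads (mapped through maximal
diagonal stretches of matching k-mers, so interior positions of short unitigs
are observed too) and the per-position lower median is used for expansion.
k-mers are packed into 2-bit uint64 codes, which caps k at 31 compressed
symbols; `k_graph=31` (~40+ bp expanded) is the default and resolves variants
spaced a few tens of bases apart. Solid threshold `solid_min=5` separates
true variants (coverage ≈ 35 × copy count) from accurate-read errors.
Cleaning removes sub-threshold nodes and weak short tips (< 25% of the best
neighbour's coverage) and re-compacts.

Known, accepted artefact: where a variant sits next to a homopolymer-length
difference, or where a tandem motif is longer than the k window, the pooled
run medians collapse per-unit lengths toward the majority. The residual
morph errors are therefore dominated by homopolymer and short tandem-motif
indels — the same error classes that dominate in this family of methods.

### Anchor selection

The loop boundary must be a node traversed once per unit. Coverage is
proportional to the number of units containing a node, so the anchor is the
highest-coverage node among those of compressed length ≥ 2k; the length
filter excludes the short cyclic stubs that tandem motifs compact into,
whose coverage counts several traversals per unit. (A coverage × length
score was tried first and rejected: it prefers long morph-private spacer
unitigs, which are not on every unit's path, so entire morphs stop producing
loops.)

### Graph alignment

A seed–chain–thread aligner: exact canonical 17-mers against the expanded
node sequences (at 5% read error ~40% of 17-mers survive), collinear anchors
merged into segments, segments chained by a DP whose weight is the anchor
count (this discriminates bubble alleles, which share flanks) with a gap
consistency penalty; segments overlapping on the read by more than anchor
jitter must sit on graph-adjacent nodes, which suppresses near-identical
homologous nodes masquerading as successors. Gaps between chained segments
are filled by a breadth-limited search for paths whose expanded span matches
the read gap, ranked by edit distance of the read gap against each candidate
path; junctions that cannot be bridged trigger a bounded backtrack that
drops the weaker of the conflicting segments. Emitted paths require overall
identity ≥ 0.75 (computed as 1 − edits/alignment length over the threaded
interval).

### Loops

A loop runs from one anchor *start* to the next, in the anchor's plus-strand
register; minus-strand visits are shifted by the anchor length before
reverse complementing so that all loops share one rotational origin
(otherwise every morph's loop family splits by read strand). Both boundary
anchor visits must lie fully inside the read's aligned clip — a loop is a
*complete*, read-supported traversal. Lengths outside [0.5, 2] × the
approximate morph size are discarded and counted. Each loop also records
its raw read segment (located through the path's base-level alignment).

### Clustering

Pairwise distances are threshold-limited (edlib with early exit) and
prefiltered by a 15-mer sketch (pairs sharing < 5% of sketch k-mers are
marked as exceeding without alignment); the sketch subsampling rate adapts
so even the shortest sequence keeps ~64 sampled k-mers, and the screen is
skipped when sketches are smaller than that (short sequences lose nearly
all exact 15-mers after a few edits, so the screen would be unsound).
Identical loop sequences are collapsed into classes, so the quadratic stage
scales with distinct traversals.

Distances are computed up to 3 × `max_rough_diff`, but distances above
`max_rough_diff` are only resolved within rough clusters: ε never exceeds
the rough radius, so DBSCAN needs no others, and the ε estimate — the mean
finite within-rough-cluster pairwise distance, rounded half-up and floored
at `min_epsilon` — would otherwise be truncated at the rough threshold and
biased low. ε is capped at `max_rough_diff` so density clusters stay within
rough clusters. `max_rough_diff` defaults to 1% of the approximate morph
size; `min_pts` defaults to 5 (2 in HiFi-only mode), below the coverage-30
reporting threshold so low-copy morphs can survive clustering. DBSCAN uses
the standard core/border/noise definitions with self-counting neighbourhoods;
border ties go to the lowest cluster id, which reproduces scikit-learn's
sequential-expansion assignment exactly.

### Consensus

Each cluster is seeded with its medoid loop and polished by iterative
pileup majority (ties keep the current base; an insertion needs a strict
majority), default 5 rounds to a fixed point. The polishing stack is the
loops' **raw read segments**: all graph-derived loop sequences share any
systematic graph defect (pooled run medians, collapsed tandem motifs),
whereas the raw segments carry independent noise that the majority vote
removes and per-morph homopolymer/motif lengths that it restores. With
cluster sizes ≥ 30 the consensus is typically within a few edits of truth;
small clusters (≈ 5 loops) retain noticeably more noise.

The genome-wide consensus follows the highest-coverage outgoing edge from
the anchor (ties: lower node id, then `+`) until the anchor re-enters or
2 × the approximate morph size is emitted.

### Evaluation

Two morphs *match* at ≥ 99% identity covering ≥ 99% of both. Matching is
rotation-aware (each sequence aligned semi-globally into the other's doubled
sequence; the better direction gives identity, each direction gives its
target's covered fraction) and strand-aware. Specificity is implemented as
precision over predictions and reported absent when there are no eligible
predictions. Pearson r uses best-match pairs (per truth morph: highest
identity, then highest coverage). Error classification labels each edit:
single-base indels extending an adjacent run ≥ 2 are homopolymer indels;
indels that are whole copies of a 2–6 bp motif with an adjacent copy in
context are tandem-motif (microsatellite) indels; everything else, including
all substitutions, is "other".

## Synthetic data

The generator emulates a tandem rDNA array with known truth. A panel of
source units is derived from one ancestor with a conserved core (35% of the
unit at ~0.4% pairwise divergence — the stand-in for the transcribed block,
which in real rDNA is nearly identical across units and gives the pipeline
its anchor) and a divergent spacer carrying the rest, including 1–10 bp
indels and an embedded 4-bp tandem motif. Per-source mutation rates are
calibrated (and verified by measurement, ±20%) so that random mosaics of the
panel differ by the target `mosaic_divergence` on average (two mosaics use
the same source at 1/n of positions). Morphs switch sources at
Poisson(3)-many uniform breakpoints and then receive `mutation_rate` random
point mutations (80% substitutions, 20% single-base indels); copy counts
follow a truncated geometric law (many rare, few abundant morphs); units are
shuffled uniformly into a tandem array. Reads are sampled uniformly from the
linear array with lognormal lengths, strand-symmetric, with substitution and
indel errors and a homopolymer indel bias (1.5× inside runs ≥ 3 for the
ONT-like profile). Defaults: HiFi-like 18 kb / 0.2% error; ONT-like 60 kb
heavy-tailed / 5% error.

What the simulation does not capture: platform-specific systematic error
motifs, chimeric reads, and the systematic HiFi coverage bias seen in real
rDNA — so passing the study says the algorithm recovers morphs under the
stated divergence/coverage regime, not that real-sample accuracy will be
identical.

## Scaled study conditions

The accuracy study runs five seeded replicates at desk scale: nine mosaic
morphs of 5 kb units (average divergence 4.4% = 4.2% mosaic + 0.2%
mutations), copy counts drawn geometrically in 1–15 (≈ 40 copies per array,
~200 kb), HiFi-like 35× and ONT-like 60× with a 25 kb mean read length and
5% error; pipeline parameters: `k_graph=31`, `max_rough_diff=50` (1% of the
unit), `min_pts=5`, reporting threshold 30. Metrics: pooled Pearson r of
best-match coverage vs copy count; overall sensitivity (no filter, averaged
over replicates); sensitivity over truth morphs with ≥ 5 copies; precision
over predictions with coverage ≥ 30. One replicate takes on the order of
two minutes on one CPU.

## Known limitations

- Copy counts are not estimated (coverage is loop counts; converting to copy
  numbers is left to the user), and morph order along the array is not
  resolved — both inherent to the data types used.
- Morphs closer than ε edits are merged; with all arrays pooled, ε is driven
  up by the cross-unit loop noise, so highly similar low-copy morphs are
  absorbed by their abundant relatives (overall sensitivity < 100% while
  abundant-morph sensitivity stays high).
- Residual consensus errors concentrate in homopolymers and short tandem
  motifs; pileup-majority polishing has no run-length-aware model.
- The aligner is a simplified seed/chain/thread scheme, not a full
  sequence-to-graph DP; per-bubble allele choices in noisy reads are
  evidence-limited and show up as within-cluster loop noise.
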