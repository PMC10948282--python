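"""Per-cluster consensus (medoid seed + pileup-majority polishing) and the
genome-wide consensus walk.

Each morph cluster is summarised by its medoid loop, iteratively polished:
every loop is globally aligned to the current consensus, per-column base/gap
observations are stacked, and each column is replaced by its majority vote
(ties keep the current base).  Majority insertions are applied between
columns.  This pileup scheme is simple and testable; like any majority
consensus it is weakest at homopolymers and short tandem motifs, where the
residual errors of the pipeline concentrate.

The genome-wide consensus is read straight off the allele graph: a greedy
heaviest walk from the anchor node.  With chromosome- or morph-specific
allele pairings, that walk can combine alleles that never co-occur in one
repeat unit — a mosaic sequence absent from the genome — which is why
per-cluster morphs, not the genome-wide consensus, are the primary output.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .allele_graph import AlleleGraph
from .loops_cluster import Loop, MorphCluster, PairwiseDistances

__all__ = [
    "Morph",
    "medoid",
    "polish",
    "genome_wide_consensus",
    "morphs_from_clusters",
]

_CIG = re.compile(r"(\d+)([=XIDM])")
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class Morph:
    """An assembled repeat-unit sequence with its loop-count coverage."""

    morph_id: str
    sequence: str
    coverage: int
    cluster_ref: int
    length: int


def medoid(cluster: Sequence[int], distances: PairwiseDistances) -> int:
    """Loop minimising total edit distance to the cluster; ties to lowest index.

    Distances missing from the threshold-limited table are computed on demand.
    """
    members = sorted(cluster)
    if not members:
        raise ValueError("empty cluster")
    # all loops of one sequence class share the same total; score classes
    classes = sorted({int(distances.class_of[i]) for i in members})
    weights = {ci: 0 for ci in classes}
    for i in members:
        weights[int(distances.class_of[i])] += 1
    reps = {ci: min(i for i in members if distances.class_of[i] == ci) for ci in classes}
    best = None
    for ci in classes:
        total = 0
        for cj in classes:
            if ci == cj:
                continue
            total += distances.exact(reps[ci], reps[cj]) * weights[cj]
        cand = (total, reps[ci])
        if best is None or cand < best:
            best = cand
    return best[1]


def _cigar_ops(cigar: str) -> List[Tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG.findall(cigar)]


def polish(
    seed: str,
    loops: Sequence,
    max_rounds: int = 5,
    weights: Optional[Sequence[int]] = None,
) -> str:
    """Iterative pileup-majority polish of ``seed`` against the cluster loops.

    Converges to a fixed point or stops after ``max_rounds`` (with a warning).
    Ties keep the current base; a majority insertion (more than half of the
    stacked weight) is applied between columns.
    """
    seqs = [lp.sequence if isinstance(lp, Loop) else lp for lp in loops]
    if not seqs:
        raise ValueError("empty cluster")
    if weights is None:
        collapsed: Dict[str, int] = {}
        for s in seqs:
            collapsed[s] = collapsed.get(s, 0) + 1
        seqs = list(collapsed)
        weights = [collapsed[s] for s in seqs]
    total_w = float(sum(weights))
    consensus = seed
    for _ in range(max_rounds):
        L = len(consensus)
        votes = np.zeros((L, 5))  # A C G T gap
        ins: List[Dict[str, float]] = [dict() for _ in range(L + 1)]
        for s, w in zip(seqs, weights):
            if s == consensus:
                idx = np.fromiter(
                    (_BASE_IDX[c] for c in consensus), dtype=np.int64, count=L
                )
                votes[np.arange(L), idx] += w
                continue
            res = edlib.align(s, consensus, mode="NW", task="path")
            tpos = qpos = 0
            for n, op in _cigar_ops(res["cigar"]):
                if op in "=XM":
                    idx = np.fromiter(
                        (_BASE_IDX[c] for c in s[qpos : qpos + n]),
                        dtype=np.int64,
                        count=n,
                    )
                    np.add.at(votes, (np.arange(tpos, tpos + n), idx), w)
                    tpos += n
                    qpos += n
                elif op == "D":  # consensus bases absent from the loop
                    votes[tpos : tpos + n, 4] += w
                    tpos += n
                elif op == "I":  # loop bases absent from the consensus
                    piece = s[qpos : qpos + n]
                    ins[tpos][piece] = ins[tpos].get(piece, 0) + w
                    qpos += n
        out: List[str] = []
        for p in range(L + 1):
            if ins[p]:
                piece, w = max(ins[p].items(), key=lambda kv: (kv[1], kv[0]))
                if w > total_w / 2:
                    out.append(piece)
            if p == L:
                break
            col = votes[p]
            top = col.max()
            cur = _BASE_IDX.get(consensus[p], 0)
            if col[cur] >= top:
                winner = cur
            else:
                winner = int(np.flatnonzero(col == top)[0])
            if winner != 4:
                out.append("ACGT"[winner])
        new = "".join(out)
        if new == consensus:
            return consensus
        consensus = new
    warnings.warn("polishing did not converge; returning last iterate")
    return consensus


def genome_wide_consensus(
    graph: AlleleGraph, anchor: int, approx_morph_size: int
) -> str:
    """Greedy heaviest walk from the anchor: one consensus repeat unit.

    From the anchor the walk repeatedly follows the highest-coverage outgoing
    edge (ties to the lowest node id, then ``+`` orientation) until the anchor
    is re-entered or 2 x ``approx_morph_size`` expanded bases are emitted.
    """
    walk: List[Tuple[int, str]] = [(anchor, "+")]
    emitted = graph.nodes[anchor].expanded_length
    closed = False
    while emitted < 2 * approx_morph_size:
        succs = graph.successors(*walk[-1])
        if not succs:
            raise ValueError("genome-wide consensus walk dead-ends (anchor not on a cycle)")
        b, ob, _ = min(succs, key=lambda t: (-t[2], t[0], t[1]))
        walk.append((b, ob))
        if b == anchor:
            closed = True
            break
        emitted += graph.nodes[b].expanded_length
    seq, starts = graph.walk_sequence(walk, check_edges=True)
    if closed:
        return seq[: starts[-1]]
    return seq[: 2 * approx_morph_size]


def morphs_from_clusters(
    clusters: Sequence[MorphCluster],
    loops: Sequence[Loop],
    distances: PairwiseDistances,
    max_rounds: int = 5,
) -> List[Morph]:
    """Polished consensus per cluster, sorted by descending coverage then id."""
    morphs: List[Morph] = []
    for ref, cluster in enumerate(clusters):
        members = sorted(cluster.loop_indices)
        seed_idx = medoid(members, distances)
        # polish with raw read segments where recorded: the graph walks share
        # any systematic graph defect (pooled homopolymer runs, collapsed
        # tandem motifs), while the raw segments carry independent noise that
        # the majority vote removes
        stack = [
            (loops[i].raw_sequence or loops[i].sequence)
            if isinstance(loops[i], Loop)
            else loops[i]
            for i in members
        ]
        seq = polish(loops[seed_idx].sequence, stack, max_rounds)
        morphs.append(
            Morph(
                morph_id="",  # assigned after sorting
                sequence=seq,
                coverage=len(members),
                cluster_ref=ref,
                length=len(seq),
            )
        )
    morphs.sort(key=lambda m: (-m.coverage, m.cluster_ref))
    for i, m in enumerate(morphs):
        m.morph_id = f"morph_{i}"
    return morphs
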