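"""Sequence-to-graph alignment of ultralong noisy reads.

A light-weight seed/chain/thread aligner: exact canonical ``anchor_k``-mers
shared between the read and the expanded node sequences become anchors,
collinear anchors on one node are merged into segments, segments are chained
by increasing read position with a gap-difference penalty, and gaps between
chained segments are filled by a breadth-limited search for graph paths whose
expanded length matches the read gap, ranked by banded edit distance.  The
output is one or more node walks per read with an overall alignment identity.

Anchoring is done in expanded (not homopolymer-compressed) space so that
noisy reads retain exact seeds: at ~5% read error roughly 40% of 17-mers
survive intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .allele_graph import AlleleGraph
from .formats import SequenceRecord
from .recruit import canonical_kmer_codes

__all__ = [
    "Anchor",
    "AlignmentPath",
    "GraphAnchorIndex",
    "anchor_read",
    "align_read",
    "align_reads",
]


@dataclass
class Anchor:
    """An exact shared k-mer: read offset vs node offset.

    ``node_pos`` indexes the node's forward (stored) sequence; orientation
    ``-`` means the read k-mer equals the reverse complement of the node
    k-mer starting at ``node_pos``.
    """

    read_pos: int
    node_id: int
    node_pos: int
    orientation: str


@dataclass
class AlignmentPath:
    """A read's walk through the graph."""

    read_id: str
    path: List[Tuple[int, str]]
    start_offset: int  # bp into the first node (oriented coordinates)
    end_offset: int  # bp into the last node (oriented coordinates)
    identity: float
    read_interval: Tuple[int, int]


class GraphAnchorIndex:
    """Canonical anchor_k-mer index over the expanded node sequences."""

    def __init__(self, graph: AlleleGraph, anchor_k: int = 17):
        if anchor_k > 31:
            raise ValueError("anchor_k must be <= 31")
        self.anchor_k = anchor_k
        self.node_len: Dict[int, int] = {}
        codes_parts, nid_parts, pos_parts, fwd_parts = [], [], [], []
        for nid in sorted(graph.nodes):
            seq = graph.nodes[nid].expanded
            self.node_len[nid] = len(seq)
            if len(seq) < anchor_k:
                continue
            codes, pos, fwd = canonical_kmer_codes(seq, anchor_k, return_strand=True)
            codes_parts.append(codes)
            nid_parts.append(np.full(len(codes), nid, dtype=np.int64))
            pos_parts.append(pos)
            fwd_parts.append(fwd)
        if codes_parts:
            codes = np.concatenate(codes_parts)
            nids = np.concatenate(nid_parts)
            poss = np.concatenate(pos_parts)
            fwds = np.concatenate(fwd_parts)
            order = np.lexsort((poss, nids, codes))
            self.codes = codes[order]
            self.nids = nids[order]
            self.poss = poss[order]
            self.fwds = fwds[order]
        else:
            self.codes = np.empty(0, dtype=np.uint64)
            self.nids = np.empty(0, dtype=np.int64)
            self.poss = np.empty(0, dtype=np.int64)
            self.fwds = np.empty(0, dtype=bool)

    def hits(self, seq: str, max_hits: int = 8):
        """Arrays (read_pos, node_id, node_pos, orient+) of shared k-mers."""
        codes, rpos, rfwd = canonical_kmer_codes(
            seq, self.anchor_k, return_strand=True
        )
        if len(codes) == 0 or len(self.codes) == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z, z, np.empty(0, dtype=bool)
        lo = np.searchsorted(self.codes, codes, side="left")
        hi = np.searchsorted(self.codes, codes, side="right")
        n_hits = np.minimum(hi - lo, max_hits)
        total = int(n_hits.sum())
        out_r = np.empty(total, dtype=np.int64)
        out_idx = np.empty(total, dtype=np.int64)
        out_plus = np.empty(total, dtype=bool)
        at = 0
        for j in np.flatnonzero(n_hits):
            m = int(n_hits[j])
            out_r[at : at + m] = rpos[j]
            out_idx[at : at + m] = np.arange(lo[j], lo[j] + m)
            out_plus[at : at + m] = rfwd[j] == self.fwds[lo[j] : lo[j] + m]
            at += m
        return out_r, self.nids[out_idx], self.poss[out_idx], out_plus


def anchor_read(
    read: SequenceRecord | str,
    graph: AlleleGraph,
    anchor_k: int = 17,
    index: Optional[GraphAnchorIndex] = None,
    max_hits: int = 8,
) -> List[Anchor]:
    """All exact shared anchor_k-mers (both orientations, capped per position)."""
    seq = read.bases if isinstance(read, SequenceRecord) else read
    if index is None:
        index = GraphAnchorIndex(graph, anchor_k)
    r, n, p, plus = index.hits(seq, max_hits)
    return [
        Anchor(int(ri), int(ni), int(pi), "+" if pl else "-")
        for ri, ni, pi, pl in zip(r, n, p, plus)
    ]


@dataclass
class _Segment:
    node: int
    orient: str
    rstart: int
    rend: int
    ostart: int  # oriented node coordinates
    oend: int
    count: int


def _build_segments(
    r: np.ndarray,
    n: np.ndarray,
    p: np.ndarray,
    plus: np.ndarray,
    node_len: Dict[int, int],
    ak: int,
    merge_gap: int = 120,
) -> List[_Segment]:
    if len(r) == 0:
        return []
    diag = np.where(plus, r - p, r + p)
    ob = (~plus).astype(np.int64)
    order = np.lexsort((r, diag, ob, n))
    segs: List[_Segment] = []
    i = 0
    n_, diag_, ob_, r_, p_ = n[order], diag[order], ob[order], r[order], p[order]
    total = len(order)
    while i < total:
        j = i + 1
        while (
            j < total
            and n_[j] == n_[i]
            and ob_[j] == ob_[i]
            and diag_[j] == diag_[i]
            and r_[j] - r_[j - 1] <= merge_gap
        ):
            j += 1
        rs, re = int(r_[i]), int(r_[j - 1]) + ak
        ns, ne = int(p_[i : j].min()), int(p_[i : j].max()) + ak
        orient = "+" if ob_[i] == 0 else "-"
        L = node_len[int(n_[i])]
        if orient == "+":
            os_, oe = ns, ne
        else:
            os_, oe = L - ne, L - ns
        segs.append(_Segment(int(n_[i]), orient, rs, re, os_, oe, j - i))
        i = j
    segs.sort(key=lambda s: (s.rstart, s.rend, s.node, s.orient, s.ostart))
    return segs


def _chain(
    segs: List[_Segment],
    ak: int,
    graph_k: int = 31,
    window: int = 64,
    graph: Optional[AlleleGraph] = None,
):
    """Weighted collinear chaining; returns chains as index lists, best first."""
    n = len(segs)
    if n == 0:
        return []
    # consecutive nodes overlap by k-1 compressed symbols, so segments of
    # adjacent nodes legitimately overlap on the read by roughly that much
    max_overlap = 2 * ak + 2 * graph_k
    rstart = np.fromiter((t.rstart for t in segs), dtype=np.int64, count=n)
    rend = np.fromiter((t.rend for t in segs), dtype=np.int64, count=n)
    oend = np.fromiter((t.oend for t in segs), dtype=np.int64, count=n)
    node = np.fromiter((t.node for t in segs), dtype=np.int64, count=n)
    ori = np.fromiter((t.orient == "-" for t in segs), dtype=np.int64, count=n)
    span = rend - rstart
    edge_ok = None
    if graph is not None:
        edge_ok = set()
        for a, oa, b, ob in graph.edges:
            edge_ok.add((a, oa == "-", b, ob == "-"))
            edge_ok.add((b, ob != "-", a, oa != "-"))
    score = np.zeros(n)
    back = np.full(n, -1, dtype=np.int64)
    for i, si in enumerate(segs):
        # anchor count weights the chain, which discriminates between bubble
        # alleles sharing flanks; a jump penalty keeps tiny spurious segments
        # from being worth a detour
        lo = max(0, i - window)
        J = slice(lo, i)
        rgap = si.rstart - rend[J]
        same = (node[J] == si.node) & (ori[J] == (si.orient == "-"))
        mask = (
            (rend[J] <= si.rend)
            & (rstart[J] <= si.rstart)
            & (rgap >= -max_overlap)
            # overlapping segments must not explain the same read bases
            & (-rgap <= 0.75 * np.minimum(span[i], span[J]))
        )
        if not mask.any():
            score[i] = si.count
            continue
        jump_pen = 1.0 + 0.02 * np.maximum(0, rgap)
        ggap = si.ostart - oend[J]
        collinear = same & (np.abs(rgap - ggap) <= 0.4 * np.maximum(rgap, 0) + 50)
        pen = np.where(collinear, 0.1 * np.abs(rgap - ggap), jump_pen)
        cand = np.where(mask, score[J] - pen, -np.inf)
        # segments overlapping by more than anchor jitter can only follow
        # each other when their nodes are graph-adjacent (the k-1 overlap);
        # otherwise the earlier one is a near-identical homolog, not a
        # predecessor -- verified lazily, best candidate first
        needs_edge = (rgap < -8) & ~same
        best = 0.0
        bj = -1
        for idx in np.argsort(-cand, kind="stable"):
            c = cand[idx]
            if not np.isfinite(c) or c <= best:
                break
            j = lo + int(idx)
            if needs_edge[idx] and edge_ok is not None:
                sj = segs[j]
                if (
                    sj.node,
                    sj.orient == "-",
                    si.node,
                    si.orient == "-",
                ) not in edge_ok:
                    continue
            best, bj = float(c), j
            break
        score[i] = best + si.count
        back[i] = bj
    used = np.zeros(n, dtype=bool)
    chains = []
    for i in np.argsort(-score, kind="stable"):
        if used[i]:
            continue
        chain = []
        j = int(i)
        while j != -1 and not used[j]:
            chain.append(j)
            used[j] = True
            j = int(back[j])
        chain.reverse()
        if not chain:
            continue
        chains.append(chain)
        # suppress leftover segments (e.g. the other allele of a bubble)
        # that lie mostly inside this chain's read interval
        lo = segs[chain[0]].rstart
        hi = segs[chain[-1]].rend
        for j in range(n):
            if used[j]:
                continue
            s = segs[j]
            ovl = min(hi, s.rend) - max(lo, s.rstart)
            if ovl > 0.5 * (s.rend - s.rstart):
                used[j] = True
        if len(chains) >= 8:
            break
    return chains


def _trim_overlap(graph: AlleleGraph, node: int, orient: str) -> int:
    """Expanded length of a node's leading k-1 compressed symbols."""
    _, runs = graph.nodes[node].oriented(orient)
    return int(runs[: graph.k - 1].sum())


def _find_gap_paths(
    graph: AlleleGraph,
    src: Tuple[int, str],
    dst: Tuple[int, str],
    target: float,
    band: float,
    max_candidates: int = 8,
    max_states: int = 256,
):
    """Graph walks src->dst whose expanded span is within ``band`` of target.

    ``target`` is measured from the *start* of the node after src to the
    start of dst, in walk coordinates.  Returns lists of intermediate nodes.
    """
    src_len = graph.nodes[src[0]].hpc.runs.sum()
    # state: (start_pos_of_node_relative_to_src_start, node, orient, mids)
    frontier = []
    for b, ob, cov in sorted(
        graph.successors(*src), key=lambda t: -t[2]
    ):
        start = int(src_len) - _trim_overlap(graph, b, ob)
        frontier.append((start, b, ob, ()))
    candidates = []
    states = 0
    while frontier and states < max_states and len(candidates) < max_candidates:
        frontier.sort(key=lambda t: t[0])
        start, node, orient, mids = frontier.pop(0)
        states += 1
        if (node, orient) == dst and abs(start - target) <= band:
            candidates.append((abs(start - target), list(mids)))
            # a path may also continue around a cycle; keep exploring
        if start > target + band:
            continue
        nlen = int(graph.nodes[node].hpc.runs.sum())
        for b, ob, cov in sorted(graph.successors(node, orient), key=lambda t: -t[2]):
            nstart = start + nlen - _trim_overlap(graph, b, ob)
            if nstart <= target + band:
                frontier.append((nstart, b, ob, mids + ((node, orient),)))
    candidates.sort(key=lambda c: (c[0], c[1]))
    return [mids for _, mids in candidates]


def align_read(
    read: SequenceRecord,
    graph: AlleleGraph,
    anchors: Sequence[Anchor],
    anchor_k: int = 17,
    min_identity: float = 0.75,
) -> List[AlignmentPath]:
    """Chain anchors and thread the read through the graph.

    Returns maximal paths with identity >= ``min_identity``; a read may yield
    several disjoint paths (chaining or gap-fill failures split the walk).
    Every consecutive node pair in an emitted path is an edge of the graph.
    """
    if not anchors:
        return []
    r = np.fromiter((a.read_pos for a in anchors), dtype=np.int64)
    n = np.fromiter((a.node_id for a in anchors), dtype=np.int64)
    p = np.fromiter((a.node_pos for a in anchors), dtype=np.int64)
    plus = np.fromiter((a.orientation == "+" for a in anchors), dtype=bool)
    node_len = {nid: node.expanded_length for nid, node in graph.nodes.items()}
    segs = _build_segments(r, n, p, plus, node_len, anchor_k)
    counts = [s.count for s in segs]
    if counts and max(counts) >= 3:
        strong = [s for s in segs if s.count >= 2]
        if strong:
            segs = strong
    paths: List[AlignmentPath] = []
    for chain in _chain(segs, anchor_k, graph.k, graph=graph):
        paths.extend(
            _thread_chain(read, graph, [segs[i] for i in chain], min_identity)
        )
    return _dedup_paths(paths)


def _dedup_paths(paths: List[AlignmentPath]) -> List[AlignmentPath]:
    """Keep the best path per read region, dropping mostly-contained ones."""

    def span(p: AlignmentPath) -> int:
        return p.read_interval[1] - p.read_interval[0]

    paths = sorted(paths, key=lambda p: (-span(p) * p.identity, p.read_interval))
    kept: List[AlignmentPath] = []
    for p in paths:
        lo, hi = p.read_interval
        ok = True
        for q in kept:
            qlo, qhi = q.read_interval
            ovl = min(hi, qhi) - max(lo, qlo)
            if ovl > 0.5 * span(p):
                ok = False
                break
        if ok:
            kept.append(p)
    kept.sort(key=lambda p: (p.read_interval, -p.identity))
    return kept


def _connect(
    read: SequenceRecord,
    graph: AlleleGraph,
    cur_nodes: List[Tuple[int, str]],
    prev: _Segment,
    seg: _Segment,
) -> Optional[List[Tuple[int, str]]]:
    """Nodes to append so the walk continues from ``prev`` to ``seg``.

    Returns an empty list for a same-node continuation, the connecting nodes
    (including seg's node) for a bridged gap, or None when no graph path
    explains the junction.
    """
    same_node = (seg.node, seg.orient) == cur_nodes[-1]
    rgap = seg.rstart - prev.rend
    ggap = seg.ostart - prev.oend
    if (
        same_node
        and seg.ostart >= prev.ostart
        and seg.oend >= prev.oend - 4
        and abs(rgap - ggap) <= 0.4 * max(rgap, 0) + 50
    ):
        return []
    band = max(40.0, 0.4 * max(rgap, 0) + 0.1 * graph.k)
    # start coordinate of seg's node relative to the start of prev's node
    abs_target = prev.oend + rgap - seg.ostart
    mids_list = _find_gap_paths(
        graph, cur_nodes[-1], (seg.node, seg.orient), abs_target, band
    )
    if not mids_list:
        return None
    if len(mids_list) == 1:
        chosen = mids_list[0]
    else:
        best = None
        gap_query = read.bases[max(prev.rend, 0) : seg.rstart]
        for mids in mids_list:
            walk = [cur_nodes[-1]] + list(mids) + [(seg.node, seg.orient)]
            seq, starts = graph.walk_sequence(walk, check_edges=False)
            gap_ref = seq[prev.oend : starts[-1] + seg.ostart]
            d = edlib.align(gap_query, gap_ref, mode="NW", task="distance")[
                "editDistance"
            ]
            if best is None or d < best[0]:
                best = (d, mids)
        chosen = best[1]
    return list(chosen) + [(seg.node, seg.orient)]


def _thread_chain(
    read: SequenceRecord,
    graph: AlleleGraph,
    chain: List[_Segment],
    min_identity: float,
) -> List[AlignmentPath]:
    out: List[AlignmentPath] = []
    cur_nodes: List[Tuple[int, str]] = [(chain[0].node, chain[0].orient)]
    # accepted segments with the walk length right before each was appended
    accepted: List[Tuple[_Segment, int]] = [(chain[0], 0)]

    def finalize() -> None:
        first, last = accepted[0][0], accepted[-1][0]
        seq, starts = graph.walk_sequence(cur_nodes, check_edges=True)
        lo = first.ostart
        hi = starts[-1] + last.oend
        ref = seq[lo:hi]
        query = read.bases[first.rstart : last.rend]
        if not ref or not query:
            return
        d = edlib.align(query, ref, mode="NW", task="distance")["editDistance"]
        identity = 1.0 - d / max(len(ref), len(query))
        if identity >= min_identity:
            out.append(
                AlignmentPath(
                    read_id=read.id,
                    path=list(cur_nodes),
                    start_offset=lo,
                    end_offset=last.oend,
                    identity=identity,
                    read_interval=(first.rstart, last.rend),
                )
            )

    for seg in chain[1:]:
        pops = 0
        while True:
            prev = accepted[-1][0]
            ext = _connect(read, graph, cur_nodes, prev, seg)
            if ext is not None:
                accepted.append((seg, len(cur_nodes)))
                cur_nodes.extend(ext)
                break
            if seg.count <= prev.count:
                break  # likely a spurious segment; keep threading from prev
            if pops < 3 and len(accepted) > 1:
                # the previously accepted segment is the suspect one: drop it
                # (and the nodes it brought in) and retry from the one before
                _, checkpoint = accepted.pop()
                del cur_nodes[checkpoint:]
                pops += 1
                continue
            # unresolvable discontinuity: emit what we have, restart at seg
            finalize()
            cur_nodes = [(seg.node, seg.orient)]
            accepted = [(seg, 0)]
            break
    finalize()
    return out


def align_reads(
    reads: Sequence[SequenceRecord],
    graph: AlleleGraph,
    anchor_k: int = 17,
    min_identity: float = 0.75,
    max_hits: int = 8,
) -> List[AlignmentPath]:
    """Anchor and align a batch of reads against one shared index."""
    index = GraphAnchorIndex(graph, anchor_k)
    node_len = index.node_len
    out: List[AlignmentPath] = []
    for read in reads:
        r, n, p, plus = index.hits(read.bases, max_hits)
        if len(r) == 0:
            continue
        segs = _build_segments(r, n, p, plus, node_len, anchor_k)
        counts = [s.count for s in segs]
        if counts and max(counts) >= 3:
            strong = [s for s in segs if s.count >= 2]
            if strong:
                segs = strong
        paths: List[AlignmentPath] = []
        for chain in _chain(segs, anchor_k, graph.k, graph=graph):
            paths.extend(
                _thread_chain(read, graph, [segs[i] for i in chain], min_identity)
            )
        out.extend(_dedup_paths(paths))
    return out
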