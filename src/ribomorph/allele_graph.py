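"""Homopolymer-compressed de Bruijn unitig graph built from accurate reads.

The *allele graph* holds all rDNA variation detected from the accurate read
set: reads are homopolymer-compressed, their canonical k-mers counted, k-mers
with multiplicity >= ``solid_min`` become graph vertices, consecutive solid
k-mers within a read induce edges, and non-branching paths are compacted to
unitigs.  Homopolymer run lengths are accumulated per compressed position
across the supporting reads and the per-position lower median is used to
expand compressed sequences back to base space.

Orientation conventions: every k-mer and every unitig is stored in its
canonical orientation (the lexicographically smaller strand); an edge
``(a, oa) -> (b, ob)`` and its mirror ``(b, flip ob) -> (a, flip oa)`` are the
same edge and are stored once under the smaller key.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .formats import SequenceRecord
from .recruit import canonical_kmer_codes, code_to_kmer, revcomp

__all__ = [
    "HpcSequence",
    "UnitigNode",
    "AlleleGraph",
    "hpc_compress",
    "hpc_expand",
    "build_allele_graph",
    "clean_graph",
]

_FLIP = {"+": "-", "-": "+"}


@dataclass
class HpcSequence:
    """A homopolymer-compressed sequence with per-position run lengths."""

    compressed: str
    runs: np.ndarray  # int per compressed position

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=np.int64)
        if len(self.runs) != len(self.compressed):
            raise ValueError("runs and compressed sequence differ in length")

    @property
    def expanded(self) -> str:
        return hpc_expand(self.compressed, self.runs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HpcSequence)
            and self.compressed == other.compressed
            and np.array_equal(self.runs, other.runs)
        )


def hpc_compress(bases: str) -> HpcSequence:
    """Collapse homopolymer runs, recording their lengths.

    N runs are dropped with a warning: they carry no usable k-mer information.
    ``hpc_expand`` with the recorded runs is the exact inverse on N-free input.
    """
    if "N" in bases:
        warnings.warn("dropping N run(s) during homopolymer compression")
        bases = bases.replace("N", "")
    if not bases:
        return HpcSequence("", np.empty(0, dtype=np.int64))
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    keep = np.empty(len(arr), dtype=bool)
    keep[0] = True
    np.not_equal(arr[1:], arr[:-1], out=keep[1:])
    idx = np.flatnonzero(keep)
    runs = np.diff(np.append(idx, len(arr)))
    return HpcSequence(arr[idx].tobytes().decode("ascii"), runs)


def hpc_expand(compressed: str, runs: Sequence[int]) -> str:
    """Run-length decode a compressed sequence."""
    runs = np.asarray(runs, dtype=np.int64)
    if len(runs) != len(compressed):
        raise ValueError("runs and compressed sequence differ in length")
    if len(compressed) == 0:
        return ""
    arr = np.frombuffer(compressed.encode("ascii"), dtype=np.uint8)
    return np.repeat(arr, runs).tobytes().decode("ascii")


@dataclass
class UnitigNode:
    """A maximal non-branching path of solid k-mers, in canonical orientation."""

    id: int
    hpc: HpcSequence
    coverage: float  # mean k-mer multiplicity across the unitig

    @property
    def compressed(self) -> str:
        return self.hpc.compressed

    @property
    def expanded(self) -> str:
        return self.hpc.expanded

    @property
    def expanded_length(self) -> int:
        return int(self.hpc.runs.sum())

    def oriented(self, orient: str) -> Tuple[str, np.ndarray]:
        """Compressed sequence and runs as traversed in ``orient``."""
        if orient == "+":
            return self.hpc.compressed, self.hpc.runs
        return revcomp(self.hpc.compressed), self.hpc.runs[::-1]

    def oriented_expanded(self, orient: str) -> str:
        comp, runs = self.oriented(orient)
        return hpc_expand(comp, runs)


def _edge_key(a: int, oa: str, b: int, ob: str):
    fwd = (a, oa, b, ob)
    rev = (b, _FLIP[ob], a, _FLIP[oa])
    return min(fwd, rev)


@dataclass
class AlleleGraph:
    """Unitig graph: k (in compressed space), nodes by id, canonical edges."""

    k: int
    nodes: Dict[int, UnitigNode] = field(default_factory=dict)
    edges: Dict[Tuple[int, str, int, str], float] = field(default_factory=dict)
    _adj: Optional[dict] = field(default=None, repr=False, compare=False)

    def add_edge(self, a: int, oa: str, b: int, ob: str, coverage: float = 1) -> None:
        key = _edge_key(a, oa, b, ob)
        self.edges[key] = self.edges.get(key, 0) + coverage
        self._adj = None

    def has_edge(self, a: int, oa: str, b: int, ob: str) -> bool:
        return _edge_key(a, oa, b, ob) in self.edges

    def successors(self, node: int, orient: str) -> List[Tuple[int, str, float]]:
        """Outgoing ``(node, orient, coverage)`` from an oriented node."""
        if self._adj is None:
            adj: dict = {}
            for (a, oa, b, ob), cov in self.edges.items():
                adj.setdefault((a, oa), []).append((b, ob, cov))
                if (a, oa, b, ob) != (b, _FLIP[ob], a, _FLIP[oa]):
                    adj.setdefault((b, _FLIP[ob]), []).append((a, _FLIP[oa], cov))
            for lst in adj.values():
                lst.sort()
            self._adj = adj
        return self._adj.get((node, orient), [])

    def walk_sequence(
        self, path: Sequence[Tuple[int, str]], check_edges: bool = True
    ) -> Tuple[str, List[int]]:
        """Expanded sequence of a walk plus the start coordinate of each node.

        Consecutive nodes overlap by k-1 compressed symbols; the junction
        bases are emitted once, using the predecessor's run estimates.
        """
        if not path:
            return "", []
        parts: List[str] = []
        starts: List[int] = [0]
        first_id, first_o = path[0]
        parts.append(self.nodes[first_id].oriented_expanded(first_o))
        cur_len = len(parts[0])
        for (pa, poa), (nb, nob) in zip(path, path[1:]):
            if check_edges and not self.has_edge(pa, poa, nb, nob):
                raise ValueError(f"walk uses non-edge ({pa}{poa})->({nb}{nob})")
            pred_comp, pred_runs = self.nodes[pa].oriented(poa)
            ovl_expanded = int(pred_runs[len(pred_runs) - (self.k - 1) :].sum())
            starts.append(cur_len - ovl_expanded)
            comp, runs = self.nodes[nb].oriented(nob)
            piece = hpc_expand(comp[self.k - 1 :], runs[self.k - 1 :])
            parts.append(piece)
            cur_len += len(piece)
        return "".join(parts), starts

    def validate(self) -> None:
        """Check edge overlap consistency: (k-1)-suffix == (k-1)-prefix."""
        for a, oa, b, ob in self.edges:
            sa, _ = self.nodes[a].oriented(oa)
            sb, _ = self.nodes[b].oriented(ob)
            if sa[len(sa) - (self.k - 1) :] != sb[: self.k - 1]:
                raise AssertionError(f"edge ({a}{oa})->({b}{ob}) overlap mismatch")

    def __eq__(self, other) -> bool:
        if not isinstance(other, AlleleGraph) or self.k != other.k:
            return False
        if set(self.nodes) != set(other.nodes):
            return False
        for nid, node in self.nodes.items():
            o = other.nodes[nid]
            if node.expanded != o.expanded:
                return False
            if abs(node.coverage - o.coverage) > 1e-6 * max(1.0, node.coverage):
                return False
        return set(self.edges) == set(other.edges)


# ---------------------------------------------------------------------------
# graph construction


def _compact_walks(n_items: int, outdeg, succ):
    """Maximal non-branching walks over a bidirected item graph.

    ``outdeg[side]`` is the out-degree of side ``2*item + orient`` and
    ``succ[side]`` the unique successor entry side where outdeg is 1.
    Returns ``(walks, circular_flags)`` where each walk is a list of
    ``(item, orient)`` pairs; items are seeded in ascending order so the
    result is deterministic.
    """
    used = np.zeros(n_items, dtype=bool)
    walks: List[List[Tuple[int, int]]] = []
    circular: List[bool] = []

    def step(side: int):
        if outdeg[side] != 1:
            return None
        t = succ[side]
        if outdeg[t ^ 1] != 1:
            return None
        return t

    for a in range(n_items):
        if used[a]:
            continue
        walk: List[Tuple[int, int]] = [(a, 0)]
        used[a] = True
        is_cycle = False
        cur = 2 * a
        while True:
            t = step(cur)
            if t is None:
                break
            b, ob = t >> 1, t & 1
            if (b, ob) == walk[0]:
                is_cycle = True
                break
            if used[b]:
                break
            walk.append((b, ob))
            used[b] = True
            cur = t
        if not is_cycle:
            cur = 2 * a + 1
            while True:
                t = step(cur)
                if t is None:
                    break
                b, ob = t >> 1, t & 1
                if used[b]:
                    break
                walk.insert(0, (b, ob ^ 1))
                used[b] = True
                cur = t
        walks.append(walk)
        circular.append(is_cycle)
    return walks, circular


def _group_median(keys: np.ndarray, values: np.ndarray, size: int) -> np.ndarray:
    """Lower median of ``values`` grouped by integer ``keys`` in [0, size)."""
    out = np.ones(size, dtype=np.int64)
    if len(keys) == 0:
        return out
    order = np.lexsort((values, keys))
    ks = keys[order]
    vs = values[order]
    bounds = np.flatnonzero(np.diff(ks)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(ks)]])
    mids = starts + (ends - starts - 1) // 2
    out[ks[starts]] = vs[mids]
    return out


def build_allele_graph(
    reads: Sequence[SequenceRecord | str],
    k: int,
    solid_min: int = 5,
) -> AlleleGraph:
    """Build the cleaned-orientation unitig graph from accurate reads.

    Reads are homopolymer-compressed before k-mer extraction; ``k`` counts
    compressed symbols and must be odd and <= 31 (packed-code fast path).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k > 31:
        raise ValueError("graph construction supports k <= 31")
    seqs = [r.bases if isinstance(r, SequenceRecord) else r for r in reads]
    comp_list: List[str] = []
    runs_list: List[np.ndarray] = []
    for s in seqs:
        h = hpc_compress(s)
        if len(h.compressed) >= k:
            comp_list.append(h.compressed)
            runs_list.append(h.runs)
    if not comp_list:
        raise ValueError("no read yields a solid k-mer (reads shorter than k?)")

    per_read = [canonical_kmer_codes(c, k, return_strand=True) for c in comp_list]
    all_codes = np.concatenate([p[0] for p in per_read])
    solid_codes, counts = np.unique(all_codes, return_counts=True)
    keep = counts >= solid_min
    solid_codes, solid_counts = solid_codes[keep], counts[keep]
    m = len(solid_codes)
    if m == 0:
        raise ValueError(
            f"no k-mer reaches multiplicity {solid_min}; lower solid_min"
        )

    # per-read solid k-mer ids and orientations
    read_hits = []  # (comp_pos, kmer_id, orient(0=canonical fwd)) per read
    for codes, pos, fwd_is_canon in per_read:
        idx = np.searchsorted(solid_codes, codes)
        idx_c = np.minimum(idx, m - 1)
        found = solid_codes[idx_c] == codes
        read_hits.append((pos[found], idx_c[found], (~fwd_is_canon[found]).astype(np.int64)))

    # k-mer level edges: consecutive solid k-mers within a read
    edge_keys = []
    big = np.int64(2 * m)
    for pos, kid, orient in read_hits:
        if len(pos) < 2:
            continue
        adjacent = (pos[1:] - pos[:-1]) == 1
        sa = 2 * kid[:-1] + orient[:-1]
        sb = 2 * kid[1:] + orient[1:]
        fwd = sa[adjacent] * big + sb[adjacent]
        rev = (sb[adjacent] ^ 1) * big + (sa[adjacent] ^ 1)
        edge_keys.append(np.minimum(fwd, rev))
    if edge_keys:
        ek = np.concatenate(edge_keys)
        uniq_edges, edge_counts = np.unique(ek, return_counts=True)
    else:
        uniq_edges = np.empty(0, dtype=np.int64)
        edge_counts = np.empty(0, dtype=np.int64)

    # side adjacency for compaction (both directions of each edge)
    ea = (uniq_edges // big).astype(np.int64)
    eb = (uniq_edges % big).astype(np.int64)
    from_sides = np.concatenate([ea, eb ^ 1])
    to_sides = np.concatenate([eb, ea ^ 1])
    pairs = np.unique(from_sides * (2 * big) + to_sides)
    from_u = (pairs // (2 * big)).astype(np.int64)
    to_u = (pairs % (2 * big)).astype(np.int64)
    outdeg = np.bincount(from_u, minlength=2 * m)
    succ = np.full(2 * m, -1, dtype=np.int64)
    single = np.flatnonzero(np.bincount(from_u, minlength=2 * m) == 1)
    # map side -> its unique successor
    order = np.argsort(from_u, kind="stable")
    succ[from_u[order]] = to_u[order]  # last write wins; only used where outdeg==1

    walks, circular = _compact_walks(m, outdeg, succ)

    # unitig sequences in compressed space
    def oriented_kmer(kid: int, orient: int) -> str:
        s = code_to_kmer(int(solid_codes[kid]), k)
        return s if orient == 0 else revcomp(s)

    raw_unitigs = []
    for walk, is_cycle in zip(walks, circular):
        comp = [oriented_kmer(walk[0][0], walk[0][1])]
        for kid, orient in walk[1:]:
            comp.append(oriented_kmer(kid, orient)[-1])
        seq = "".join(comp)
        cov = float(np.mean([solid_counts[kid] for kid, _ in walk]))
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
            walk = [(kid, orient ^ 1) for kid, orient in reversed(walk)]
        raw_unitigs.append((seq, walk, cov, is_cycle))
    raw_unitigs.sort(key=lambda t: t[0])

    # k-mer -> (unitig, offset, orientation-in-unitig)
    k_uid = np.empty(m, dtype=np.int64)
    k_pos = np.empty(m, dtype=np.int64)
    k_or = np.empty(m, dtype=np.int64)
    for uid, (_, walk, _, _) in enumerate(raw_unitigs):
        for off, (kid, orient) in enumerate(walk):
            k_uid[kid] = uid
            k_pos[kid] = off
            k_or[kid] = orient

    # unitig edges from boundary k-mer edges
    graph = AlleleGraph(k=k)
    ubase = np.zeros(len(raw_unitigs) + 1, dtype=np.int64)
    for uid, (seq, walk, cov, _) in enumerate(raw_unitigs):
        ubase[uid + 1] = ubase[uid] + len(seq)
    total_comp = int(ubase[-1])

    for key, cnt in zip(uniq_edges, edge_counts):
        sa, sb = int(key // big), int(key % big)
        a, oa = sa >> 1, sa & 1
        b, ob = sb >> 1, sb & 1
        ua, pa = int(k_uid[a]), int(k_pos[a])
        ub, pb = int(k_uid[b]), int(k_pos[b])
        # orientation of traversal relative to the unitig's stored strand
        ta = "+" if oa == k_or[a] else "-"
        tb = "+" if ob == k_or[b] else "-"
        if ua == ub and (
            (ta == "+" and tb == "+" and pb == pa + 1)
            or (ta == "-" and tb == "-" and pb == pa - 1)
        ):
            continue  # interior junction, already compacted
        graph.add_edge(ua, ta, ub, tb, float(cnt))

    # run-length observations: maximal diagonal stretches of matching k-mers
    # map contiguous read intervals onto unitig intervals, so every unitig
    # position (interior positions of short unitigs included) is observed
    gp_parts = []
    val_parts = []
    for (pos, kid, orient), runs in zip(read_hits, runs_list):
        if len(pos) == 0:
            continue
        same = orient == k_or[kid]
        uid = k_uid[kid]
        p = k_pos[kid]
        diag = np.where(same, p - pos, p + pos)
        brk = np.flatnonzero(
            (np.diff(pos) != 1)
            | (np.diff(uid) != 0)
            | (np.diff(same.astype(np.int8)) != 0)
            | (np.diff(diag) != 0)
        )
        starts = np.concatenate([[0], brk + 1])
        ends = np.concatenate([brk, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            j0, j1 = int(pos[a]), int(pos[b])
            length = j1 - j0 + k
            vals = runs[j0 : j0 + length]
            base = int(ubase[uid[a]])
            if same[a]:
                gp = base + np.arange(int(p[a]), int(p[a]) + length)
            else:
                gp = base + np.arange(int(p[b]), int(p[a]) + k)
                vals = vals[::-1]
            gp_parts.append(gp)
            val_parts.append(vals)
    gps = np.concatenate(gp_parts)
    vals = np.concatenate(val_parts)
    medians = _group_median(gps, vals, total_comp)

    for uid, (seq, walk, cov, _) in enumerate(raw_unitigs):
        runs = medians[ubase[uid] : ubase[uid + 1]]
        graph.nodes[uid] = UnitigNode(
            id=uid, hpc=HpcSequence(seq, runs), coverage=cov
        )
    return graph


# ---------------------------------------------------------------------------
# cleaning


def _recompact(graph: AlleleGraph) -> AlleleGraph:
    """Merge non-branching unitig chains after node removals."""
    ids = sorted(graph.nodes)
    id_of = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    adj_count = np.zeros(2 * n, dtype=np.int64)
    succ = np.full(2 * n, -1, dtype=np.int64)
    for nid in ids:
        for orient, bit in (("+", 0), ("-", 1)):
            succs = graph.successors(nid, orient)
            s = 2 * id_of[nid] + bit
            adj_count[s] = len(succs)
            if len(succs) == 1:
                b, ob, _ = succs[0]
                succ[s] = 2 * id_of[b] + (0 if ob == "+" else 1)
    walks, circular = _compact_walks(n, adj_count, succ)

    k = graph.k
    merged = []
    where: Dict[int, Tuple[int, int, int, int]] = {}  # old id -> (walk, pos, orient, walk_len)
    for w_i, walk in enumerate(walks):
        comp_parts: List[str] = []
        run_parts: List[np.ndarray] = []
        weights = 0.0
        covsum = 0.0
        for j, (item, orient) in enumerate(walk):
            node = graph.nodes[ids[item]]
            ochar = "+" if orient == 0 else "-"
            comp, runs = node.oriented(ochar)
            if j == 0:
                comp_parts.append(comp)
                run_parts.append(runs)
            else:
                comp_parts.append(comp[k - 1 :])
                run_parts.append(runs[k - 1 :])
            w = max(len(comp) - k + 1, 1)
            weights += w
            covsum += node.coverage * w
            where[ids[item]] = (w_i, j, orient, len(walk))
        seq = "".join(comp_parts)
        runs = np.concatenate(run_parts)
        flipped = False
        rc = revcomp(seq)
        if rc < seq:
            seq, runs, flipped = rc, runs[::-1], True
        merged.append((seq, runs, covsum / weights, flipped))

    order = sorted(range(len(merged)), key=lambda i: merged[i][0])
    new_id = {w_i: rank for rank, w_i in enumerate(order)}
    out = AlleleGraph(k=k)
    for w_i, (seq, runs, cov, _) in enumerate(merged):
        out.nodes[new_id[w_i]] = UnitigNode(
            id=new_id[w_i], hpc=HpcSequence(seq, runs), coverage=cov
        )

    def endpoint(old: int, o: str):
        """New (node, orient) when *exiting* old node ``old`` via strand o."""
        w_i, pos, orient, wlen = where[old]
        oi = 0 if o == "+" else 1
        flipped = merged[w_i][3]
        exits_fwd = oi == orient  # exit in walk-forward direction
        if exits_fwd and pos != wlen - 1:
            return None
        if not exits_fwd and pos != 0:
            return None
        no = "+" if exits_fwd != flipped else "-"
        return new_id[w_i], no

    for (a, oa, b, ob), cov in graph.edges.items():
        ea = endpoint(a, oa)
        # entering b with orientation ob == exiting b with flipped strand
        eb = endpoint(b, _FLIP[ob])
        if ea is None or eb is None:
            continue  # interior edge consumed by the merge
        na, noa = ea
        nb, nob = eb
        key = _edge_key(na, noa, nb, _FLIP[nob])
        out.edges[key] = out.edges.get(key, 0) + cov
    return out


def clean_graph(
    graph: AlleleGraph,
    min_node_coverage: float,
    max_tip_length: int,
) -> AlleleGraph:
    """Drop low-coverage nodes and weak short tips, then re-compact.

    A tip is a dead-end unitig (no edges on at least one side) shorter than
    ``max_tip_length`` expanded bases whose coverage is below 25% of its
    best-covered neighbour.
    """
    drop = {nid for nid, n in graph.nodes.items() if n.coverage < min_node_coverage}
    for nid, node in graph.nodes.items():
        if nid in drop:
            continue
        succ_f = [s for s in graph.successors(nid, "+") if s[0] not in drop]
        succ_r = [s for s in graph.successors(nid, "-") if s[0] not in drop]
        if succ_f and succ_r:
            continue
        if node.expanded_length >= max_tip_length:
            continue
        neigh = [graph.nodes[s[0]].coverage for s in succ_f + succ_r if s[0] != nid]
        if neigh and node.coverage < 0.25 * max(neigh):
            drop.add(nid)
    kept = AlleleGraph(k=graph.k)
    for nid, node in graph.nodes.items():
        if nid not in drop:
            kept.nodes[nid] = node
    for (a, oa, b, ob), cov in graph.edges.items():
        if a not in drop and b not in drop:
            kept.edges[(a, oa, b, ob)] = cov
    if not kept.nodes:
        raise ValueError(
            "cleaning removed every node; lower min_node_coverage or solid_min"
        )
    return _recompact(kept)
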