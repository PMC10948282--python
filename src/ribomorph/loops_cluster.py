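"""Loop extraction and density clustering of repeat-unit traversals.

A *loop* is one complete repeat-unit traversal: the expanded graph sequence
between two consecutive same-orientation visits of a fixed high-coverage
*anchor* node in an ultralong read's alignment path.  Because the loop
sequence comes from the graph (built from accurate reads) rather than from
the raw noisy read, loops from the same morph are identical or nearly so,
and morphs separate as density clusters of the pairwise edit distances.

Clustering is two-stage: union-find *rough clusters* join loops within
``max_rough_diff`` edits; the DBSCAN radius epsilon is then estimated as the
mean within-rough-cluster pairwise distance (floored at ``min_epsilon``), and
DBSCAN with a precomputed sparse metric produces the morph clusters.  Since
epsilon never exceeds ``max_rough_diff``, every density cluster is contained
in one rough cluster.

Identical loop sequences are collapsed to one representative internally, so
the pairwise stage scales with the number of distinct traversals, not reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import edlib
import numpy as np

from .allele_graph import AlleleGraph
from .graph_align import AlignmentPath
from .recruit import canonical_kmer_codes, revcomp

__all__ = [
    "Loop",
    "ClusterParams",
    "MorphCluster",
    "PairwiseDistances",
    "select_anchor_node",
    "extract_loops",
    "pairwise_distances",
    "rough_cluster",
    "estimate_epsilon",
    "dbscan_cluster",
]


@dataclass
class Loop:
    """One full repeat-unit traversal, in canonical (anchor) orientation.

    ``sequence`` is the expanded graph walk (accurate-read derived);
    ``raw_sequence``, when available, is the corresponding raw read segment —
    noisy, but with per-unit homopolymer and tandem-motif lengths intact —
    used as independent evidence when polishing a cluster consensus.
    """

    read_id: str
    ordinal: int
    sequence: str
    path: List[Tuple[int, str]]
    raw_sequence: Optional[str] = None


@dataclass
class ClusterParams:
    max_rough_diff: int = 450
    min_epsilon: int = 1
    min_pts: int = 5
    epsilon: Optional[int] = None  # estimated when None

    def __post_init__(self) -> None:
        if self.min_epsilon < 1:
            raise ValueError("min_epsilon must be >= 1")
        if self.max_rough_diff < self.min_epsilon:
            raise ValueError("max_rough_diff must be >= min_epsilon")


@dataclass
class MorphCluster:
    loop_indices: Set[int]
    epsilon_used: int


def select_anchor_node(graph: AlleleGraph) -> int:
    """Pick the loop-boundary node.

    The anchor must be traversed once per repeat unit, so it should be the
    node shared by the most units: k-mer coverage is proportional to that
    count.  Among nodes of compressed length >= 2k (which excludes the short
    cyclic stubs that tandem motifs compact into, whose coverage counts many
    traversals per unit), the highest-coverage node wins; ties go to the
    longer node, then the smaller id.  If no node passes the length filter,
    the highest coverage x length product wins.
    """
    if not graph.nodes:
        raise ValueError("empty graph")
    candidates = [
        n for n in graph.nodes.values() if len(n.compressed) >= 2 * graph.k
    ]
    if candidates:
        best = min(
            candidates, key=lambda n: (-n.coverage, -n.expanded_length, n.id)
        )
        return best.id
    return min(
        graph.nodes,
        key=lambda nid: (
            -graph.nodes[nid].coverage * graph.nodes[nid].expanded_length,
            nid,
        ),
    )


def _walk_to_read_map(
    read_bases: str, path: AlignmentPath, walk_seq: str, starts: Sequence[int]
) -> Optional[np.ndarray]:
    """Read coordinate for every walk coordinate of the aligned clip."""
    import edlib

    from .consensus import _cigar_ops

    r0, r1 = path.read_interval
    lo = path.start_offset
    hi = starts[-1] + path.end_offset
    query = read_bases[r0:r1]
    ref = walk_seq[lo:hi]
    if not query or not ref:
        return None
    res = edlib.align(query, ref, mode="NW", task="path")
    mapping = np.zeros(len(ref) + 1, dtype=np.int64)
    t = q = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op in "=XM":
            mapping[t : t + n] = np.arange(q, q + n)
            t += n
            q += n
        elif op == "D":
            mapping[t : t + n] = q
            t += n
        elif op == "I":
            q += n
    mapping[len(ref)] = q
    # shift into absolute coordinates
    return mapping + r0


def extract_loops(
    path: AlignmentPath,
    anchor: int,
    approx_morph_size: int,
    graph: AlleleGraph,
    read_bases: Optional[str] = None,
) -> Tuple[List[Loop], int]:
    """Loops between consecutive same-orientation anchor visits in one path.

    Loops whose length falls outside [0.5, 2.0] x ``approx_morph_size`` are
    discarded; the second return value counts them.  Loops anchored on the
    ``-`` strand are reverse-complemented to canonical orientation.  When the
    read sequence is supplied, each loop also records its raw read segment
    (located through the path's base-level alignment).
    """
    occ = [i for i, (nid, _) in enumerate(path.path) if nid == anchor]
    if len(occ) < 2:
        return [], 0
    walk_seq, starts = graph.walk_sequence(path.path, check_edges=False)
    alen = graph.nodes[anchor].expanded_length
    clip_lo = path.start_offset
    clip_hi = starts[-1] + path.end_offset
    mapping = (
        _walk_to_read_map(read_bases, path, walk_seq, starts)
        if read_bases is not None
        else None
    )
    loops: List[Loop] = []
    discarded = 0
    ordinal = 0

    def anchor_fully_covered(v: int) -> bool:
        # a complete traversal needs both of its boundary anchor visits
        # to lie entirely inside the read's aligned clip
        return starts[v] >= clip_lo and starts[v] + alen <= clip_hi

    for i, j in zip(occ, occ[1:]):
        if path.path[i][1] != path.path[j][1]:
            continue
        if not (anchor_fully_covered(i) and anchor_fully_covered(j)):
            continue
        if path.path[i][1] == "-":
            # a minus-strand walk meets the anchor end first; shift by the
            # anchor length so every loop's origin is the anchor *start* on
            # the plus strand, keeping all loops in one rotational register
            lo, hi = starts[i] + alen, starts[j] + alen
            if hi > len(walk_seq):
                continue  # walk ends inside the shifted window
            seq = revcomp(walk_seq[lo:hi])
        else:
            lo, hi = starts[i], starts[j]
            seq = walk_seq[lo:hi]
        if not (0.5 * approx_morph_size <= len(seq) <= 2.0 * approx_morph_size):
            discarded += 1
            continue
        raw = None
        if mapping is not None and clip_lo <= lo and hi <= clip_hi:
            rlo = int(mapping[lo - clip_lo])
            rhi = int(mapping[hi - clip_lo])
            if rhi - rlo < 0.8 * (hi - lo):
                # the read does not actually span this traversal (e.g. a
                # short read touching the anchor twice across a self-edge)
                discarded += 1
                continue
            raw = read_bases[rlo:rhi]
            if path.path[i][1] == "-":
                raw = revcomp(raw)
        loops.append(
            Loop(
                read_id=path.read_id,
                ordinal=ordinal,
                sequence=seq,
                path=path.path[i : j + 1],
                raw_sequence=raw,
            )
        )
        ordinal += 1
    return loops, discarded


def _loop_seqs(loops: Sequence) -> List[str]:
    return [lp.sequence if isinstance(lp, Loop) else lp for lp in loops]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


class PairwiseDistances:
    """Sparse symmetric threshold-limited edit distances between loops.

    Distances above ``limit`` are represented as absent ("exceeds").
    Identical sequences are collapsed into classes; a 15-mer sketch prefilter
    marks pairs sharing <5% of sketch k-mers as exceeding without alignment.
    """

    SKETCH_K = 15
    SKETCH_TARGET = 64  # aim for at least this many sampled k-mers
    SKETCH_MIN_SHARE = 0.05

    def __init__(
        self,
        sequences: Sequence[str],
        limit: int,
        rough_limit: Optional[int] = None,
    ):
        self.limit = int(limit)
        self.rough_limit = int(rough_limit) if rough_limit is not None else None
        self.n = len(sequences)
        self.class_of = np.empty(self.n, dtype=np.int64)
        self.class_seqs: List[str] = []
        seen: Dict[str, int] = {}
        for i, s in enumerate(sequences):
            ci = seen.setdefault(s, len(self.class_seqs))
            if ci == len(self.class_seqs):
                self.class_seqs.append(s)
            self.class_of[i] = ci
        self.class_members: List[List[int]] = [[] for _ in self.class_seqs]
        for i, ci in enumerate(self.class_of):
            self.class_members[ci].append(i)
        self.class_weight = np.array(
            [len(m) for m in self.class_members], dtype=np.int64
        )
        shortest = min((len(c) for c in self.class_seqs), default=0)
        # subsample so even the shortest sequence keeps ~SKETCH_TARGET k-mers
        self._mod = 1
        while (
            self._mod < 64
            and (shortest - self.SKETCH_K + 1) // (2 * self._mod) >= self.SKETCH_TARGET
        ):
            self._mod *= 2
        self._d: Dict[Tuple[int, int], int] = {}
        self._exact: Dict[Tuple[int, int], int] = {}
        self._compute()

    def _sketch(self, seq: str) -> frozenset:
        codes = canonical_kmer_codes(seq, self.SKETCH_K)
        if len(codes) == 0:
            return frozenset()
        return frozenset(codes[codes % np.uint64(self._mod) == 0].tolist())

    def _compute(self) -> None:
        m = len(self.class_seqs)
        sketches = [self._sketch(s) for s in self.class_seqs]
        lens = [len(s) for s in self.class_seqs]
        k1 = self.rough_limit if self.rough_limit is not None else self.limit
        for i in range(m):
            si = self.class_seqs[i]
            sk_i = sketches[i]
            for j in range(i + 1, m):
                if abs(lens[i] - lens[j]) > self.limit:
                    continue
                sk_j = sketches[j]
                # the sketch screen is only statistically sound when sketches
                # are reasonably large (short sequences lose nearly all exact
                # 15-mers after a few edits)
                if min(len(sk_i), len(sk_j)) >= self.SKETCH_TARGET:
                    share = len(sk_i & sk_j) / min(len(sk_i), len(sk_j))
                    if share < self.SKETCH_MIN_SHARE:
                        continue
                d = edlib.align(
                    si, self.class_seqs[j], mode="NW", task="distance", k=k1
                )["editDistance"]
                if d != -1:
                    self._d[(i, j)] = d
        if self.rough_limit is None or self.limit <= self.rough_limit:
            return
        # second pass: distances between rough_limit and limit are only
        # needed inside rough clusters (epsilon never exceeds the rough
        # radius), so complete them there instead of over all pairs
        uf = _UnionFind(m)
        for (a, b), d in self._d.items():
            if d <= self.rough_limit:
                uf.union(a, b)
        groups: Dict[int, List[int]] = {}
        for ci in range(m):
            groups.setdefault(uf.find(ci), []).append(ci)
        for members in groups.values():
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    key = (members[x], members[y])
                    if key in self._d:
                        continue
                    d = edlib.align(
                        self.class_seqs[key[0]],
                        self.class_seqs[key[1]],
                        mode="NW",
                        task="distance",
                        k=self.limit,
                    )["editDistance"]
                    if d != -1:
                        self._d[key] = d

    def class_distance(self, ci: int, cj: int) -> Optional[int]:
        if ci == cj:
            return 0
        key = (min(ci, cj), max(ci, cj))
        return self._d.get(key)

    def get(self, i: int, j: int) -> Optional[int]:
        """Edit distance between loops i and j, or None if above the limit."""
        return self.class_distance(int(self.class_of[i]), int(self.class_of[j]))

    def exact(self, i: int, j: int) -> int:
        """Unbounded edit distance, computed on demand and cached."""
        ci, cj = int(self.class_of[i]), int(self.class_of[j])
        if ci == cj:
            return 0
        key = (min(ci, cj), max(ci, cj))
        if key in self._d:
            return self._d[key]
        if key not in self._exact:
            self._exact[key] = edlib.align(
                self.class_seqs[key[0]],
                self.class_seqs[key[1]],
                mode="NW",
                task="distance",
            )["editDistance"]
        return self._exact[key]

    def class_neighbors(self, ci: int, radius: int) -> List[int]:
        out = [ci]
        for (a, b), d in self._d.items():
            if d <= radius:
                if a == ci:
                    out.append(b)
                elif b == ci:
                    out.append(a)
        return out


def pairwise_distances(
    loops: Sequence, limit: int, rough_limit: Optional[int] = None
) -> PairwiseDistances:
    """Threshold-limited pairwise edit distance table of the loops.

    With ``rough_limit`` set, distances above it are only resolved for pairs
    that fall in the same rough cluster (union-find at ``rough_limit``); this
    is what the pipeline needs — the DBSCAN radius never exceeds the rough
    radius — at a fraction of the all-pairs cost.
    """
    return PairwiseDistances(_loop_seqs(loops), limit, rough_limit)


def rough_cluster(
    distances: PairwiseDistances, max_rough_diff: int
) -> List[List[int]]:
    """Connected components of pairs within ``max_rough_diff`` edits."""
    if max_rough_diff > distances.limit:
        raise ValueError("distances were computed with a limit below max_rough_diff")
    m = len(distances.class_seqs)
    uf = _UnionFind(m)
    for (a, b), d in distances._d.items():
        if d <= max_rough_diff:
            uf.union(a, b)
    groups: Dict[int, List[int]] = {}
    for ci in range(m):
        groups.setdefault(uf.find(ci), []).append(ci)
    clusters = []
    for classes in groups.values():
        members = sorted(i for ci in classes for i in distances.class_members[ci])
        clusters.append(members)
    clusters.sort(key=lambda c: c[0])
    return clusters


def estimate_epsilon(
    rough_clusters: Sequence[Sequence[int]],
    distances: PairwiseDistances,
    min_epsilon: int = 1,
) -> int:
    """DBSCAN radius: mean finite pairwise distance within rough clusters.

    Rounded half-up and floored at ``min_epsilon``; clusters of size one
    contribute nothing, and with no eligible pair the floor is returned.
    """
    if not rough_clusters:
        raise ValueError("need at least one rough cluster")
    total = 0.0
    weight = 0
    for cluster in rough_clusters:
        if len(cluster) < 2:
            continue
        classes: Dict[int, int] = {}
        for i in cluster:
            ci = int(distances.class_of[i])
            classes[ci] = classes.get(ci, 0) + 1
        items = sorted(classes.items())
        for ci, mi in items:
            weight += mi * (mi - 1) // 2  # identical pairs at distance 0
        for x in range(len(items)):
            for y in range(x + 1, len(items)):
                d = distances.class_distance(items[x][0], items[y][0])
                if d is None:
                    continue
                w = items[x][1] * items[y][1]
                total += d * w
                weight += w
    if weight == 0:
        return min_epsilon
    return max(min_epsilon, int(np.floor(total / weight + 0.5)))


def dbscan_cluster(
    loops: Sequence,
    distances: PairwiseDistances,
    epsilon: int,
    min_pts: int,
) -> Tuple[List[MorphCluster], Set[int]]:
    """Standard DBSCAN over the precomputed metric.

    A loop is a core point iff it has >= ``min_pts`` neighbours within
    ``epsilon`` (inclusive, counting itself); clusters are the connected core
    points plus border points, borders assigned to the lowest-id adjacent
    cluster; remaining loops are noise.
    """
    if epsilon < 1:
        raise ValueError("epsilon must be >= 1")
    if epsilon > distances.limit:
        raise ValueError("epsilon exceeds the distance table limit")
    m = len(distances.class_seqs)
    neigh: List[List[int]] = [[ci] for ci in range(m)]
    for (a, b), d in distances._d.items():
        if d <= epsilon:
            neigh[a].append(b)
            neigh[b].append(a)
    weight = distances.class_weight
    core = np.array(
        [sum(int(weight[cj]) for cj in neigh[ci]) >= min_pts for ci in range(m)]
    )
    # connected components of core classes
    comp = np.full(m, -1, dtype=np.int64)
    comp_min_loop: List[int] = []
    n_comp = 0
    min_loop_of_class = [
        (min(mbrs) if mbrs else -1) for mbrs in distances.class_members
    ]
    for ci in range(m):
        if not core[ci] or comp[ci] != -1:
            continue
        stack = [ci]
        comp[ci] = n_comp
        lowest = min_loop_of_class[ci]
        while stack:
            cur = stack.pop()
            for nb in neigh[cur]:
                if core[nb] and comp[nb] == -1:
                    comp[nb] = n_comp
                    lowest = min(lowest, min_loop_of_class[nb])
                    stack.append(nb)
        comp_min_loop.append(lowest)
        n_comp += 1
    order = sorted(range(n_comp), key=lambda c: comp_min_loop[c])
    rank = {c: r for r, c in enumerate(order)}

    clusters: List[Set[int]] = [set() for _ in range(n_comp)]
    noise: Set[int] = set()
    for ci in range(m):
        if core[ci]:
            clusters[rank[comp[ci]]].update(distances.class_members[ci])
        else:
            adj = sorted(rank[comp[nb]] for nb in neigh[ci] if core[nb])
            if adj:
                clusters[adj[0]].update(distances.class_members[ci])
            else:
                noise.update(distances.class_members[ci])
    return [MorphCluster(c, epsilon) for c in clusters], noise
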