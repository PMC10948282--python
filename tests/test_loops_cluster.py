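import numpy as np
import pytest

from ribomorph.allele_graph import build_allele_graph, clean_graph
from ribomorph.formats import SequenceRecord
from ribomorph.graph_align import align_reads
from ribomorph.loops_cluster import (
    dbscan_cluster,
    estimate_epsilon,
    extract_loops,
    pairwise_distances,
    rough_cluster,
    select_anchor_node,
)
from ribomorph.recruit import revcomp

from conftest import random_dna


def dp_edit_distance(a, b):
    """Plain dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(
                prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)
            )
        prev = cur
    return prev[-1]


def mutate(rng, s, n):
    s = list(s)
    for p in rng.integers(0, len(s), n):
        s[p] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(s)


# ---------------------------------------------------------------------- anchor


def test_select_anchor_prefers_most_shared_node(single_morph_setup):
    unit, _, _, hifi, _ = single_morph_setup
    g = clean_graph(build_allele_graph(hifi, k=31, solid_min=3), 3, 150)
    assert select_anchor_node(g) == next(iter(g.nodes))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_select_anchor_equals_bruteforce(seed):
    rng = np.random.default_rng(seed)
    base = random_dna(rng, 2500)
    variants = [base] + [mutate(rng, base, 5) for _ in range(3)]
    reads = [v for v in variants for _ in range(5)]
    g = build_allele_graph(reads, k=21, solid_min=3)
    best = select_anchor_node(g)
    candidates = [n for n in g.nodes.values() if len(n.compressed) >= 2 * g.k]
    pool = candidates or list(g.nodes.values())
    if candidates:
        oracle = min(pool, key=lambda n: (-n.coverage, -n.expanded_length, n.id)).id
    else:
        oracle = min(pool, key=lambda n: (-n.coverage * n.expanded_length, n.id)).id
    assert best == oracle


def test_select_anchor_empty_graph():
    from ribomorph.allele_graph import AlleleGraph

    with pytest.raises(ValueError):
        select_anchor_node(AlleleGraph(k=31))


# ----------------------------------------------------------------------- loops


def test_loop_extraction_fencepost(single_morph_setup):
    """An error-free read of exactly three unit lengths starting at the
    anchor yields exactly two complete loops."""
    unit, array_seq, _, hifi, _ = single_morph_setup
    g = clean_graph(build_allele_graph(hifi, k=31, solid_min=3), 3, 150)
    anchor = select_anchor_node(g)
    anchor_seq = g.nodes[anchor].expanded
    pos = array_seq.find(anchor_seq)
    if pos < 0:
        pos = array_seq.find(revcomp(anchor_seq))
    # two full traversals plus the complete closing anchor
    read = SequenceRecord(
        "r", array_seq[pos : pos + 2 * len(unit) + len(anchor_seq)]
    )
    (path,) = align_reads([read], g)
    loops, discarded = extract_loops(path, anchor, len(unit), g)
    assert discarded == 0
    assert len(loops) == 2
    for lp in loops:
        assert len(lp.sequence) == len(unit)
        assert lp.sequence in unit + unit or revcomp(lp.sequence) in unit + unit
        assert lp.path[0][0] == anchor and lp.path[-1][0] == anchor
        assert lp.path[0][1] == lp.path[-1][1]


def test_loop_count_matches_string_search(single_morph_setup):
    """Error-free: total loops = sum over reads of (anchor occurrences - 1)."""
    unit, array_seq, _, hifi, ont = single_morph_setup
    g = clean_graph(build_allele_graph(hifi, k=31, solid_min=3), 3, 150)
    anchor = select_anchor_node(g)
    anchor_seq = g.nodes[anchor].expanded
    paths = align_reads(ont, g)
    total = 0
    for p in paths:
        loops, _ = extract_loops(p, anchor, len(unit), g)
        total += len(loops)
    expected = 0
    for read in ont:
        occ = sum(
            read.bases[i : i + len(anchor_seq)] in (anchor_seq, revcomp(anchor_seq))
            for i in range(len(read.bases) - len(anchor_seq) + 1)
        )
        expected += max(occ - 1, 0)
    assert total == expected


def test_single_anchor_visit_yields_no_loops(single_morph_setup):
    unit, array_seq, _, hifi, _ = single_morph_setup
    g = clean_graph(build_allele_graph(hifi, k=31, solid_min=3), 3, 150)
    anchor = select_anchor_node(g)
    read = SequenceRecord("s", array_seq[: (3 * len(unit)) // 4])
    paths = align_reads([read], g)
    loops = []
    for p in paths:
        loops += extract_loops(p, anchor, len(unit), g)[0]
    assert loops == []


# ------------------------------------------------------------------- distances


def test_distance_examples():
    d = pairwise_distances(["ACGT", "ACGT", "ACT"], limit=10)
    assert d.get(0, 1) == 0
    assert d.get(0, 2) == 1


@pytest.mark.parametrize("seed", range(4))
def test_threshold_limited_distance_equals_dp(seed):
    rng = np.random.default_rng(seed)
    seqs = []
    for _ in range(25):
        base = random_dna(rng, int(rng.integers(50, 260)))
        seqs.append(mutate(rng, base, int(rng.integers(0, 12))))
    limit = 40
    table = pairwise_distances(seqs, limit)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            truth = dp_edit_distance(seqs[i], seqs[j])
            got = table.get(i, j)
            if truth <= limit:
                assert got == truth
            else:
                assert got is None
            assert table.exact(i, j) == truth


# ------------------------------------------------------------- rough clusters


@pytest.mark.parametrize("seed", range(5))
def test_rough_cluster_equals_connected_components(seed):
    rng = np.random.default_rng(seed)
    families = [random_dna(rng, 120) for _ in range(4)]
    seqs = [mutate(rng, families[int(rng.integers(0, 4))], 2) for _ in range(30)]
    thr = 8
    table = pairwise_distances(seqs, limit=thr)
    got = rough_cluster(table, thr)
    # BFS oracle over the thresholded pair graph
    adj = {i: set() for i in range(len(seqs))}
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if dp_edit_distance(seqs[i], seqs[j]) <= thr:
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(len(seqs)):
        if i in seen:
            continue
        queue, comp = [i], set()
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.append(sorted(comp))
    comps.sort(key=lambda c: c[0])
    assert got == comps


def test_transitivity_example():
    # d(a,b)=5, d(b,c)=5, d(a,c)=10 > threshold transitively joined
    a = "A" * 40 + "C" * 40
    b = a[:-5] + "G" * 5
    c = b[:5].replace("A", "T") + b[5:]
    table = pairwise_distances([a, b, c], limit=12)
    assert rough_cluster(table, 6) == [[0, 1, 2]]


# ---------------------------------------------------------------------- epsilon


def test_epsilon_floor_when_all_identical():
    loops = ["ACGTACGTAC"] * 8
    table = pairwise_distances(loops, limit=10)
    rough = rough_cluster(table, 10)
    assert estimate_epsilon(rough, table, min_epsilon=1) == 1


def test_epsilon_is_the_rounded_mean():
    base = "ACGT" * 30
    s1 = base
    s2 = base[:-10] + "T" * 10  # some edits from base
    s3 = "TGCA" * 5 + base[20:]  # more edits from base
    table = pairwise_distances([s1, s2, s3], limit=60)
    rough = rough_cluster(table, 60)
    d12 = table.get(0, 1)
    d13 = table.get(0, 2)
    d23 = table.get(1, 2)
    expected = max(1, int(np.floor((d12 + d13 + d23) / 3 + 0.5)))
    assert estimate_epsilon(rough, table, 1) == expected


@pytest.mark.parametrize("trial", range(10))
def test_epsilon_monotone_under_pooling(trial):
    """Pooling two divergent loop families never shrinks epsilon."""
    rng = np.random.default_rng(100 + trial)
    fam_a = random_dna(rng, 600)
    fam_b = mutate(rng, fam_a, 40)
    loops_a = [mutate(rng, fam_a, int(rng.integers(0, 5))) for _ in range(8)]
    loops_b = [mutate(rng, fam_b, int(rng.integers(0, 5))) for _ in range(8)]
    lim = 400
    ta = pairwise_distances(loops_a, lim)
    tb = pairwise_distances(loops_b, lim)
    tp = pairwise_distances(loops_a + loops_b, lim)
    ea = estimate_epsilon(rough_cluster(ta, lim), ta, 1)
    eb = estimate_epsilon(rough_cluster(tb, lim), tb, 1)
    ep = estimate_epsilon(rough_cluster(tp, lim), tp, 1)
    assert ep >= ea and ep >= eb


# ----------------------------------------------------------------------- dbscan


def _sklearn_labels(seqs, eps, min_pts):
    from sklearn.cluster import DBSCAN

    import edlib

    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = edlib.align(seqs[i], seqs[j], mode="NW")[
                "editDistance"
            ]
    return DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(D).labels_


@pytest.mark.parametrize("seed", range(40))
def test_dbscan_matches_reference_implementation(seed):
    """Partition equality with scikit-learn DBSCAN on random instances."""
    rng = np.random.default_rng(seed)
    n_fam = int(rng.integers(1, 4))
    fams = [random_dna(rng, 60) for _ in range(n_fam)]
    seqs = [
        mutate(rng, fams[int(rng.integers(0, n_fam))], int(rng.integers(0, 6)))
        for _ in range(int(rng.integers(8, 22)))
    ]
    eps = int(rng.integers(2, 8))
    min_pts = int(rng.integers(2, 5))
    table = pairwise_distances(seqs, limit=200)
    clusters, noise = dbscan_cluster(seqs, table, eps, min_pts)
    labels = _sklearn_labels(seqs, eps, min_pts)
    ref_clusters = {}
    ref_noise = {i for i, l in enumerate(labels) if l == -1}
    for i, l in enumerate(labels):
        if l != -1:
            ref_clusters.setdefault(l, set()).add(i)
    got = {frozenset(c.loop_indices) for c in clusters}
    assert got == {frozenset(v) for v in ref_clusters.values()}
    assert noise == ref_noise
    # conservation
    assert sum(len(c.loop_indices) for c in clusters) + len(noise) == len(seqs)


def test_dbscan_examples():
    seqs = ["ACGTACGTACGT"] * 6
    table = pairwise_distances(seqs, 10)
    clusters, noise = dbscan_cluster(seqs, table, 2, 5)
    assert len(clusters) == 1 and not noise

    two = ["A" * 60] * 10 + ["C" * 30 + "G" * 30] * 10
    table = pairwise_distances(two, 600)
    clusters, noise = dbscan_cluster(two, table, 5, 5)
    assert len(clusters) == 2 and not noise


@pytest.mark.parametrize("seed", range(6))
def test_higher_epsilon_is_coarser(seed):
    rng = np.random.default_rng(200 + seed)
    fams = [random_dna(rng, 80) for _ in range(3)]
    seqs = [
        mutate(rng, fams[int(rng.integers(0, 3))], int(rng.integers(0, 5)))
        for _ in range(20)
    ]
    table = pairwise_distances(seqs, limit=300)
    c1, _ = dbscan_cluster(seqs, table, 3, 3)
    c2, _ = dbscan_cluster(seqs, table, 9, 3)
    for small in c1:
        assert any(small.loop_indices <= big.loop_indices for big in c2)


def test_density_clusters_stay_within_rough_clusters(seed=0):
    rng = np.random.default_rng(seed)
    fams = [random_dna(rng, 100) for _ in range(3)]
    seqs = [
        mutate(rng, fams[int(rng.integers(0, 3))], int(rng.integers(0, 4)))
        for _ in range(24)
    ]
    table = pairwise_distances(seqs, limit=30)
    rough = rough_cluster(table, 30)
    clusters, _ = dbscan_cluster(seqs, table, 6, 3)
    rough_sets = [set(c) for c in rough]
    for c in clusters:
        assert any(c.loop_indices <= r for r in rough_sets)


def test_cluster_params_validation():
    from ribomorph.loops_cluster import ClusterParams

    ClusterParams(max_rough_diff=10, min_epsilon=1)  # the HiFi-only defaults
    with pytest.raises(ValueError):
        ClusterParams(max_rough_diff=10, min_epsilon=0)
    with pytest.raises(ValueError):
        ClusterParams(max_rough_diff=2, min_epsilon=5)
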