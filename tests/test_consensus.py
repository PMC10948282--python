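import edlib
import numpy as np
import pytest

from ribomorph.allele_graph import build_allele_graph, clean_graph
from ribomorph.consensus import genome_wide_consensus, medoid, polish
from ribomorph.formats import SequenceRecord
from ribomorph.loops_cluster import pairwise_distances, select_anchor_node
from ribomorph.recruit import revcomp
from ribomorph.simulate import ONT_PROFILE, ReadProfile, _inject_errors

from conftest import random_dna


def test_medoid_examples():
    table = pairwise_distances(["AAAA", "AAAA", "AAAA"], 10)
    assert medoid([0, 1, 2], table) == 0
    table = pairwise_distances(["A" * 20, "A" * 20, "C" * 20], 40)
    assert medoid([0, 1, 2], table) == 0  # an 'A', lowest index


@pytest.mark.parametrize("seed", range(4))
def test_medoid_equals_bruteforce(seed):
    rng = np.random.default_rng(seed)
    base = random_dna(rng, 100)
    seqs = []
    for _ in range(9):
        s = list(base)
        for p in rng.integers(0, len(s), int(rng.integers(0, 8))):
            s[p] = "ACGT"[int(rng.integers(0, 4))]
        seqs.append("".join(s))
    table = pairwise_distances(seqs, limit=300)
    totals = [
        sum(
            edlib.align(seqs[i], seqs[j], mode="NW")["editDistance"]
            for j in range(len(seqs))
            if j != i
        )
        for i in range(len(seqs))
    ]
    oracle = min(range(len(seqs)), key=lambda i: (totals[i], i))
    assert medoid(list(range(len(seqs))), table) == oracle


def test_polish_fixed_point_and_idempotence():
    seq = "ACGTACGTGGTCAA" * 20
    assert polish(seq, [seq] * 5) == seq
    rng = np.random.default_rng(0)
    noisy = [
        _inject_errors(rng, seq, ReadProfile(100, 0.1, 0.02, 0.01, 0.01))
        for _ in range(15)
    ]
    once = polish(seq, noisy)
    assert polish(once, noisy) == once


def test_polish_recovers_truth_from_noisy_loops():
    """Truth + 20 loops at ~5% error: consensus within 0.1% in >=19/20 trials."""
    ok = 0
    for trial in range(20):
        rng = np.random.default_rng(1000 + trial)
        truth = random_dna(rng, 2000)
        loops = [_inject_errors(rng, truth, ONT_PROFILE) for _ in range(20)]
        seed = loops[0]
        cons = polish(seed, loops, max_rounds=8)
        d = edlib.align(cons, truth, mode="NW")["editDistance"]
        if d <= 0.001 * len(truth):
            ok += 1
    assert ok >= 19


def test_genome_wide_consensus_single_morph(single_morph_setup):
    unit, _, _, hifi, _ = single_morph_setup
    g = clean_graph(build_allele_graph(hifi, k=31, solid_min=3), 3, 150)
    anchor = select_anchor_node(g)
    cons = genome_wide_consensus(g, anchor, len(unit))
    assert len(cons) == len(unit)
    assert cons in unit + unit or revcomp(cons) in unit + unit


def test_genome_wide_consensus_follows_heaviest_edges(small_pipeline_result):
    config, _, result = small_pipeline_result
    g = result.graph
    anchor = result.anchor
    cons = genome_wide_consensus(g, anchor, config.approx_morph_size)
    # replay: from the anchor, each step must take the max-coverage successor
    cur = (anchor, "+")
    walk = [cur]
    while True:
        succs = g.successors(*cur)
        assert succs
        nxt = min(succs, key=lambda t: (-t[2], t[0], t[1]))
        cur = (nxt[0], nxt[1])
        walk.append(cur)
        if nxt[0] == anchor or sum(
            g.nodes[n].expanded_length for n, _ in walk
        ) > 2 * config.approx_morph_size:
            break
    replay, starts = g.walk_sequence(walk)
    if walk[-1][0] == anchor:
        replay = replay[: starts[-1]]
    else:
        replay = replay[: 2 * config.approx_morph_size]
    assert cons == replay


def _paired_snp_fixture():
    """Two morphs with paired SNP alleles; skewed local coverage makes the
    heaviest walk combine alleles that co-occur in no real unit."""
    rng = np.random.default_rng(42)
    f1, f2, f3 = (random_dna(rng, 700) for _ in range(3))
    a1, b1 = "A", "T"
    a2 = "C" if f2[0] != "C" else "G"
    b2 = "G" if f3[0] != "G" else "C"
    morph_a = f1 + a1 + f2 + b1 + f3
    morph_b = f1 + a2 + f2 + b2 + f3
    array_seq = (morph_a + morph_b) * 6
    reads = [array_seq[i : i + 3000] for i in range(0, len(array_seq) - 3000, 150)]
    # skewed local evidence: bubble 1 favours morph A's allele, bubble 2
    # favours morph B's, so the heaviest walk must cross morphs
    boost = [morph_a[500:1000]] * 30 + [morph_b[1100:1700]] * 30
    return morph_a, morph_b, reads + boost


def test_genome_wide_consensus_can_be_a_mosaic():
    """The heaviest walk may pick allele pairings absent from every unit."""
    morph_a, morph_b, reads = _paired_snp_fixture()
    g = clean_graph(build_allele_graph(reads, k=31, solid_min=3), 3, 150)
    anchor = select_anchor_node(g)
    cons = genome_wide_consensus(g, anchor, len(morph_a))
    def exact(morph):
        doubled = morph + morph
        return cons in doubled or revcomp(cons) in doubled
    assert not exact(morph_a) and not exact(morph_b)
    # yet the consensus is close to both: every allele it picked exists
    da = edlib.align(cons, morph_a + morph_a, mode="HW")["editDistance"]
    db = edlib.align(cons, morph_b + morph_b, mode="HW")["editDistance"]
    assert 0 < da <= 2 and 0 < db <= 2


def test_morph_output_order_and_conservation(small_pipeline_result):
    _, _, result = small_pipeline_result
    covs = [m.coverage for m in result.morphs]
    assert covs == sorted(covs, reverse=True)
    clustered = sum(len(c.loop_indices) for c in result.clusters)
    assert sum(covs) == clustered
    assert clustered + len(result.noise) == len(result.loops)
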