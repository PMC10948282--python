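import edlib
import numpy as np
import pytest

from ribomorph.simulate import (
    HIFI_PROFILE,
    ReadProfile,
    SimParams,
    SimulatedArray,
    build_array,
    generate_morphs,
    generate_source_panel,
    simulate_reads,
)


def pairwise_divergence(seqs):
    ds = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = edlib.align(seqs[i], seqs[j], mode="NW")["editDistance"]
            ds.append(2 * d / (len(seqs[i]) + len(seqs[j])))
    return float(np.mean(ds))


def test_zero_divergence_panel_is_identical():
    params = SimParams(
        n_sources=3, morph_length=1000, n_morphs=2, mosaic_divergence=0.0, seed=1
    )
    panel = generate_source_panel(params)
    assert len(set(panel)) == 1


def test_panel_divergence_hits_target():
    # two sources, pairwise target 0.05 (mosaic target x n/(n-1) = 0.05)
    params = SimParams(
        n_sources=2, morph_length=1000, n_morphs=2, mosaic_divergence=0.025, seed=2
    )
    panel = generate_source_panel(params)
    assert 0.04 <= pairwise_divergence(panel) <= 0.06


def test_panel_is_deterministic():
    params = SimParams(n_sources=3, morph_length=800, n_morphs=2, seed=7)
    assert list(generate_source_panel(params)) == list(generate_source_panel(params))


def test_morph_without_switches_or_mutations_is_a_source():
    params = SimParams(
        n_sources=3,
        morph_length=900,
        n_morphs=4,
        mutation_rate=0.0,
        mean_breakpoints=0.0,
        seed=3,
    )
    panel = generate_source_panel(params)
    for m in generate_morphs(panel, params):
        assert m.sequence in list(panel)
        assert len(m.source_segments) == 1


def test_segments_match_their_sources_before_mutation():
    params = SimParams(
        n_sources=4, morph_length=1200, n_morphs=5, mutation_rate=0.0, seed=4
    )
    panel = generate_source_panel(params)
    for m in generate_morphs(panel, params):
        rebuilt = 0
        for start, end, src in m.source_segments:
            assert m.sequence[start:end] in panel[src]
            rebuilt += end - start
        assert rebuilt == len(m.sequence)


def test_mutation_count_is_binomial():
    params = SimParams(
        n_sources=2,
        morph_length=20_000,
        n_morphs=6,
        mosaic_divergence=0.0,  # identical sources: edits vs source = mutations
        mutation_rate=0.002,
        seed=5,
    )
    panel = generate_source_panel(params)
    n, p = params.morph_length, params.mutation_rate
    sigma = np.sqrt(n * p * (1 - p))
    for m in generate_morphs(panel, params):
        d = edlib.align(m.sequence, panel[0], mode="NW")["editDistance"]
        assert abs(d - n * p) <= 3 * sigma


def test_array_is_a_shuffled_tiling():
    params = SimParams(n_sources=3, morph_length=600, n_morphs=3, seed=6)
    panel = generate_source_panel(params)
    morphs = generate_morphs(panel, params)
    array = build_array(morphs, seed=9)
    by_id = {m.morph_id: m for m in morphs}
    assert array.array_sequence == "".join(
        by_id[u].sequence for u in array.unit_order
    )
    from collections import Counter

    assert Counter(array.unit_order) == {m.morph_id: m.copy_count for m in morphs}
    assert len(array.array_sequence) == sum(
        m.copy_count * len(m.sequence) for m in morphs
    )


def _plain_array(rng, n):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    return SimulatedArray(seq, [], [])


def test_error_free_reads_are_exact_substrings():
    rng = np.random.default_rng(10)
    array = _plain_array(rng, 30_000)
    profile = ReadProfile(5000, 0.3, 0.0, 0.0, 0.0)
    reads = simulate_reads(array, profile, coverage=2, seed=1)
    for r in reads:
        origin = r.description.split()[0].split("=")[1]
        start, end = map(int, origin.split("-"))
        bases = r.bases
        if "strand=-" in r.description:
            from ribomorph.recruit import revcomp

            bases = revcomp(bases)
        assert bases == array.array_sequence[start:end]


def test_coverage_conservation():
    rng = np.random.default_rng(11)
    array = _plain_array(rng, 100_000)
    reads = simulate_reads(array, HIFI_PROFILE, coverage=10, seed=2)
    total = sum(len(r) for r in reads)
    assert 0.95e6 <= total <= 1.05e6


def test_substitution_rate_matches_profile():
    rng = np.random.default_rng(12)
    array = _plain_array(rng, 40_000)
    profile = ReadProfile(20_000, 0.01, 0.05, 0.0, 0.0)
    reads = simulate_reads(array, profile, coverage=1.5, seed=3)
    for r in reads[:3]:
        start, end = map(
            int, r.description.split()[0].split("=")[1].split("-")
        )
        bases = r.bases
        if "strand=-" in r.description:
            from ribomorph.recruit import revcomp

            bases = revcomp(bases)
        template = array.array_sequence[start:end]
        d = edlib.align(bases, template, mode="NW")["editDistance"]
        n = len(template)
        assert abs(d - 0.05 * n) <= 3 * np.sqrt(n * 0.05 * 0.95)


def test_reads_deterministic_under_seed():
    rng = np.random.default_rng(13)
    array = _plain_array(rng, 20_000)
    a = simulate_reads(array, HIFI_PROFILE, 2, seed=5)
    b = simulate_reads(array, HIFI_PROFILE, 2, seed=5)
    assert [(r.id, r.bases) for r in a] == [(r.id, r.bases) for r in b]


def test_truncation_warning_when_reads_longer_than_array():
    rng = np.random.default_rng(14)
    array = _plain_array(rng, 3_000)
    with pytest.warns(UserWarning, match="truncated"):
        simulate_reads(array, ReadProfile(10_000, 0.1, 0.0, 0.0, 0.0), 1, seed=0)


def test_morph_divergence_approximates_study_conditions():
    """Average morph divergence ~ mosaic + mutation contribution (4.4% +- 1pp)."""
    divs = []
    for seed in range(5):
        params = SimParams(
            n_sources=9, morph_length=3000, n_morphs=9, seed=seed
        )
        panel = generate_source_panel(params)
        morphs = generate_morphs(panel, params)
        divs.append(pairwise_divergence([m.sequence for m in morphs]))
    mean = float(np.mean(divs))
    assert abs(mean - 0.044) <= 0.01
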