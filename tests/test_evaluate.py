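import numpy as np
import pytest

from ribomorph.consensus import Morph
from ribomorph.evaluate import classify_errors, match_morphs, score_assembly
from ribomorph.recruit import revcomp
from ribomorph.simulate import MorphTruth

from conftest import random_dna


def _truth(mid, seq, copies):
    return MorphTruth(mid, seq, copies, [(0, len(seq), 0)])


def _pred(mid, seq, cov):
    return Morph(mid, seq, cov, 0, len(seq))


def substituted(rng, seq, n):
    """n substitutions at well-separated positions (edit distance == n)."""
    pos = rng.choice(np.arange(0, len(seq) - 3, 3), size=n, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = "ACGT"[("ACGT".index(s[p]) + 1) % 4]
    return "".join(s)


def test_identical_sequences_match():
    rng = np.random.default_rng(0)
    a = random_dna(rng, 5000)
    m = match_morphs(a, a)
    assert m.is_match and m.identity == 1.0 and m.cov_a == m.cov_b == 1.0


def test_rotation_invariance():
    rng = np.random.default_rng(1)
    a = random_dna(rng, 5000)
    rotated = a[1000:] + a[:1000]
    m = match_morphs(a, rotated)
    assert m.is_match and m.identity == 1.0


def test_strand_invariance():
    rng = np.random.default_rng(2)
    a = random_dna(rng, 4000)
    assert match_morphs(a, revcomp(a)).is_match


def test_match_boundary_at_one_percent():
    """45 kb pairs straddling the 99% identity threshold."""
    rng = np.random.default_rng(3)
    a = random_dna(rng, 45_000)
    far = substituted(rng, a, 600)  # ~1.3% divergence
    near = substituted(rng, a, 200)  # ~0.45%
    assert not match_morphs(a, far).is_match
    assert match_morphs(a, near).is_match


def test_coverage_gate():
    rng = np.random.default_rng(4)
    a = random_dna(rng, 5000)
    half = a[:2500]
    m = match_morphs(a, half)
    assert not m.is_match and m.cov_a <= 0.55


def test_is_match_symmetric_on_random_pairs():
    rng = np.random.default_rng(5)
    for _ in range(12):
        a = random_dna(rng, 1500)
        b = substituted(rng, a, int(rng.integers(0, 40)))
        if rng.random() < 0.3:
            b = b[: int(rng.integers(800, 1500))]
        assert match_morphs(a, b).is_match == match_morphs(b, a).is_match


def test_perfect_assembly_scores_perfectly():
    rng = np.random.default_rng(6)
    seqs = [random_dna(rng, 2000) for _ in range(4)]
    truth = [_truth(f"t{i}", s, i + 1) for i, s in enumerate(seqs)]
    preds = [_pred(f"p{i}", s, 10 * (i + 1)) for i, s in enumerate(seqs)]
    rep = score_assembly(truth, preds)
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    assert rep.pearson_r == pytest.approx(1.0)
    assert rep.mean_mismatches == 0.0


def test_empty_predictions():
    rng = np.random.default_rng(7)
    truth = [_truth("t", random_dna(rng, 1000), 3)]
    rep = score_assembly(truth, [])
    assert rep.sensitivity == 0.0
    assert rep.specificity is None
    assert rep.pearson_r is None


def test_pearson_from_known_pairs():
    """Truth copies (1,2,3) matched by coverages (3,5,9) give r = 0.982."""
    rng = np.random.default_rng(8)
    seqs = [random_dna(rng, 1500) for _ in range(3)]
    truth = [_truth(f"t{i}", s, c) for i, (s, c) in enumerate(zip(seqs, [1, 2, 3]))]
    preds = [_pred(f"p{i}", s, c) for i, (s, c) in enumerate(zip(seqs, [3, 5, 9]))]
    rep = score_assembly(truth, preds)
    assert rep.pearson_r == pytest.approx(0.982, abs=5e-4)


def test_score_assembly_permutation_invariant():
    rng = np.random.default_rng(9)
    seqs = [random_dna(rng, 1200) for _ in range(4)]
    truth = [_truth(f"t{i}", s, i + 1) for i, s in enumerate(seqs)]
    preds = [_pred(f"p{i}", substituted(rng, s, 3), 5 * (i + 1)) for i, s in enumerate(seqs)]
    a = score_assembly(truth, preds)
    b = score_assembly(truth[::-1], preds[::-1])
    assert a.sensitivity == b.sensitivity
    assert a.specificity == b.specificity
    assert a.pearson_r == pytest.approx(b.pearson_r)
    assert sorted(a.coverage_copy_pairs) == sorted(b.coverage_copy_pairs)


def test_abundance_filters():
    rng = np.random.default_rng(10)
    seqs = [random_dna(rng, 1500) for _ in range(3)]
    truth = [
        _truth("rare", seqs[0], 1),
        _truth("mid", seqs[1], 5),
        _truth("big", seqs[2], 9),
    ]
    preds = [_pred("p0", seqs[1], 40), _pred("p1", seqs[2], 60)]
    rep = score_assembly(truth, preds, min_truth_copies=5, min_pred_coverage=30)
    assert rep.sensitivity == 1.0  # the copy-1 morph is excluded by the filter
    assert rep.n_truth == 2 and rep.n_predicted == 2


def test_classify_errors_examples():
    assert classify_errors("AAAA", "AAA") == {
        "homopolymer_indel": 1.0,
        "microsatellite_indel": 0.0,
        "other": 0.0,
    }
    assert classify_errors("ACACAC", "ACAC")["microsatellite_indel"] == 1.0
    ref = "ACGTACGTAA"
    alt = ref[:4] + "C" + ref[5:]
    assert classify_errors(ref, alt)["other"] == 1.0


def test_classify_errors_fractions_sum_to_one():
    rng = np.random.default_rng(11)
    ref = random_dna(rng, 500)
    alt = substituted(rng, ref, 7)
    alt = alt[:100] + alt[101:]  # plus one deletion
    fr = classify_errors(ref, alt)
    assert sum(fr.values()) == pytest.approx(1.0)


def test_classify_errors_no_edits():
    fr = classify_errors("ACGT", "ACGT")
    assert sum(fr.values()) == 0.0
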