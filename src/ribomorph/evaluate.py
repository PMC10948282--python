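"""Comparison metrics for assembled morphs against a ground truth.

Two morphs *match* when they align with at least 99% identity over at least
99% of both sequences.  Assembled loops and truth morphs start at arbitrary
origins within the repeat unit, so matching is rotation-aware: each sequence
is aligned (semi-global) into the other's doubled sequence and the better
direction supplies the identity, while each direction supplies the aligned
coverage of its target.  From the pairwise matches the study metrics follow:
sensitivity (truth morphs recovered), specificity (predictions that are
real, i.e. precision), the Pearson correlation between predicted coverage
and truth copy count, the mean mismatch count of matched pairs, and a
breakdown of consensus errors into homopolymer indels, microsatellite
indels and everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .consensus import Morph, _cigar_ops
from .recruit import revcomp
from .simulate import MorphTruth

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_morphs",
    "score_assembly",
    "classify_errors",
]

MATCH_IDENTITY = 0.99
MATCH_COVERAGE = 0.99
_EPS = 1e-12


@dataclass
class MatchResult:
    identity: float
    cov_a: float
    cov_b: float
    is_match: bool
    edits: int = 0


def _directional(query: str, target: str) -> Tuple[float, int, int, Optional[tuple]]:
    """Align query into target+target; identity, edits and span on target."""
    doubled = target + target
    res = edlib.align(query, doubled, mode="HW", task="locations")
    d = res["editDistance"]
    start, end = res["locations"][0]
    span = end - start + 1
    identity = 1.0 - d / max(len(query), span)
    return identity, d, min(span, len(target)), (start, end)


def match_morphs(a: str, b: str) -> MatchResult:
    """Rotation- and strand-aware match of two repeat-unit sequences.

    ``b`` (or its reverse complement, whichever aligns better) is aligned
    into the doubled ``a`` — absorbing origin differences — and vice versa;
    the better direction gives the identity, and the aligned span in each
    direction gives that sequence's coverage.  Symmetric in ``is_match``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    b_oriented = b
    rc = revcomp(b)
    if (
        edlib.align(rc, a + a, mode="HW", task="distance")["editDistance"]
        < edlib.align(b, a + a, mode="HW", task="distance")["editDistance"]
    ):
        b_oriented = rc
    id_ab, d_ab, span_a, _ = _directional(b_oriented, a)
    id_ba, d_ba, span_b, _ = _directional(a, b_oriented)
    identity = max(id_ab, id_ba)
    edits = d_ab if id_ab >= id_ba else d_ba
    cov_a = span_a / len(a)
    cov_b = span_b / len(b)
    return MatchResult(
        identity=identity,
        cov_a=cov_a,
        cov_b=cov_b,
        is_match=(
            identity >= MATCH_IDENTITY - _EPS
            and cov_a >= MATCH_COVERAGE - _EPS
            and cov_b >= MATCH_COVERAGE - _EPS
        ),
        edits=edits,
    )


@dataclass
class EvalReport:
    sensitivity: float
    specificity: Optional[float]
    pearson_r: Optional[float]
    mean_mismatches: Optional[float]
    error_fractions: Dict[str, float] = field(default_factory=dict)
    n_truth: int = 0
    n_predicted: int = 0
    matched_pairs: List[Tuple[str, str, float]] = field(default_factory=list)
    coverage_copy_pairs: List[Tuple[int, int]] = field(default_factory=list)


def score_assembly(
    truth: Sequence[MorphTruth],
    predicted: Sequence[Morph],
    min_truth_copies: int = 1,
    min_pred_coverage: int = 1,
) -> EvalReport:
    """Score predictions against ground truth under the 99%/99% criterion.

    Sensitivity is the fraction of truth morphs (copy count at or above
    ``min_truth_copies``) matched by at least one prediction; specificity is
    the fraction of predictions (coverage at or above ``min_pred_coverage``)
    matching at least one truth morph.  Matching is many-to-many.  Pearson r
    is computed over best-match pairs (prediction coverage vs truth copy
    count, best match per truth morph) and reported absent with fewer than 3
    pairs (or degenerate variance).  With zero eligible predictions the
    specificity is reported absent.
    """
    matches: Dict[Tuple[int, int], MatchResult] = {}
    for ti, t in enumerate(truth):
        for pi, p in enumerate(predicted):
            matches[(ti, pi)] = match_morphs(t.sequence, p.sequence)

    truth_idx = [i for i, t in enumerate(truth) if t.copy_count >= min_truth_copies]
    pred_idx = [
        j for j, p in enumerate(predicted) if p.coverage >= min_pred_coverage
    ]
    matched_truth = [
        i for i in truth_idx if any(matches[(i, j)].is_match for j in range(len(predicted)))
    ]
    sensitivity = len(matched_truth) / len(truth_idx) if truth_idx else 0.0
    if pred_idx:
        matched_pred = [
            j for j in pred_idx if any(matches[(i, j)].is_match for i in range(len(truth)))
        ]
        specificity = len(matched_pred) / len(pred_idx)
    else:
        specificity = None

    pairs: List[Tuple[int, int]] = []  # (coverage, copy count) of best matches
    match_rows: List[Tuple[str, str, float]] = []
    edits_list: List[int] = []
    err_counts = {"homopolymer_indel": 0, "microsatellite_indel": 0, "other": 0}
    for i in range(len(truth)):
        cands = [
            (j, matches[(i, j)])
            for j in range(len(predicted))
            if matches[(i, j)].is_match
        ]
        if not cands:
            continue
        cands.sort(
            key=lambda t: (
                -t[1].identity,
                -predicted[t[0]].coverage,
                predicted[t[0]].sequence,
            )
        )
        j, mr = cands[0]
        pairs.append((predicted[j].coverage, truth[i].copy_count))
        match_rows.append((truth[i].morph_id, predicted[j].morph_id, mr.identity))
        edits_list.append(mr.edits)
        for kind, cnt in _best_match_error_counts(
            truth[i].sequence, predicted[j].sequence
        ).items():
            err_counts[kind] += cnt

    pearson = None
    if len(pairs) >= 3:
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        if x.std() > 0 and y.std() > 0:
            pearson = float(np.corrcoef(x, y)[0, 1])
    total_err = sum(err_counts.values())
    fractions = (
        {k: v / total_err for k, v in err_counts.items()}
        if total_err
        else {k: 0.0 for k in err_counts}
    )
    return EvalReport(
        sensitivity=sensitivity,
        specificity=specificity,
        pearson_r=pearson,
        mean_mismatches=float(np.mean(edits_list)) if edits_list else None,
        error_fractions=fractions,
        n_truth=len(truth_idx),
        n_predicted=len(pred_idx),
        matched_pairs=match_rows,
        coverage_copy_pairs=pairs,
    )


def _best_match_error_counts(truth_seq: str, pred_seq: str) -> Dict[str, int]:
    """Edit-class counts from the rotation/strand-resolved alignment of a match."""
    doubled = truth_seq + truth_seq
    rc = revcomp(pred_seq)
    if (
        edlib.align(rc, doubled, mode="HW", task="distance")["editDistance"]
        < edlib.align(pred_seq, doubled, mode="HW", task="distance")["editDistance"]
    ):
        pred_seq = rc
    res = edlib.align(pred_seq, doubled, mode="HW", task="path")
    start, end = res["locations"][0]
    window = doubled[start : end + 1]
    return classify_errors(window, pred_seq, res["cigar"], fractions=False)


def classify_errors(
    ref: str,
    query: str,
    cigar: Optional[str] = None,
    fractions: bool = True,
):
    """Label every edit of an alignment trace.

    ``homopolymer_indel``: a single-base indel whose base equals an adjacent
    base (a run of >= 2 in either sequence).  ``microsatellite_indel``: an
    indel that is a whole number of copies of a 2-6 bp motif with at least
    one adjacent copy of the motif in either sequence.  Everything else —
    all substitutions included — is ``other``.  Each edited base counts as
    one edit; indel events are labelled as a unit.
    """
    if cigar is None:
        cigar = edlib.align(query, ref, mode="NW", task="path")["cigar"]
    counts = {"homopolymer_indel": 0, "microsatellite_indel": 0, "other": 0}
    t = q = 0
    for n, op in _cigar_ops(cigar):
        if op in "=M":
            t += n
            q += n
        elif op == "X":
            counts["other"] += n
            t += n
            q += n
        elif op == "D":  # present in ref, absent from query
            seq = ref[t : t + n]
            counts[_indel_class(seq, ref, t, t + n, query, q, q)] += n
            t += n
        elif op == "I":  # present in query, absent from ref
            seq = query[q : q + n]
            counts[_indel_class(seq, query, q, q + n, ref, t, t)] += n
            q += n
    if not fractions:
        return counts
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}


def _indel_class(
    seq: str,
    host: str,
    h_lo: int,
    h_hi: int,
    other: str,
    o_lo: int,
    o_hi: int,
) -> str:
    """Classify one indel event given its flanking context in both sequences."""
    n = len(seq)
    if n == 1:
        b = seq
        neighbours = [
            host[h_lo - 1 : h_lo],
            host[h_hi : h_hi + 1],
            other[o_lo - 1 : o_lo],
            other[o_hi : o_hi + 1],
        ]
        if b in neighbours:
            return "homopolymer_indel"
    for mlen in range(2, 7):
        if n % mlen != 0:
            continue
        motif = seq[:mlen]
        if motif * (n // mlen) != seq:
            continue
        contexts = [
            host[h_lo - mlen : h_lo],
            host[h_hi : h_hi + mlen],
            other[o_lo - mlen : o_lo],
            other[o_hi : o_hi + mlen],
        ]
        if motif in contexts:
            return "microsatellite_indel"
    return "other"
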