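"""Canonical k-mer indexing and read recruitment.

A reference repeat sequence (or the expanded node sequences of an allele
graph) is indexed by its canonical k-mers — the lexicographic minimum of a
k-mer and its reverse complement — and a read is recruited when the fraction
of its canonical k-mers found in the index reaches a threshold.  Accurate
reads are recruited against the reference; noisy ultralong reads are
recruited against the allele graph's k-mers with a lower threshold because
sequencing errors break exact k-mer sharing.

k-mers over windows containing N are skipped.  For k <= 31 the k-mers are
packed into 2-bit-per-base uint64 codes and all scanning is vectorised with
numpy; larger k falls back to string k-mers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .formats import SequenceRecord

__all__ = [
    "KmerIndex",
    "RecruitDecision",
    "build_kmer_index",
    "recruit_reads",
    "canonical_kmer_codes",
    "encode_bases",
    "revcomp",
    "code_to_kmer",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_DECODE = "ACGT"

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_RC)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map a base string to uint8 codes (A=0 C=1 G=2 T=3, other=255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(vals: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward, reverse-complement codes and validity mask for every window."""
    n = len(vals)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rc = np.zeros(m, dtype=np.uint64)
    clean = np.where(vals == 255, 0, vals).astype(np.uint64)
    comp = (3 - clean) & np.uint64(3)
    for j in range(k):
        fwd |= clean[j : j + m] << np.uint64(2 * (k - 1 - j))
        rc |= comp[j : j + m] << np.uint64(2 * j)
    bad = (vals == 255).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    return fwd, rc, valid


def canonical_kmer_codes(seq: str, k: int, return_strand: bool = False):
    """Canonical (min of strand pair) uint64 codes of all valid k-mers.

    With ``return_strand`` also returns the window start positions and a
    boolean array that is True where the forward k-mer is the canonical one.
    """
    if k > 31:
        raise ValueError("packed k-mer codes support k <= 31")
    if len(seq) < k:
        empty = np.empty(0, dtype=np.uint64)
        if return_strand:
            return empty, np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
        return empty
    vals = encode_bases(seq)
    fwd, rc, valid = _window_codes(vals, k)
    canon = np.minimum(fwd, rc)
    if return_strand:
        pos = np.nonzero(valid)[0]
        return canon[valid], pos, (fwd <= rc)[valid]
    return canon[valid]


def code_to_kmer(code: int, k: int) -> str:
    """Decode a packed uint64 code back to the k-mer string."""
    out = []
    for j in range(k):
        out.append(_DECODE[(int(code) >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


def _canonical_kmer_strings(seq: str, k: int) -> List[str]:
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        out.append(min(w, revcomp(w)))
    return out


@dataclass
class KmerIndex:
    """Set of canonical k-mers, stored as a sorted packed-code array for k<=31."""

    k: int
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))
    strings: frozenset = frozenset()  # used only when k > 31

    def __len__(self) -> int:
        return len(self.codes) if self.k <= 31 else len(self.strings)

    @property
    def members(self) -> set:
        """Canonical k-mers as strings (convenience; O(index size))."""
        if self.k > 31:
            return set(self.strings)
        return {code_to_kmer(c, self.k) for c in self.codes}

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.codes, codes)
        idx = np.minimum(idx, max(len(self.codes) - 1, 0))
        if len(self.codes) == 0:
            return np.zeros(len(codes), dtype=bool)
        return self.codes[idx] == codes

    def matched_fraction(self, seq: str) -> float:
        if self.k <= 31:
            codes = canonical_kmer_codes(seq, self.k)
            if len(codes) == 0:
                return 0.0
            return float(self.contains_codes(codes).mean())
        kmers = _canonical_kmer_strings(seq, self.k)
        if not kmers:
            return 0.0
        return sum(km in self.strings for km in kmers) / len(kmers)


@dataclass
class RecruitDecision:
    read_id: str
    matched_fraction: float
    recruited: bool


def build_kmer_index(
    sequences: Iterable[SequenceRecord | str], k: int
) -> KmerIndex:
    """Index the canonical k-mers of the input sequences.

    ``k`` must be odd (so no k-mer is its own reverse complement) and within
    [11, 63].  Windows containing N are skipped.
    """
    if k % 2 == 0 or not (11 <= k <= 63):
        raise ValueError("k must be odd and within [11, 63]")
    seqs = [s.bases if isinstance(s, SequenceRecord) else s for s in sequences]
    if k <= 31:
        parts = [canonical_kmer_codes(s, k) for s in seqs]
        codes = (
            np.unique(np.concatenate(parts))
            if parts
            else np.empty(0, dtype=np.uint64)
        )
        if len(codes) == 0:
            warnings.warn("no k-mers indexed (all sequences shorter than k?)")
        return KmerIndex(k=k, codes=codes)
    members = set()
    for s in seqs:
        members.update(_canonical_kmer_strings(s, k))
    if not members:
        warnings.warn("no k-mers indexed (all sequences shorter than k?)")
    return KmerIndex(k=k, strings=frozenset(members))


def recruit_reads(
    reads: Sequence[SequenceRecord],
    index: KmerIndex,
    min_fraction: float,
) -> Tuple[List[SequenceRecord], List[RecruitDecision]]:
    """Select reads sharing at least ``min_fraction`` of their k-mers with the index.

    Reads shorter than k are never recruited.  Deterministic and
    order-independent: each decision depends only on the read and the index.
    """
    selected: List[SequenceRecord] = []
    decisions: List[RecruitDecision] = []
    for read in reads:
        frac = index.matched_fraction(read.bases)
        ok = len(read.bases) >= index.k and frac >= min_fraction
        decisions.append(RecruitDecision(read.id, frac, ok))
        if ok:
            selected.append(read)
    return selected, decisions
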