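"""Synthetic rDNA arrays with known morph truth, plus long-read simulation.

The generator emulates the structure of eukaryotic rDNA repeats: a panel of
divergent *source* units is built around a common ancestor — with a conserved
core (standing in for the transcribed 18S/5.8S/28S block, where real units
are nearly identical) and a divergent spacer that carries most of the
variation, including short indels and an embedded microsatellite — and each
*morph* is a mosaic of the sources (switching source at random breakpoints)
plus additional random point mutations.  Morphs are tiled into a tandem
array according to drawn copy counts, and HiFi-like and ONT-like reads are
sampled from the array with platform-typical lengths and error profiles.

Every operation takes an explicit seed and uses a single numpy Generator
stream, so outputs are reproducible across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .formats import SequenceRecord
from .recruit import revcomp

__all__ = [
    "SimParams",
    "MorphTruth",
    "SimulatedArray",
    "ReadProfile",
    "SourcePanel",
    "HIFI_PROFILE",
    "ONT_PROFILE",
    "generate_source_panel",
    "generate_morphs",
    "build_array",
    "simulate_reads",
    "simulate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimParams:
    """Study conditions for one simulated rDNA array."""

    n_sources: int = 9
    morph_length: int = 45_000
    n_morphs: int = 9
    mosaic_divergence: float = 0.042  # pairwise divergence contributed by mosaics
    mutation_rate: float = 0.002  # additional random per-base mutations
    copy_count_law: tuple = ("geometric", 0.25, 1, 30)
    seed: int = 0
    conserved_fraction: float = 0.35  # core block with near-zero divergence
    conserved_divergence: float = 0.004  # pairwise divergence inside the core
    mean_breakpoints: float = 3.0  # Poisson mean of mosaic switch events

    def __post_init__(self) -> None:
        if not (0 <= self.mosaic_divergence < 1 and 0 <= self.mutation_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.morph_length < 200:
            raise ValueError("morph_length must be >= 200")
        if self.n_sources < 2:
            raise ValueError("n_sources must be >= 2")


@dataclass
class MorphTruth:
    """Ground-truth morph: sequence, copy count and its mosaic composition."""

    morph_id: str
    sequence: str
    copy_count: int
    source_segments: List[Tuple[int, int, int]]  # (start, end, source) half-open

    def __post_init__(self) -> None:
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")
        pos = 0
        for start, end, _ in self.source_segments:
            if start != pos:
                raise ValueError("source segments must tile the morph")
            pos = end
        if self.source_segments and pos != len(self.sequence):
            raise ValueError("source segments must tile the morph")


@dataclass
class SimulatedArray:
    array_sequence: str
    morphs: List[MorphTruth]
    unit_order: List[str]


@dataclass
class ReadProfile:
    """Length and error model of a sequencing platform."""

    mean_length: float
    length_sigma: float  # sigma of the lognormal length law
    sub_rate: float
    ins_rate: float
    del_rate: float
    homopolymer_indel_weight: float = 1.0  # indel multiplier inside runs >= 3

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")
        if self.mean_length <= 0:
            raise ValueError("mean_length must be positive")


# Platform-typical defaults: HiFi ~18 kb at 0.2% error, ultralong ONT ~60 kb
# with a heavy length tail at ~5% error and homopolymer-biased indels.
HIFI_PROFILE = ReadProfile(18_000, 0.25, 0.0010, 0.0005, 0.0005, 1.0)
ONT_PROFILE = ReadProfile(60_000, 0.60, 0.025, 0.012, 0.013, 1.5)


class SourcePanel(list):
    """List of source sequences plus their ancestor-aligned block forms."""

    def __init__(self, seqs: Sequence[str], blocks: List[List[str]], ancestor: str):
        super().__init__(seqs)
        self.blocks = blocks
        self.ancestor = ancestor


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _mutate_blocks(
    rng: np.random.Generator,
    ancestor: str,
    positions: np.ndarray,
    indel_fraction: float,
    max_indel: int = 10,
) -> List[str]:
    """Per-ancestor-position block strings after mutating at ``positions``."""
    blocks = list(ancestor)
    for p in positions:
        p = int(p)
        r = rng.random()
        if r >= indel_fraction:  # substitution
            old = blocks[p][-1] if blocks[p] else ancestor[p]
            choices = [b for b in "ACGT" if b != old]
            repl = choices[rng.integers(0, 3)]
            blocks[p] = (blocks[p][:-1] + repl) if blocks[p] else repl
        elif r >= indel_fraction / 2:  # insertion after p
            ins = _random_bases(rng, int(rng.integers(1, max_indel + 1)))
            blocks[p] = blocks[p] + ins.tobytes().decode()
        else:  # deletion of up to max_indel ancestor positions
            ln = int(rng.integers(1, max_indel + 1))
            for q in range(p, min(p + ln, len(blocks))):
                blocks[q] = ""
    return blocks


def _pairwise_divergence(seqs: Sequence[str]) -> float:
    import edlib

    dists = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")[
                "editDistance"
            ]
            dists.append(2 * d / (len(seqs[i]) + len(seqs[j])))
    return float(np.mean(dists)) if dists else 0.0


def generate_source_panel(params: SimParams) -> SourcePanel:
    """Generate ``n_sources`` divergent source units around one ancestor.

    The panel's average pairwise divergence is calibrated so that random
    mosaics of the panel differ by ``mosaic_divergence`` on average (two
    mosaics use the same source at a fraction 1/n_sources of positions).
    Divergence is concentrated in the spacer; the conserved core diverges at
    ``conserved_divergence``.  Sources carry SNPs and 1-10 bp indels, and the
    ancestor embeds a tandem-motif (microsatellite) region in the spacer.
    """
    rng = np.random.default_rng(params.seed)
    L = params.morph_length
    core_len = int(round(params.conserved_fraction * L))
    ancestor_arr = _random_bases(rng, L)
    # embed a microsatellite in the spacer so repeat-motif variation exists
    motif = _random_bases(rng, 4)
    ms_copies = 15
    ms_start = core_len + (L - core_len) // 3
    ms = np.tile(motif, ms_copies)
    ancestor_arr[ms_start : ms_start + len(ms)] = ms[: max(0, L - ms_start)]
    ancestor = ancestor_arr.tobytes().decode()

    pair_target = (
        params.mosaic_divergence * params.n_sources / (params.n_sources - 1)
    )
    if pair_target == 0:
        return SourcePanel(
            [ancestor] * params.n_sources,
            [list(ancestor) for _ in range(params.n_sources)],
            ancestor,
        )

    m_total = pair_target / 2  # per-source mutation rate vs ancestor
    m_core = min(params.conserved_divergence / 2, m_total)
    f = params.conserved_fraction
    m_var = (m_total - f * m_core) / (1 - f)
    scale = 1.0
    for _ in range(4):
        seqs: List[str] = []
        blocks_all: List[List[str]] = []
        for s in range(params.n_sources):
            n_core = rng.binomial(core_len, min(1.0, scale * m_core))
            n_var = rng.binomial(L - core_len, min(1.0, scale * m_var))
            pos = np.concatenate(
                [
                    rng.choice(core_len, size=min(n_core, core_len), replace=False),
                    core_len
                    + rng.choice(
                        L - core_len, size=min(n_var, L - core_len), replace=False
                    ),
                ]
            )
            blocks = _mutate_blocks(rng, ancestor, pos, indel_fraction=0.1)
            blocks_all.append(blocks)
            seqs.append("".join(blocks))
        measured = _pairwise_divergence(seqs)
        if abs(measured - pair_target) <= 0.2 * pair_target:
            return SourcePanel(seqs, blocks_all, ancestor)
        if measured <= 0:
            break
        scale *= pair_target / measured
    raise ValueError(
        f"could not reach panel divergence target {pair_target:.4f} "
        f"(measured {measured:.4f})"
    )


def generate_morphs(panel: Sequence[str], params: SimParams) -> List[MorphTruth]:
    """Mosaic morphs from the panel plus random mutations.

    Each morph switches among sources at Poisson-many uniformly placed
    breakpoints (in ancestor coordinates), then receives point mutations at
    ``mutation_rate`` (80% substitutions, 20% single-base indels).  Copy
    counts are drawn from ``copy_count_law``.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    rng = np.random.default_rng(params.seed + 1)
    if isinstance(panel, SourcePanel):
        blocks_all = panel.blocks
        anc_len = len(panel.ancestor)
    else:
        lens = {len(s) for s in panel}
        if len(lens) != 1:
            raise ValueError("a plain panel must have equal-length sources")
        blocks_all = [list(s) for s in panel]
        anc_len = len(panel[0])

    morphs: List[MorphTruth] = []
    for mi in range(params.n_morphs):
        nb = int(rng.poisson(params.mean_breakpoints))
        cuts = sorted(int(c) for c in rng.integers(1, anc_len, size=nb))
        bounds = [0] + cuts + [anc_len]
        pieces: List[str] = []
        segments: List[Tuple[int, int, int]] = []
        pos = 0
        for lo, hi in zip(bounds, bounds[1:]):
            if hi <= lo:
                continue
            src = int(rng.integers(0, len(blocks_all)))
            piece = "".join(blocks_all[src][lo:hi])
            if not piece:
                continue
            pieces.append(piece)
            segments.append((pos, pos + len(piece), src))
            pos += len(piece)
        seq = "".join(pieces)

        # random point mutations on top of the mosaic
        n_mut = rng.binomial(len(seq), params.mutation_rate)
        mut_pos = np.sort(
            rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
        )
        chars = list(seq)
        for p in mut_pos:
            p = int(p)
            r = rng.random()
            if r < 0.8:
                choices = [b for b in "ACGT" if b != chars[p][-1:]]
                chars[p] = chars[p][:-1] + choices[rng.integers(0, 3)]
            elif r < 0.9:
                ins = "ACGT"[rng.integers(0, 4)]
                chars[p] = chars[p] + ins
            else:
                chars[p] = chars[p][:-1] if len(chars[p]) > 1 else ""
        lens_per_pos = np.fromiter((len(c) for c in chars), dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(lens_per_pos)])
        new_segments = [
            (int(cum[s]), int(cum[e]), src) for s, e, src in segments
        ]
        new_segments = [(s, e, src) for s, e, src in new_segments if e > s]
        morphs.append(
            MorphTruth(
                morph_id=f"truth_{mi}",
                sequence="".join(chars),
                copy_count=_draw_copies(rng, params.copy_count_law),
                source_segments=new_segments,
            )
        )
    return morphs


def _draw_copies(rng: np.random.Generator, law: tuple) -> int:
    kind = law[0]
    if kind == "geometric":
        _, p, lo, hi = law
        while True:
            c = int(rng.geometric(p))
            if lo <= c <= hi:
                return c
    if kind == "uniform":
        _, lo, hi = law
        return int(rng.integers(lo, hi + 1))
    if kind == "fixed":
        return int(law[1])
    raise ValueError(f"unknown copy count law {law!r}")


def build_array(morphs: Sequence[MorphTruth], seed: int) -> SimulatedArray:
    """Tandem array: uniformly shuffled multiset of morph copies."""
    if any(m.copy_count < 1 for m in morphs):
        raise ValueError("all copy counts must be >= 1")
    rng = np.random.default_rng(seed)
    units = [m.morph_id for m in morphs for _ in range(m.copy_count)]
    order = [units[i] for i in rng.permutation(len(units))]
    by_id = {m.morph_id: m for m in morphs}
    return SimulatedArray(
        array_sequence="".join(by_id[u].sequence for u in order),
        morphs=list(morphs),
        unit_order=order,
    )


def _run_lengths_per_pos(vals: np.ndarray) -> np.ndarray:
    """Homopolymer run length at each position."""
    n = len(vals)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    new_run = np.empty(n, dtype=bool)
    new_run[0] = True
    np.not_equal(vals[1:], vals[:-1], out=new_run[1:])
    run_id = np.cumsum(new_run) - 1
    lengths = np.bincount(run_id)
    return lengths[run_id]


def _inject_errors(
    rng: np.random.Generator, template: str, profile: ReadProfile
) -> str:
    from .recruit import encode_bases

    vals = encode_bases(template).astype(np.int64)
    n = len(vals)
    sub = rng.random(n) < profile.sub_rate
    vals[sub] = (vals[sub] + rng.integers(1, 4, int(sub.sum()))) % 4
    w = np.where(
        _run_lengths_per_pos(vals) >= 3, profile.homopolymer_indel_weight, 1.0
    )
    dels = rng.random(n) < profile.del_rate * w
    inss = rng.random(n) < profile.ins_rate * w
    rep = np.where(dels, 0, 1) + np.where(inss & ~dels, 1, 0)
    out = np.repeat(vals, rep)
    # half of the insertions duplicate the current base (homopolymer-like),
    # half are replaced by a random base
    ins_sites = np.flatnonzero(inss & ~dels)
    if len(ins_sites) > 0:
        out_pos = np.cumsum(rep)[ins_sites] - 1
        rand_mask = rng.random(len(out_pos)) < 0.5
        out[out_pos[rand_mask]] = rng.integers(0, 4, int(rand_mask.sum()))
    return _BASES[out].tobytes().decode()


def simulate_reads(
    array: SimulatedArray,
    profile: ReadProfile,
    coverage: float,
    seed: int,
    id_prefix: str = "read",
) -> List[SequenceRecord]:
    """Sample reads uniformly from the linear array to a target fold coverage.

    Lengths follow a lognormal law truncated at the remaining array length;
    errors are injected per the profile with homopolymer bias; the true origin
    interval and strand are recorded in each read's description.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    seq = array.array_sequence
    L = len(seq)
    if profile.mean_length > L:
        warnings.warn("mean read length exceeds array length; reads truncated")
    rng = np.random.default_rng(seed)
    mu = np.log(profile.mean_length) - profile.length_sigma**2 / 2
    target = coverage * L
    total = 0
    reads: List[SequenceRecord] = []
    i = 0
    while total < target:
        start = int(rng.integers(0, L))
        length = int(rng.lognormal(mu, profile.length_sigma))
        length = max(200, length)
        length = min(length, L - start)
        template = seq[start : start + length]
        bases = _inject_errors(rng, template, profile)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            bases = revcomp(bases)
        reads.append(
            SequenceRecord(
                id=f"{id_prefix}{i}",
                bases=bases,
                description=f"origin={start}-{start + length} strand={strand}",
            )
        )
        total += length
        i += 1
    return reads


def simulate_dataset(
    params: SimParams,
    hifi_coverage: float = 35.0,
    ont_coverage: float = 120.0,
    hifi_profile: ReadProfile = HIFI_PROFILE,
    ont_profile: ReadProfile = ONT_PROFILE,
):
    """Full study-condition dataset: truth array, reference, HiFi and ONT reads.

    The recruitment reference is the first panel source — a related unit that
    is not itself any morph, mimicking reference-based recruitment of reads
    from a diverged genome.
    """
    panel = generate_source_panel(params)
    morphs = generate_morphs(panel, params)
    array = build_array(morphs, seed=params.seed + 2)
    hifi = simulate_reads(
        array, hifi_profile, hifi_coverage, seed=params.seed + 3, id_prefix="hifi_"
    )
    ont = simulate_reads(
        array, ont_profile, ont_coverage, seed=params.seed + 4, id_prefix="ont_"
    )
    reference = SequenceRecord(id="reference", bases=panel[0])
    return array, reference, hifi, ont
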