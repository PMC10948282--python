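"""End-to-end reference-based morph assembly workflow.

Recruit accurate reads with a reference repeat unit, build the allele graph,
recruit and align ultralong reads to it, extract loops, cluster them into
morphs, polish a consensus per cluster and a genome-wide consensus from the
graph.  A HiFi-only mode reuses the accurate reads in both roles for genomes
whose repeat unit is shorter than an accurate read, with tighter clustering
parameters (rough-cluster radius 10 edits, minimum epsilon 1).

All stages are deterministic; a run writes every intermediate artifact plus a
machine-readable manifest, and two runs with the same configuration produce
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

from . import allele_graph as ag
from . import consensus as cons
from . import formats, loops_cluster, recruit
from .formats import SequenceRecord
from .graph_align import align_reads

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "run_ref_pipeline", "run_hifi_only"]

Reads = Union[str, Sequence[SequenceRecord]]


class PipelineError(RuntimeError):
    """Fatal stage error, named after the stage, with a remediation hint."""


@dataclass
class PipelineConfig:
    reference: Union[str, SequenceRecord]
    hifi: Reads
    ont: Optional[Reads] = None
    out_dir: Optional[str] = None
    approx_morph_size: int = 45_000
    k_graph: int = 31  # compressed-space k; packed 2-bit codes cap this at 31
    k_recruit: int = 21
    anchor_k: int = 17
    solid_min: int = 5
    min_fraction_hifi: float = 0.2
    min_fraction_ont: float = 0.1
    max_rough_diff: Optional[int] = None  # default: 1% of approx_morph_size
    min_epsilon: int = 1
    min_pts: int = 5
    report_min_coverage: int = 30
    min_alignment_identity: float = 0.75
    seed: int = 0
    mode: str = "ref"  # or "hifi-only"

    def __post_init__(self) -> None:
        if self.approx_morph_size <= 2 * self.k_graph:
            raise ValueError("approx_morph_size must exceed 2 x k_graph")
        if self.mode not in ("ref", "hifi-only"):
            raise ValueError("mode must be 'ref' or 'hifi-only'")

    @property
    def rough_diff(self) -> int:
        if self.max_rough_diff is not None:
            return self.max_rough_diff
        return max(self.min_epsilon, round(0.01 * self.approx_morph_size))


@dataclass
class PipelineResult:
    morphs: List[cons.Morph]
    genome_wide_consensus: str
    graph: ag.AlleleGraph
    loops: List[loops_cluster.Loop]
    clusters: List[loops_cluster.MorphCluster]
    noise: set
    epsilon: int
    anchor: int
    counts: Dict[str, int]
    low_confidence: List[str] = field(default_factory=list)


class _Log:
    """Timestamp-free run log: deterministic bytes, echoed to stderr."""

    def __init__(self, echo: bool = True):
        self.lines: List[str] = []
        self.echo = echo

    def __call__(self, msg: str) -> None:
        self.lines.append(msg)
        if self.echo:
            print(msg, file=sys.stderr)

    def dump(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.lines) + "\n")


def _load_reads(src: Reads) -> List[SequenceRecord]:
    if isinstance(src, (str, os.PathLike)):
        return formats.read_sequences(src)
    return list(src)


def _load_reference(src) -> SequenceRecord:
    if isinstance(src, SequenceRecord):
        return src
    recs = formats.read_sequences(src)
    if not recs:
        raise PipelineError("[recruit] reference file contains no sequence")
    if len(recs) == 1:
        return recs[0]
    return SequenceRecord(
        id=recs[0].id, bases="".join(r.bases for r in recs), description="concatenated"
    )


def run_hifi_only(config: PipelineConfig) -> PipelineResult:
    """HiFi-only mode: accurate reads serve in both roles.

    Applies the short-morph parameter overrides (maximum rough cluster
    difference 10 edits, minimum epsilon 1, minimum cluster size 2) unless
    the caller set them explicitly.
    """
    overrides = dict(mode="hifi-only", ont=config.hifi, min_pts=min(config.min_pts, 2))
    if config.max_rough_diff is None:
        overrides["max_rough_diff"] = 10
    cfg = replace(config, **overrides)
    return run_ref_pipeline(cfg)


def run_ref_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the reference-based workflow; see the module docstring."""
    if config.mode == "hifi-only" and config.ont is None:
        return run_hifi_only(config)
    log = _Log()
    out = config.out_dir
    if out:
        os.makedirs(out, exist_ok=True)
    log(f"mode={config.mode} approx_morph_size={config.approx_morph_size}")
    log(
        f"params k_graph={config.k_graph} k_recruit={config.k_recruit} "
        f"anchor_k={config.anchor_k} solid_min={config.solid_min} "
        f"max_rough_diff={config.rough_diff} min_epsilon={config.min_epsilon} "
        f"min_pts={config.min_pts} seed={config.seed}"
    )

    reference = _load_reference(config.reference)
    hifi = _load_reads(config.hifi)
    if config.ont is None:
        raise PipelineError("[input] no ultralong reads given; use hifi-only mode")
    ont = _load_reads(config.ont)
    log(f"input hifi_reads={len(hifi)} ont_reads={len(ont)}")
    if config.mode == "hifi-only":
        mean_hifi = sum(len(r) for r in hifi) / max(len(hifi), 1)
        if config.approx_morph_size > mean_hifi:
            warnings.warn(
                "morph size exceeds the mean accurate read length; "
                "HiFi-only mode will not find complete loops"
            )

    # 1. recruit accurate reads against the reference
    ref_index = recruit.build_kmer_index([reference], config.k_recruit)
    hifi_sel, hifi_dec = recruit.recruit_reads(hifi, ref_index, config.min_fraction_hifi)
    log(f"recruit hifi_recruited={len(hifi_sel)}")
    if out:
        formats.write_tsv(
            [(d.read_id, d.matched_fraction, int(d.recruited)) for d in hifi_dec],
            os.path.join(out, "recruit_hifi.tsv"),
            ("read_id", "matched_fraction", "recruited"),
        )
        formats.write_sequences(hifi_sel, os.path.join(out, "recruited_hifi.fasta"))
    if not hifi_sel:
        raise PipelineError(
            "[recruit] no accurate reads recruited; the reference may be too "
            "divergent — build a species-specific reference or lower "
            "min_fraction_hifi"
        )

    # 2. allele graph
    try:
        graph = ag.build_allele_graph(hifi_sel, config.k_graph, config.solid_min)
        graph = ag.clean_graph(
            graph,
            min_node_coverage=config.solid_min,
            max_tip_length=5 * config.k_graph,
        )
    except ValueError as e:
        raise PipelineError(f"[allele_graph] {e}") from e
    log(f"allele_graph nodes={len(graph.nodes)} edges={len(graph.edges)}")
    if out:
        formats.write_gfa(graph, os.path.join(out, "allele_graph.gfa"))
        formats.write_tsv(
            [
                (n.id, n.expanded_length, n.coverage)
                for n in sorted(graph.nodes.values(), key=lambda n: n.id)
            ],
            os.path.join(out, "nodes.tsv"),
            ("node", "length", "coverage"),
        )

    # 3. recruit ultralong reads against the graph k-mers
    graph_index = recruit.build_kmer_index(
        [n.expanded for n in graph.nodes.values()], config.k_recruit
    )
    ont_sel, ont_dec = recruit.recruit_reads(ont, graph_index, config.min_fraction_ont)
    log(f"recruit ont_recruited={len(ont_sel)}")
    if out:
        formats.write_tsv(
            [(d.read_id, d.matched_fraction, int(d.recruited)) for d in ont_dec],
            os.path.join(out, "recruit_ont.tsv"),
            ("read_id", "matched_fraction", "recruited"),
        )
    if not ont_sel:
        raise PipelineError(
            "[recruit] no ultralong reads recruited; lower min_fraction_ont"
        )

    # 4. align ultralong reads to the graph
    paths = align_reads(
        ont_sel,
        graph,
        anchor_k=config.anchor_k,
        min_identity=config.min_alignment_identity,
    )
    log(f"graph_align aligned_paths={len(paths)}")
    if out:
        formats.write_tsv(
            [
                (
                    p.read_id,
                    ",".join(f"{n}{o}" for n, o in p.path),
                    p.read_interval[0],
                    p.read_interval[1],
                    p.identity,
                )
                for p in paths
            ],
            os.path.join(out, "alignments.tsv"),
            ("read_id", "path", "read_start", "read_end", "identity"),
        )

    # 5. loops
    anchor = loops_cluster.select_anchor_node(graph)
    log(f"loops anchor_node={anchor}")
    loops: List[loops_cluster.Loop] = []
    discarded = 0
    read_seq = {r.id: r.bases for r in ont_sel}
    for p in paths:
        lps, disc = loops_cluster.extract_loops(
            p, anchor, config.approx_morph_size, graph, read_seq.get(p.read_id)
        )
        loops.extend(lps)
        discarded += disc
    log(f"loops extracted={len(loops)} discarded_by_length={discarded}")
    if not loops:
        raise PipelineError(
            "[loops] zero loops extracted; reads may be too short to span a "
            "repeat unit, or approx_morph_size is wrong"
        )
    if out:
        formats.write_sequences(
            [
                SequenceRecord(f"{lp.read_id}_{lp.ordinal}", lp.sequence)
                for lp in loops
            ],
            os.path.join(out, "loops.fasta"),
        )

    # 6. clustering
    # distances are computed with headroom above the rough-cluster radius so
    # the epsilon estimate (a mean over finite within-cluster distances) is
    # not truncated at the rough threshold
    distances = loops_cluster.pairwise_distances(
        loops, limit=3 * config.rough_diff, rough_limit=config.rough_diff
    )
    rough = loops_cluster.rough_cluster(distances, config.rough_diff)
    # epsilon may never exceed the rough-cluster radius (density clusters
    # must stay within rough clusters)
    epsilon = min(
        loops_cluster.estimate_epsilon(rough, distances, config.min_epsilon),
        config.rough_diff,
    )
    clusters, noise = loops_cluster.dbscan_cluster(
        loops, distances, epsilon, config.min_pts
    )
    assert sum(len(c.loop_indices) for c in clusters) + len(noise) == len(loops)
    log(
        f"cluster rough_clusters={len(rough)} epsilon={epsilon} "
        f"density_clusters={len(clusters)} noise_loops={len(noise)}"
    )
    if not clusters:
        raise PipelineError(
            "[cluster] every loop is noise; lower min_pts or check read quality"
        )
    if out:
        rough_of = {}
        for ri, cl in enumerate(rough):
            for i in cl:
                rough_of[i] = ri
        cluster_of = {}
        for ci, c in enumerate(clusters):
            for i in c.loop_indices:
                cluster_of[i] = str(ci)
        formats.write_tsv(
            [
                (
                    f"{loops[i].read_id}_{loops[i].ordinal}",
                    rough_of[i],
                    cluster_of.get(i, "noise"),
                )
                for i in range(len(loops))
            ],
            os.path.join(out, "clusters.tsv"),
            ("loop_id", "rough_cluster", "morph_cluster"),
        )
        with open(os.path.join(out, "params.json"), "w") as fh:
            json.dump(
                {
                    "epsilon": epsilon,
                    "min_pts": config.min_pts,
                    "max_rough_diff": config.rough_diff,
                    "min_epsilon": config.min_epsilon,
                },
                fh,
                sort_keys=True,
                indent=1,
            )

    # 7. consensus per cluster + genome-wide consensus
    morphs = cons.morphs_from_clusters(clusters, loops, distances)
    low_conf = [m.morph_id for m in morphs if m.coverage < config.report_min_coverage]
    for m in morphs:
        flag = " low-confidence" if m.morph_id in low_conf else ""
        log(f"morph {m.morph_id} coverage={m.coverage} length={m.length}{flag}")
    try:
        gw = cons.genome_wide_consensus(graph, anchor, config.approx_morph_size)
    except ValueError as e:
        log(f"consensus genome-wide walk failed: {e}")
        gw = ""
    counts = {
        "hifi_reads": len(hifi),
        "hifi_recruited": len(hifi_sel),
        "ont_reads": len(ont),
        "ont_recruited": len(ont_sel),
        "graph_nodes": len(graph.nodes),
        "graph_edges": len(graph.edges),
        "aligned_paths": len(paths),
        "loops": len(loops),
        "loops_discarded": discarded,
        "rough_clusters": len(rough),
        "clusters": len(clusters),
        "noise": len(noise),
    }
    result = PipelineResult(
        morphs=morphs,
        genome_wide_consensus=gw,
        graph=graph,
        loops=loops,
        clusters=clusters,
        noise=noise,
        epsilon=epsilon,
        anchor=anchor,
        counts=counts,
        low_confidence=low_conf,
    )
    if out:
        formats.write_sequences(
            [
                SequenceRecord(
                    m.morph_id,
                    m.sequence,
                    f"coverage={m.coverage} length={m.length}",
                )
                for m in morphs
            ],
            os.path.join(out, "morphs.fasta"),
            sort=False,
        )
        if gw:
            formats.write_sequences(
                [SequenceRecord("consensus", gw)],
                os.path.join(out, "consensus.fasta"),
            )
        formats.write_tsv(
            [(m.morph_id, m.coverage, m.length) for m in morphs],
            os.path.join(out, "summary.tsv"),
            ("morph", "coverage", "length"),
        )
        log.dump(os.path.join(out, "run.log"))
        _write_manifest(out, config, counts, epsilon)
    return result


def _write_manifest(out: str, config: PipelineConfig, counts: Dict, epsilon: int) -> None:
    entries = {}
    for name in sorted(os.listdir(out)):
        if name == "manifest.json":
            continue
        path = os.path.join(out, name)
        if os.path.isfile(path):
            with open(path, "rb") as fh:
                entries[name] = hashlib.sha256(fh.read()).hexdigest()
    manifest = {
        "outputs": entries,
        "counts": counts,
        "epsilon": epsilon,
        "params": {
            "approx_morph_size": config.approx_morph_size,
            "k_graph": config.k_graph,
            "k_recruit": config.k_recruit,
            "anchor_k": config.anchor_k,
            "solid_min": config.solid_min,
            "max_rough_diff": config.rough_diff,
            "min_epsilon": config.min_epsilon,
            "min_pts": config.min_pts,
            "mode": config.mode,
            "seed": config.seed,
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
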