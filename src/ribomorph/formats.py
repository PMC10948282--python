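"""Strict readers and writers for the formats the pipeline touches.

FASTA, FASTQ (Phred+33), GFA 1.0 and TSV reports.  The dialects are
deliberately narrow: bases are uppercased, U is mapped to T, anything outside
{A,C,G,T,N} is rejected with the offending line number, and writers are
deterministic (records and graph nodes sorted by id) so identical inputs give
byte-identical files.  Files ending in ``.gz`` are read and written through
gzip transparently.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

__all__ = [
    "SequenceRecord",
    "ParseError",
    "read_sequences",
    "write_sequences",
    "write_gfa",
    "read_gfa",
    "write_tsv",
]

_VALID = set("ACGTN")
_TRANS = str.maketrans("acgtun" + "U", "ACGTTN" + "T")


class ParseError(ValueError):
    """Malformed record in a sequence or graph file."""


@dataclass
class SequenceRecord:
    """One named sequence with optional per-base Phred qualities."""

    id: str
    bases: str
    description: str = ""
    qualities: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


def _open_text(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_bases(raw: str, line_no: int) -> str:
    bases = raw.translate(_TRANS)
    bad = set(bases) - _VALID
    if bad:
        raise ParseError(
            f"line {line_no}: invalid sequence character(s) {sorted(bad)!r}"
        )
    return bases


def _split_header(line: str, line_no: int) -> tuple[str, str]:
    head = line[1:].strip()
    if not head:
        raise ParseError(f"line {line_no}: empty sequence id")
    parts = head.split(None, 1)
    return parts[0], parts[1] if len(parts) > 1 else ""


def read_sequences(path, format: str = "auto") -> List[SequenceRecord]:
    """Read FASTA or FASTQ records in file order.

    ``format`` may be ``fasta``, ``fastq`` or ``auto`` (sniffed from the first
    non-empty character, ``>`` vs ``@``).  An empty file yields an empty list.
    """
    with _open_text(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    first = next((ln for ln in lines if ln.strip()), None)
    if first is None:
        return []
    if format == "auto":
        if first.lstrip().startswith(">"):
            format = "fasta"
        elif first.lstrip().startswith("@"):
            format = "fastq"
        else:
            raise ParseError("line 1: cannot sniff format (no '>' or '@' header)")
    if format == "fasta":
        records = _parse_fasta(lines)
    elif format == "fastq":
        records = _parse_fastq(lines)
    else:
        raise ValueError(f"unknown format {format!r}")
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
    return records


def _parse_fasta(lines: Sequence[str]) -> List[SequenceRecord]:
    records: List[SequenceRecord] = []
    rid = desc = None
    chunks: List[str] = []
    start_line = 0

    def flush() -> None:
        if rid is None:
            return
        records.append(SequenceRecord(rid, "".join(chunks), desc))

    for i, ln in enumerate(lines, 1):
        if ln.startswith(">"):
            flush()
            rid, desc = _split_header(ln, i)
            chunks = []
            start_line = i
        elif ln.strip():
            if rid is None:
                raise ParseError(f"line {i}: sequence data before first header")
            chunks.append(_clean_bases(ln.strip(), i))
    flush()
    return records


def _parse_fastq(lines: Sequence[str]) -> List[SequenceRecord]:
    body = [(i, ln) for i, ln in enumerate(lines, 1) if ln.strip()]
    if len(body) % 4 != 0:
        raise ParseError(
            f"line {body[-1][0] if body else 0}: truncated FASTQ (records are 4 lines)"
        )
    records = []
    for j in range(0, len(body), 4):
        (i1, h), (i2, s), (i3, plus), (i4, q) = body[j : j + 4]
        if not h.startswith("@"):
            raise ParseError(f"line {i1}: expected '@' header")
        if not plus.startswith("+"):
            raise ParseError(f"line {i3}: expected '+' separator")
        rid, desc = _split_header(h, i1)
        bases = _clean_bases(s.strip(), i2)
        qual = q.strip()
        if len(qual) != len(bases):
            raise ParseError(
                f"line {i4}: quality length {len(qual)} != sequence length {len(bases)}"
            )
        records.append(
            SequenceRecord(rid, bases, desc, [ord(c) - 33 for c in qual])
        )
    return records


def write_sequences(
    records: Iterable[SequenceRecord],
    path,
    format: str = "fasta",
    sort: bool = True,
    width: int = 80,
) -> None:
    """Write records as FASTA or FASTQ; deterministic (sorted by id) by default."""
    recs = list(records)
    if sort:
        recs = sorted(recs, key=lambda r: r.id)
    buf = io.StringIO()
    for rec in recs:
        head = f"{rec.id} {rec.description}".strip()
        if format == "fasta":
            buf.write(f">{head}\n")
            for i in range(0, len(rec.bases), width):
                buf.write(rec.bases[i : i + width] + "\n")
        elif format == "fastq":
            quals = rec.qualities or [30] * len(rec.bases)
            buf.write(f"@{head}\n{rec.bases}\n+\n")
            buf.write("".join(chr(q + 33) for q in quals) + "\n")
        else:
            raise ValueError(f"unknown format {format!r}")
    with _open_text(path, "wt") as fh:
        fh.write(buf.getvalue())


def write_gfa(graph, path) -> None:
    """Write an allele graph as GFA 1.0.

    One S line per node carrying the expanded (run-length decoded) sequence
    with mean coverage as a ``dp:f`` tag, one L line per edge with overlap
    CIGAR ``<k-1>M`` (the overlap is k-1 symbols in homopolymer-compressed
    space) and an ``ec:i`` coverage tag.  The compressed-space k is recorded
    on the header as ``kl:i`` so that parsing is possible for edge-free graphs.
    """
    lines = [f"H\tVN:Z:1.0\tkl:i:{graph.k}"]
    for node in sorted(graph.nodes.values(), key=lambda n: n.id):
        lines.append(
            f"S\t{node.id}\t{node.expanded}\tdp:f:{node.coverage:.6g}"
        )
    for (a, oa, b, ob), cov in sorted(graph.edges.items()):
        lines.append(
            f"L\t{a}\t{oa}\t{b}\t{ob}\t{graph.k - 1}M\tec:i:{int(round(cov))}"
        )
    with _open_text(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gfa(path):
    """Parse a GFA 1.0 file produced by :func:`write_gfa`.

    Unknown line types are ignored.  An L line referring to an absent segment
    is an error.
    """
    from .allele_graph import AlleleGraph, UnitigNode, hpc_compress

    k = None
    nodes = {}
    edges = {}
    pending_edges = []
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            fields = raw.rstrip("\n").split("\t")
            if not fields or not fields[0]:
                continue
            tag = fields[0]
            if tag == "H":
                for f in fields[1:]:
                    if f.startswith("kl:i:"):
                        k = int(f[5:])
            elif tag == "S":
                if len(fields) < 3:
                    raise ParseError(f"line {line_no}: S line needs id and sequence")
                nid = int(fields[1])
                cov = 1.0
                for f in fields[3:]:
                    if f.startswith("dp:f:"):
                        cov = float(f[5:])
                hpc = hpc_compress(fields[2])
                nodes[nid] = UnitigNode(id=nid, hpc=hpc, coverage=cov)
            elif tag == "L":
                if len(fields) < 6:
                    raise ParseError(f"line {line_no}: short L line")
                a, oa, b, ob = int(fields[1]), fields[2], int(fields[3]), fields[4]
                cov = 1
                for f in fields[6:]:
                    if f.startswith("ec:i:"):
                        cov = int(f[5:])
                if k is None:
                    k = int(fields[5].rstrip("M")) + 1
                pending_edges.append(((a, oa, b, ob), cov, line_no))
    for (a, oa, b, ob), cov, line_no in pending_edges:
        if a not in nodes or b not in nodes:
            raise ParseError(f"line {line_no}: L line references absent segment")
        edges[(a, oa, b, ob)] = cov
    if k is None:
        k = 2  # edge-free graph from a foreign writer; harmless placeholder
    return AlleleGraph(k=k, nodes=nodes, edges=edges)


def write_tsv(rows: Iterable[Sequence], path, header: Sequence[str]) -> None:
    """Write a UTF-8 TSV with a header row and '.' decimal floats."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{v:.6g}" if isinstance(v, float) else str(v) for v in row
                )
                + "\n"
            )
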