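"""Readers and writers for the formats the pipeline touches.

Sequence I/O is FASTA only (contigs, chromosomes, corrected long reads).
Connection graphs come in two dialects: GFA1 (``S``/``L`` lines) and a
minimal Newbler-like tab-separated dialect documented below.  Gene
annotations are ingested from a GenBank-feature-table-lite format --
``LOCUS``/``FEATURES`` plus ``gene``/``CDS``/``tRNA``/``rRNA`` feature
lines with standard location strings -- which is sufficient to represent
deposited organelle records without full flat-file compliance.

Coordinate convention: everything that crosses the package boundary
(files, truth tables, reports) is 1-based inclusive, as in GenBank and
the microsatellite literature; everything internal is 0-based half-open.
:func:`parse_location` / :func:`format_location` are the only crossing
points for annotation coordinates.

Newbler-like dialect (one record per line, tab-separated)::

    C   <contig_id>  <length>  <depth>  [<n_reads>]
    L   <contig_id>  <b|e>     <contig_id>  <b|e>  [<support>]

``b`` is the 5' (begin) end of a contig, ``e`` the 3' (end) end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio.SeqFeature import Location as _BioLocation

__all__ = [
    "SeqRecord",
    "GeneFeature",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "parse_location",
    "format_location",
    "read_connection_graph",
    "write_connection_graph",
    "read_feature_table",
    "write_feature_table",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file or string did not conform to its declared format."""


@dataclass
class SeqRecord:
    """A DNA sequence with an identifier and topology.

    The sequence alphabet is {A, C, G, T, N}; readers upper-case input
    and map other IUPAC letters to ``N``, counting the replacements.
    """

    id: str
    sequence: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord requires a non-empty id")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SeqRecord":
        return SeqRecord(self.id, revcomp(self.sequence), self.topology)


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """A gene with one or more exons, possibly spread over chromosomes.

    ``exons`` are ordered (chromosome id, start, end, strand) tuples with
    1-based inclusive coordinates, in transcription order.  Multi-exon
    genes whose exons share one chromosome are cis-spliced; exon sets
    spanning several chromosomes mark trans-chromosomal genes such as
    nad1/nad5 in multi-circular poplar mitogenomes.
    """

    gene: str
    category: str  # "PCG" | "tRNA" | "rRNA"
    exons: list[tuple[str, int, int, str]] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if self.category not in ("PCG", "tRNA", "rRNA"):
            raise ValueError(f"unknown gene category {self.category!r}")
        for chrom, start, end, strand in self.exons:
            if start > end:
                raise ValueError(
                    f"{self.gene}: exon start {start} > end {end} "
                    "(wrap-around exons must be split)"
                )
            if strand not in "+-":
                raise ValueError(f"{self.gene}: bad strand {strand!r}")

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for chrom, *_ in self.exons:
            if chrom not in seen:
                seen.append(chrom)
        return seen

    @property
    def exon_length(self) -> int:
        return sum(end - start + 1 for _, start, end, _ in self.exons)


# ---------------------------------------------------------------------------
# FASTA


def _normalize(seq: str) -> tuple[str, int]:
    seq = seq.upper()
    n_ambiguous = sum(1 for c in seq if c not in _VALID)
    if n_ambiguous:
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq, n_ambiguous


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Lower-case input is upper-cased; IUPAC ambiguity codes become ``N``
    (the total replacement count is stored on the returned list as the
    ``ambiguity_count`` attribute).  Duplicate ids or an empty file are
    format errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    total_ambiguous = 0
    name = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal total_ambiguous
        if name is None:
            return
        seq, n_amb = _normalize("".join(chunks))
        total_ambiguous += n_amb
        if name in seen:
            raise FormatError(f"duplicate FASTA id {name!r} in {path}")
        seen.add(name)
        records.append(SeqRecord(name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before first header")
                chunks.append(line)
    flush()
    if not records:
        raise FormatError(f"{path}: empty FASTA file")

    class _RecordList(list):
        pass

    out = _RecordList(records)
    out.ambiguity_count = total_ambiguous
    return out


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank-style location strings


def parse_location(location: str) -> list[tuple[int, int, str]]:
    """Parse a GenBank location string into oriented 1-based intervals.

    Supports ``start..end``, single-base positions, ``join(...)`` and
    ``complement(...)`` with nesting.  ``complement(join(a, b))`` yields
    the intervals in reversed order with ``-`` strands, i.e. in
    transcription order of the minus-strand gene.

    Returns a list of (start, end, strand) with start <= end.
    """
    try:
        loc = _BioLocation.fromstring(location.replace(" ", ""))
    except Exception as exc:
        raise FormatError(
            f"unparseable location {location!r} at offset "
            f"{_error_offset(location)}: {exc}"
        ) from None
    if loc is None:
        raise FormatError(
            f"unparseable location {location!r} at offset {_error_offset(location)}"
        )
    out: list[tuple[int, int, str]] = []
    for part in loc.parts:
        strand = "-" if part.strand == -1 else "+"
        out.append((int(part.start) + 1, int(part.end), strand))
    return out


def _error_offset(location: str) -> int:
    """Best-effort offset of the first unparseable character."""
    for i in range(1, len(location) + 1):
        prefix = location[:i]
        plausible = re.fullmatch(r"[\w().,<>^:]*", prefix)
        if not plausible:
            return i - 1
    return len(location)


def format_location(intervals: list[tuple[int, int, str]]) -> str:
    """Inverse of :func:`parse_location` on canonical interval lists."""
    if not intervals:
        raise ValueError("empty interval list")
    strands = {s for _, _, s in intervals}
    if strands == {"+"}:
        parts = [f"{a}..{b}" for a, b, _ in intervals]
        return parts[0] if len(parts) == 1 else "join(" + ",".join(parts) + ")"
    if strands == {"-"}:
        parts = [f"{a}..{b}" for a, b, _ in reversed(intervals)]
        inner = parts[0] if len(parts) == 1 else "join(" + ",".join(parts) + ")"
        return f"complement({inner})"
    # mixed strands: per-part complement inside a join
    parts = [f"complement({a}..{b})" if s == "-" else f"{a}..{b}" for a, b, s in intervals]
    return "join(" + ",".join(parts) + ")"


# ---------------------------------------------------------------------------
# Connection graphs

# The ConnectionGraph class itself lives in mitocircles.graph; imported lazily
# to keep the io module free of graph logic.


def read_connection_graph(path: str | Path, dialect: str = "newbler"):
    """Read a contig connection graph in the ``newbler`` or ``gfa1`` dialect.

    Nodes carry length/depth when the file declares them; every link must
    reference a declared contig or a :class:`FormatError` is raised.
    """
    from .graph import ConnectionGraph

    graph = ConnectionGraph()
    if dialect == "newbler":
        _read_newbler(path, graph)
    elif dialect == "gfa1":
        _read_gfa1(path, graph)
    else:
        raise ValueError(f"unknown graph dialect {dialect!r}")
    return graph


def _read_newbler(path, graph) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            tag = parts[0]
            if tag == "C":
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: short C line")
                cid, length, depth = parts[1], int(parts[2]), float(parts[3])
                n_reads = int(parts[4]) if len(parts) > 4 else 0
                graph.add_contig(cid, length=length, depth=depth, n_reads=n_reads)
            elif tag == "L":
                if len(parts) < 5:
                    raise FormatError(f"{path}:{lineno}: short L line")
                a, ea, b, eb = parts[1], parts[2], parts[3], parts[4]
                support = int(parts[5]) if len(parts) > 5 else 0
                for cid in (a, b):
                    if cid not in graph.nodes:
                        raise FormatError(
                            f"{path}:{lineno}: link references undeclared contig {cid!r}"
                        )
                if ea not in "be" or eb not in "be":
                    raise FormatError(f"{path}:{lineno}: contig end must be 'b' or 'e'")
                graph.add_link(a, ea, b, eb, support=support)
            else:
                raise FormatError(f"{path}:{lineno}: unknown record type {tag!r}")


def _read_gfa1(path, graph) -> None:
    links = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("H"):
                continue
            parts = line.split("\t")
            if parts[0] == "S":
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: short S line")
                cid, seq = parts[1], parts[2]
                length = None if seq == "*" else len(seq)
                depth = 0.0
                for tag in parts[3:]:
                    if tag.startswith("LN:i:"):
                        length = int(tag[5:])
                    elif tag.startswith(("DP:f:", "dp:f:")):
                        depth = float(tag[5:])
                graph.add_contig(
                    cid,
                    length=length or 0,
                    depth=depth,
                    sequence=None if seq == "*" else seq.upper(),
                )
            elif parts[0] == "L":
                if len(parts) < 6:
                    raise FormatError(f"{path}:{lineno}: short L line")
                links.append((lineno, parts[1], parts[2], parts[3], parts[4]))
    for lineno, a, oa, b, ob in links:
        for cid in (a, b):
            if cid not in graph.nodes:
                raise FormatError(
                    f"{path}:{lineno}: link references undeclared contig {cid!r}"
                )
        # GFA1: A+ -> B+ joins end of A to begin of B; a '-' orientation
        # flips which physical end participates in the junction.
        ea = "e" if oa == "+" else "b"
        eb = "b" if ob == "+" else "e"
        graph.add_link(a, ea, b, eb)


def write_connection_graph(graph, path: str | Path, dialect: str = "newbler") -> None:
    with open(path, "w") as fh:
        if dialect == "newbler":
            for cid in sorted(graph.nodes):
                node = graph.nodes[cid]
                fh.write(
                    f"C\t{cid}\t{node.length}\t{node.depth:g}\t{node.n_reads}\n"
                )
            for (a, ea), (b, eb), support in graph.iter_links():
                fh.write(f"L\t{a}\t{ea}\t{b}\t{eb}\t{support}\n")
        elif dialect == "gfa1":
            fh.write("H\tVN:Z:1.0\n")
            for cid in sorted(graph.nodes):
                node = graph.nodes[cid]
                seq = node.sequence or "*"
                fh.write(f"S\t{cid}\t{seq}\tLN:i:{node.length}\tDP:f:{node.depth:g}\n")
            for (a, ea), (b, eb), _ in graph.iter_links():
                oa = "+" if ea == "e" else "-"
                ob = "+" if eb == "b" else "-"
                fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M\n")
        else:
            raise ValueError(f"unknown graph dialect {dialect!r}")


# ---------------------------------------------------------------------------
# GenBank-feature-table-lite

_FEATURE_KEYS = {"gene": None, "CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_feature_table(path: str | Path) -> list[GeneFeature]:
    """Parse a GenBank-feature-table-lite file into gene features.

    The dialect is a sequence of record blocks::

        LOCUS   <chromosome id>  [<length> bp] [circular]
        FEATURES
             CDS    join(1..100,200..400)
                    /gene="nad7"
             tRNA   complement(500..570)
                    /gene="trnM-CAU"

    ``gene`` feature lines are accepted and ignored (the typed CDS/tRNA/
    rRNA line is authoritative).  A ``/note`` qualifier is carried through.
    Exons of a gene already seen on another LOCUS are merged into one
    :class:`GeneFeature` (trans-chromosomal genes).
    """
    features: dict[tuple[str, str], GeneFeature] = {}
    order: list[tuple[str, str]] = []
    chrom = None
    pending: tuple[str, list[tuple[int, int, str]]] | None = None
    pending_quals: dict[str, str] = {}

    def commit() -> None:
        nonlocal pending, pending_quals
        if pending is None:
            return
        category, intervals = pending
        name = pending_quals.get("gene")
        if name is None:
            raise FormatError(f"{path}: {category} feature without /gene qualifier")
        key = (name, category)
        exons = [(chrom, a, b, s) for a, b, s in intervals]
        if key in features:
            features[key].exons.extend(exons)
        else:
            features[key] = GeneFeature(
                gene=name,
                category=category,
                exons=exons,
                note=pending_quals.get("note", ""),
            )
            order.append(key)
        pending = None
        pending_quals = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            stripped = line.strip()
            if stripped.startswith("LOCUS"):
                commit()
                parts = stripped.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: LOCUS without id")
                chrom = parts[1]
            elif stripped.startswith("FEATURES"):
                continue
            elif stripped.startswith("/"):
                m = re.match(r'/(\w+)=?"?([^"]*)"?', stripped)
                if not m:
                    raise FormatError(f"{path}:{lineno}: bad qualifier {stripped!r}")
                pending_quals[m.group(1)] = m.group(2)
            else:
                parts = stripped.split(None, 1)
                if parts[0] not in _FEATURE_KEYS:
                    raise FormatError(f"{path}:{lineno}: unknown feature key {parts[0]!r}")
                commit()
                if parts[0] == "gene":
                    continue  # untyped gene span; the typed feature carries it
                if chrom is None:
                    raise FormatError(f"{path}:{lineno}: feature before any LOCUS")
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: feature without location")
                pending = (_FEATURE_KEYS[parts[0]], parse_location(parts[1]))
    commit()
    return [features[k] for k in order]


def write_feature_table(
    features: Iterable[GeneFeature], path: str | Path, chromosome_lengths: dict[str, int] | None = None
) -> None:
    """Write gene features in the feature-table-lite dialect, one LOCUS per
    chromosome, exons grouped per (gene, chromosome)."""
    by_chrom: dict[str, list[tuple[GeneFeature, list[tuple[int, int, str]]]]] = {}
    for feat in features:
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, a, b, s in feat.exons:
            per_chrom.setdefault(chrom, []).append((a, b, s))
        for chrom, ivals in per_chrom.items():
            by_chrom.setdefault(chrom, []).append((feat, ivals))
    with open(path, "w") as fh:
        for chrom in sorted(by_chrom):
            length = (chromosome_lengths or {}).get(chrom)
            suffix = f"  {length} bp  circular" if length else ""
            fh.write(f"LOCUS   {chrom}{suffix}\nFEATURES\n")
            key_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
            for feat, ivals in by_chrom[chrom]:
                loc = format_location(ivals)
                fh.write(f"     {key_of[feat.category]:<6} {loc}\n")
                fh.write(f'            /gene="{feat.gene}"\n')
                if feat.note:
                    fh.write(f'            /note="{feat.note}"\n')
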