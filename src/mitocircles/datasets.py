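"""Published bookkeeping tables for the *Populus simonii* mitogenome and
fixture builders around them.

The deposited *P. simonii* mitogenome (GenBank MZ905370-MZ905372) comes
with printed per-contig assembly statistics, a coding/intergenic
partition, and a comparative dispersed-repeat table.  Those numbers are
inputs here: the builders below turn them into in-memory objects
(contig sets, connection graphs, annotation fixtures, repeat-pair sets)
on which the pipeline's arithmetic can be re-run and checked end to end
without downloading the deposited records.

Sequences attached to these fixtures are synthetic stand-ins of the
printed lengths (the deposited bases are not bundled); every builder is
deterministic under its seed.
"""

from __future__ import annotations

import numpy as np

from .graph import ConnectionGraph
from .io import GeneFeature
from .repeats import DispersedRepeatPair
from .screen import Contig

__all__ = [
    "PSIMONII_CONTIG_TABLE",
    "PSIMONII_CHROMOSOME_SIZES",
    "PSIMONII_CODING_COMPONENTS",
    "POPULUS_DISPERSED_TABLE",
    "table1_contigs",
    "table1_graph",
    "coding_partition_features",
    "dispersed_pairs_fixture",
]

#: Newbler per-contig assembly statistics of the P. simonii mitogenome:
#: (draft chromosome, contig id, read depth x, n reads, length bp).
#: Contig85684 is the chloroplast-derived contig (plastid-level depth).
PSIMONII_CONTIG_TABLE: list[tuple[str, str, float, int, int]] = [
    ("mtChr1", "Contig00001", 73.3, 1931, 312303),
    ("mtChr2", "Contig00003", 70.4, 757, 124150),
    ("mtChr2", "Contig00004", 61.1, 455, 81303),
    ("mtChr2", "Contig00006", 71.3, 444, 71063),
    ("mtChr2", "Contig54890", 68.9, 98, 3376),
    ("mtChr2", "Contig72445", 88.1, 109, 1363),
    ("mtChr2", "Contig74673", 73.3, 79, 1191),
    ("mtChr2", "Contig85684", 1036.2, 1059, 291),
    ("mtChr3", "Contig00002", 72.6, 927, 135137),
    ("mtChr3", "Contig02993", 71.7, 197, 25710),
    ("mtChr3", "Contig09733", 65.7, 144, 17871),
    ("mtChr3", "Contig48355", 67.0, 99, 4456),
    ("mtChr3", "Contig69702", 113.7, 123, 1607),
    ("mtChr3", "Contig74574", 82.3, 96, 1199),
]

CP_DERIVED_CONTIG = "Contig85684"

#: final polished chromosome sizes of the deposited records, bp
PSIMONII_CHROMOSOME_SIZES = {"MZ905370": 312510, "MZ905371": 282934, "MZ905372": 186034}

#: coding-length components of the P. simonii mitogenome, bp
PSIMONII_CODING_COMPONENTS = {
    "genome": 781_478,
    "tRNA": 1_583,
    "rRNA": 5_365,
    "PCG": 30_237,
    "cis_intron": 27_298,
}

#: comparative dispersed-repeat table for the four Populus mitogenomes:
#: size-bin pair counts (30-49, 50-69, 70-99, 100-149, 150-199, 200-499,
#: >500), longest pair, union of covered bases, genome size.
POPULUS_DISPERSED_TABLE = {
    "P_simonii": ([227, 49, 24, 11, 4, 7, 0], 297, 32_635, 781_478),
    "P_alba": ([242, 43, 30, 19, 4, 6, 0], 308, 35_485, 838_420),
    "P_davidiana": ([219, 36, 27, 15, 6, 5, 0], 286, 31_665, 779_361),
    "P_tremula": ([217, 40, 26, 15, 7, 5, 0], 308, 32_056, 783_442),
}


def table1_contigs(with_sequences: bool = False, seed: int = 0) -> list[Contig]:
    """The printed contig set, optionally with synthetic sequences of the
    printed lengths."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out = []
    for _, cid, depth, n_reads, length in PSIMONII_CONTIG_TABLE:
        seq = (
            rng.choice(bases, size=length).tobytes().decode()
            if with_sequences
            else None
        )
        out.append(Contig(cid, length, depth, n_reads=n_reads, sequence=seq))
    return out


def table1_graph(contigs: list[Contig] | None = None) -> ConnectionGraph:
    """Connection graph of the printed contig set: one self-adjacent
    contig plus a 7-cycle and a 6-cycle.

    The printed statistics do not record which contig abuts which, so
    the cycles use table order -- a documented convention that preserves
    the cycle sizes and all length/depth bookkeeping.
    """
    contigs = contigs or table1_contigs()
    by_id = {c.id: c for c in contigs}
    graph = ConnectionGraph()
    for c in contigs:
        graph.add_contig(
            c.id, length=c.length, depth=c.depth, n_reads=c.n_reads, sequence=c.sequence
        )
    groups: dict[str, list[str]] = {}
    for chrom, cid, *_ in PSIMONII_CONTIG_TABLE:
        if cid in by_id:
            groups.setdefault(chrom, []).append(cid)
    for members in groups.values():
        for i, cid in enumerate(members):
            graph.add_link(cid, "e", members[(i + 1) % len(members)], "b")
    return graph


def coding_partition_features() -> tuple[list[GeneFeature], dict[str, int]]:
    """An annotation fixture whose per-category base counts equal the
    printed coding components: one rRNA, one tRNA and one two-exon PCG
    whose exon lengths and intron gap reproduce the printed totals, laid
    out without overlap on a genome of the printed size."""
    comp = PSIMONII_CODING_COMPONENTS
    exon1 = 15_000
    exon2 = comp["PCG"] - exon1
    intron = comp["cis_intron"]
    features = [
        GeneFeature(
            gene="nad5",
            category="PCG",
            exons=[
                ("chrA", 10_000, 10_000 + exon1 - 1, "+"),
                ("chrA", 10_000 + exon1 + intron, 10_000 + exon1 + intron + exon2 - 1, "+"),
            ],
        ),
        GeneFeature(
            gene="trnM-CAU",
            category="tRNA",
            exons=[("chrA", 70_000, 70_000 + comp["tRNA"] - 1, "+")],
        ),
        GeneFeature(
            gene="rrn26",
            category="rRNA",
            exons=[("chrA", 90_000, 90_000 + comp["rRNA"] - 1, "+")],
        ),
    ]
    return features, {"chrA": comp["genome"]}


def dispersed_pairs_fixture(
    genome: str = "P_simonii",
) -> tuple[list[DispersedRepeatPair], int]:
    """A dispersed-repeat pair set realising a printed comparative-table
    row: the printed size-bin counts and longest pair exactly, with pair
    coordinates arranged so that the union of covered bases equals the
    printed total repeat length."""
    bins, longest, union_target, genome_len = POPULUS_DISPERSED_TABLE[genome]
    bin_bounds = [(30, 49), (50, 69), (70, 99), (100, 149), (150, 199), (200, 499), (500, None)]
    lengths: list[int] = []
    for (lo, hi), count in zip(bin_bounds, bins):
        if count == 0:
            continue
        cap = min(hi, longest) if hi else longest
        lengths.extend(_spread_bin(count, lo, cap, longest, lengths))
    lengths.sort()
    # adjust within-bin lengths so that 2 * sum(lengths) slightly exceeds
    # the printed union; the excess becomes a single declared overlap
    total = sum(lengths)
    deficit = union_target - 2 * total
    i = 0
    while deficit > 0 and i < len(lengths):
        lo, hi = _bin_of(lengths[i], bin_bounds)
        room = (min(hi, longest) if hi else longest) - lengths[i]
        bump = min(room, (deficit + 1) // 2)
        if lengths[i] == longest:
            bump = 0  # keep the printed maximum unique
        lengths[i] += bump
        deficit = union_target - 2 * sum(lengths)
        i += 1
    overlap = 2 * sum(lengths) - union_target
    if overlap < 0:
        raise ValueError("cannot realise printed union with printed bins")

    pairs: list[DispersedRepeatPair] = []
    pos = 1
    for j, L in enumerate(lengths):
        start1 = pos
        if j == 0 and overlap:
            start2 = start1 + L - overlap  # two instances sharing `overlap` bp
            pos = start2 + L + 10
        else:
            start2 = start1 + L + 10
            pos = start2 + L + 10
        pairs.append(
            DispersedRepeatPair(
                chrom1="genome",
                start1=start1,
                chrom2="genome",
                start2=start2,
                length=L,
                mismatches=0,
                orientation="direct",
            )
        )
    return pairs, genome_len


def _bin_of(length: int, bounds) -> tuple[int, int | None]:
    for lo, hi in bounds:
        if length >= lo and (hi is None or length <= hi):
            return lo, hi
    raise ValueError(length)


def _spread_bin(count, lo, cap, longest, existing) -> list[int]:
    out = [lo] * count
    if cap == longest and longest not in existing and longest not in out:
        out[-1] = longest  # realise the printed longest pair once
    return out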