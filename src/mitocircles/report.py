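"""Descriptive genome statistics and gene-content comparisons.

Bookkeeping over sequences plus annotations: genome size and GC content,
the partition of the genome into gene territory (protein-coding, tRNA
and rRNA exons plus cis-spliced introns) versus intergenic sequence,
start/stop codon inspection, cis-intron histograms, trans-chromosomal
genes (multi-exon genes whose exons sit on different molecules, as nad1
and nad5 do in multi-circular poplar mitogenomes), gene
presence/absence matrices across taxa, and extraction of the
protein-coding genes shared by all taxa for downstream phylogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import GeneFeature, SeqRecord, revcomp

__all__ = [
    "GenomeStats",
    "gc_content",
    "partition_coding",
    "gene_inventory",
    "trans_chromosomal_genes",
    "presence_matrix",
    "extract_shared_pcgs",
]


@dataclass
class GenomeStats:
    genome_size: int
    coding_bp: int  # gene territory: exons + cis-spliced introns (union)
    intergenic_bp: int
    pcg_bp: int
    trna_bp: int
    rrna_bp: int
    cis_intron_bp: int
    n_pcg: int = 0
    n_trna: int = 0
    n_rrna: int = 0

    @property
    def coding_pct(self) -> float:
        return round(100.0 * self.coding_bp / self.genome_size, 2)

    @property
    def intergenic_pct(self) -> float:
        return round(100.0 * self.intergenic_bp / self.genome_size, 2)


def gc_content(seqs: list[SeqRecord] | SeqRecord) -> float:
    """(G+C) / (A+C+G+T) x 100, Ns excluded from the denominator, two
    decimals."""
    if isinstance(seqs, SeqRecord):
        seqs = [seqs]
    gc = acgt = 0
    for rec in seqs:
        for base in "ACGT":
            n = rec.sequence.count(base)
            acgt += n
            if base in "GC":
                gc += n
    if acgt == 0:
        raise ValueError("no unambiguous bases: GC content undefined")
    return round(100.0 * gc / acgt, 2)


def _gene_territory_intervals(feat: GeneFeature) -> list[tuple[str, int, int]]:
    """Spans of a gene's cis-connected exon runs (exons plus cis-spliced
    introns).  Trans-spliced junctions split the gene into separate
    spans, so their inter-segment gaps never count as gene territory."""
    runs: list[list[tuple[str, int, int, str]]] = [[feat.exons[0]]] if feat.exons else []
    for prev, nxt in zip(feat.exons, feat.exons[1:]):
        if _is_cis(prev, nxt):
            runs[-1].append(nxt)
        else:
            runs.append([nxt])
    return [
        (run[0][0], min(e[1] for e in run), max(e[2] for e in run)) for run in runs
    ]


def _union(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_a, cur_b = intervals[0]
    for a, b in intervals[1:]:
        if a > cur_b + 1:
            total += cur_b - cur_a + 1
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    return total + (cur_b - cur_a + 1)


def partition_coding(
    features: list[GeneFeature],
    genome_sizes: dict[str, int],
) -> GenomeStats:
    """Partition the genome into gene territory and intergenic sequence.

    Gene territory is the union of per-gene spans (exons plus cis-spliced
    introns); overlapping genes are counted once.  Per-category base
    counts (PCG / tRNA / rRNA exon length, cis-intron length) are summed
    per gene.  ``intergenic = genome - territory`` holds exactly for any
    input.  Exons outside the declared chromosome bounds raise.
    """
    genome = sum(genome_sizes.values())
    territory: list[tuple[int, int]] = []  # offset into a virtual concatenation
    offsets: dict[str, int] = {}
    off = 0
    for chrom in genome_sizes:
        offsets[chrom] = off
        off += genome_sizes[chrom]

    pcg = trna = rrna = cis_intron = 0
    counts = {"PCG": 0, "tRNA": 0, "rRNA": 0}
    for feat in features:
        for chrom, a, b, _ in feat.exons:
            if chrom not in genome_sizes:
                raise ValueError(f"{feat.gene}: unknown chromosome {chrom!r}")
            if a < 1 or b > genome_sizes[chrom]:
                raise ValueError(
                    f"{feat.gene}: exon {a}..{b} outside {chrom} "
                    f"(1..{genome_sizes[chrom]})"
                )
        counts[feat.category] += 1
        exon_len = feat.exon_length
        if feat.category == "PCG":
            pcg += exon_len
        elif feat.category == "tRNA":
            trna += exon_len
        else:
            rrna += exon_len
        cis_intron += cis_intron_length(feat)
        for chrom, lo, hi in _gene_territory_intervals(feat):
            territory.append((offsets[chrom] + lo, offsets[chrom] + hi))

    coding = _union(territory)
    return GenomeStats(
        genome_size=genome,
        coding_bp=coding,
        intergenic_bp=genome - coding,
        pcg_bp=pcg,
        trna_bp=trna,
        rrna_bp=rrna,
        cis_intron_bp=cis_intron,
        n_pcg=counts["PCG"],
        n_trna=counts["tRNA"],
        n_rrna=counts["rRNA"],
    )


#: largest inter-exon gap still treated as a cis-spliced intron; plant
#: mitochondrial cis introns run up to a few kb, while trans-spliced
#: segments of one gene lie tens to hundreds of kb apart even when they
#: share a molecule
MAX_CIS_INTRON = 50_000


def _is_cis(
    exon1: tuple[str, int, int, str],
    exon2: tuple[str, int, int, str],
    max_cis_gap: int = MAX_CIS_INTRON,
) -> bool:
    """Whether the junction between two consecutive exons is cis-spliced:
    same chromosome, same strand, and a positive genomic gap of at most
    ``max_cis_gap``.  Different molecules, different strands, or distant
    segments on one molecule mark trans-spliced junctions."""
    c1, a1, b1, s1 = exon1
    c2, a2, b2, s2 = exon2
    if c1 != c2 or s1 != s2:
        return False
    gap = a2 - b1 - 1 if a2 > b1 else a1 - b2 - 1
    return 0 < gap <= max_cis_gap


def _cis_gaps(feat: GeneFeature, max_cis_gap: int = MAX_CIS_INTRON):
    """Gap lengths of the cis-spliced introns of a gene."""
    for prev, nxt in zip(feat.exons, feat.exons[1:]):
        if _is_cis(prev, nxt, max_cis_gap):
            c1, a1, b1, _ = prev
            c2, a2, b2, _ = nxt
            yield a2 - b1 - 1 if a2 > b1 else a1 - b2 - 1


def cis_intron_length(feat: GeneFeature, max_cis_gap: int = MAX_CIS_INTRON) -> int:
    """Summed length of the gene's cis-spliced introns."""
    return sum(_cis_gaps(feat, max_cis_gap))


def cis_intron_count(feat: GeneFeature, max_cis_gap: int = MAX_CIS_INTRON) -> int:
    """Number of cis-spliced introns of the gene."""
    return sum(1 for _ in _cis_gaps(feat, max_cis_gap))


def gene_inventory(
    features: list[GeneFeature],
    sequences: dict[str, SeqRecord] | None = None,
) -> dict:
    """Gene counts, duplicate names, start/stop codons and the cis-intron
    histogram.

    Codons are read off the stitched coding sequence in annotation
    orientation; a CDS whose length is not divisible by three is flagged
    (organelle annotations may depend on RNA editing) but not fatal.
    Start/stop codons are reported as annotated, never adjusted.
    """
    counts = {"PCG": 0, "tRNA": 0, "rRNA": 0}
    name_count: dict[str, int] = {}
    codons: dict[str, tuple[str, str]] = {}
    flagged: list[str] = []
    intron_per_gene: dict[str, int] = {}
    for feat in features:
        counts[feat.category] += 1
        name_count[feat.gene] = name_count.get(feat.gene, 0) + 1
        n_introns = cis_intron_count(feat)
        if n_introns:
            intron_per_gene[feat.gene] = intron_per_gene.get(feat.gene, 0) + n_introns
        if feat.category == "PCG" and sequences is not None:
            cds = extract_gene_sequence(feat, sequences)
            if len(cds) % 3 != 0:
                flagged.append(feat.gene)
            if len(cds) >= 6:
                codons[feat.gene] = (cds[:3], cds[-3:])
    histogram: dict[int, int] = {}
    for n in intron_per_gene.values():
        histogram[n] = histogram.get(n, 0) + 1
    return {
        "n_genes": sum(counts.values()),
        "counts": counts,
        "n_distinct_names": len(name_count),
        "duplicates": sorted(n for n, c in name_count.items() if c > 1),
        "codons": codons,
        "frame_flagged": sorted(flagged),
        "intron_histogram": dict(sorted(histogram.items())),
        "total_cis_introns": sum(intron_per_gene.values()),
    }


def extract_gene_sequence(
    feat: GeneFeature, sequences: dict[str, SeqRecord]
) -> str:
    """Stitch a gene's exons in annotation order and orientation."""
    parts = []
    for chrom, a, b, strand in feat.exons:
        seq = sequences[chrom].sequence[a - 1 : b]
        parts.append(seq if strand == "+" else revcomp(seq))
    return "".join(parts)


def trans_chromosomal_genes(
    features: list[GeneFeature],
) -> dict[str, dict[str, list[int]]]:
    """Genes whose exons span two or more chromosomes, with the split
    structure (exon indices per chromosome, 1-based in annotation
    order)."""
    out: dict[str, dict[str, list[int]]] = {}
    for feat in features:
        split: dict[str, list[int]] = {}
        for i, (chrom, *_rest) in enumerate(feat.exons, 1):
            split.setdefault(chrom, []).append(i)
        if len(split) >= 2:
            out[feat.gene] = split
    return out


def presence_matrix(
    inventories: dict[str, list[GeneFeature] | list[str]],
    query_genes: list[str],
    synonyms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Gene presence/absence across taxa.

    ``inventories`` maps taxon name to its features (or plain gene-name
    lists).  Names are normalised case-insensitively through the synonym
    table; unknown query genes produce a warning and a row of absences.
    Order-invariant in both taxa and genes.
    """
    if len(inventories) < 2:
        raise ValueError("presence_matrix requires at least two taxa")
    synonyms = {k.lower(): v for k, v in (synonyms or {}).items()}

    def norm(name: str) -> str:
        low = name.lower()
        return synonyms.get(low, low)

    taxa = list(inventories)
    have: dict[str, set[str]] = {}
    for taxon, features in inventories.items():
        names = {
            norm(f.gene if isinstance(f, GeneFeature) else f) for f in features
        }
        have[taxon] = names
    data = {
        taxon: [norm(g) in have[taxon] for g in query_genes] for taxon in taxa
    }
    return pd.DataFrame(data, index=query_genes)


def extract_shared_pcgs(
    inventories: dict[str, list[GeneFeature]],
    sequences: dict[str, dict[str, SeqRecord]],
) -> tuple[dict[str, dict[str, str]], dict[str, str]]:
    """Extract protein-coding genes present in every taxon.

    Returns ``(per_gene, concatenated)``: ``per_gene[gene][taxon]`` is
    the coding sequence in annotation orientation, and ``concatenated``
    joins the shared genes per taxon in fixed (sorted) gene order.  A
    taxon carrying duplicate copies of a shared gene with differing
    sequences is an error naming taxon and gene.
    """
    if len(inventories) < 2:
        raise ValueError("extract_shared_pcgs requires at least two taxa")
    per_taxon_genes: dict[str, dict[str, list[GeneFeature]]] = {}
    for taxon, features in inventories.items():
        genes: dict[str, list[GeneFeature]] = {}
        for feat in features:
            if feat.category == "PCG":
                genes.setdefault(feat.gene, []).append(feat)
        per_taxon_genes[taxon] = genes
    shared = sorted(
        set.intersection(*(set(g) for g in per_taxon_genes.values()))
        if per_taxon_genes
        else set()
    )
    if not shared:
        import warnings

        warnings.warn("taxa share no protein-coding genes")
        return {}, {taxon: "" for taxon in inventories}
    per_gene: dict[str, dict[str, str]] = {}
    for gene in shared:
        per_gene[gene] = {}
        for taxon in inventories:
            copies = {
                extract_gene_sequence(f, sequences[taxon])
                for f in per_taxon_genes[taxon][gene]
            }
            if len(copies) > 1:
                raise ValueError(
                    f"inconsistent duplicate sequences for gene {gene!r} "
                    f"in taxon {taxon!r}"
                )
            per_gene[gene][taxon] = copies.pop()
    concatenated = {
        taxon: "".join(per_gene[g][taxon] for g in shared) for taxon in inventories
    }
    return per_gene, concatenated
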