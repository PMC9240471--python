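import numpy as np
import pytest

from mitocircles.datasets import coding_partition_features
from mitocircles.io import GeneFeature, SeqRecord, revcomp
from mitocircles.report import (
    extract_shared_pcgs,
    gc_content,
    gene_inventory,
    partition_coding,
    presence_matrix,
    trans_chromosomal_genes,
)
from oracles import random_seq


class TestGC:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 50.0), ("AAAA", 0.0), ("GGCC", 100.0)])
    def test_simple(self, seq, expected):
        assert gc_content(SeqRecord("x", seq)) == expected

    def test_matches_direct_count_on_random_sequence(self, rng):
        seq = random_seq(rng, 10_000)
        expected = round(
            100 * (seq.count("G") + seq.count("C")) / len(seq), 2
        )
        assert gc_content(SeqRecord("x", seq)) == expected

    def test_invariant_under_reverse_complement(self, rng):
        seq = random_seq(rng, 5_000)
        assert gc_content(SeqRecord("x", seq)) == gc_content(
            SeqRecord("y", revcomp(seq))
        )

    def test_n_excluded_and_all_n_rejected(self):
        assert gc_content(SeqRecord("x", "GCNN")) == 100.0
        with pytest.raises(ValueError):
            gc_content(SeqRecord("x", "NNNN"))


class TestPartition:
    def test_published_component_arithmetic(self):
        features, sizes = coding_partition_features()
        stats = partition_coding(features, sizes)
        assert stats.coding_bp == 64_483
        assert stats.coding_pct == 8.25
        assert stats.intergenic_bp == 716_995
        assert stats.intergenic_pct == 91.75
        assert stats.trna_bp == 1_583
        assert stats.rrna_bp == 5_365
        assert stats.pcg_bp == 30_237
        assert stats.cis_intron_bp == 27_298

    def test_single_gene_partition(self):
        feats = [GeneFeature("cox1", "PCG", exons=[("c", 101, 200, "+")])]
        stats = partition_coding(feats, {"c": 1000})
        assert (stats.coding_bp, stats.intergenic_bp) == (100, 900)

    def test_partition_identity_holds_with_overlapping_genes(self):
        feats = [
            GeneFeature("g1", "PCG", exons=[("c", 1, 300, "+")]),
            GeneFeature("g2", "tRNA", exons=[("c", 250, 400, "-")]),
        ]
        stats = partition_coding(feats, {"c": 1000})
        assert stats.coding_bp + stats.intergenic_bp == stats.genome_size
        assert stats.coding_bp == 400  # union, not double-counted

    def test_exon_outside_bounds_rejected(self):
        feats = [GeneFeature("g", "PCG", exons=[("c", 900, 1100, "+")])]
        with pytest.raises(ValueError):
            partition_coding(feats, {"c": 1000})


def intron_fixture():
    """Gene set with the poplar mitogenome cis-intron structure:
    3 genes x1, 2 genes x2, 2 genes x3, 1 gene x4 = 17 cis introns; nad1
    and nad5 additionally trans-spliced across chromosomes."""

    def cis_gene(name, chrom, n_exons, start=1000, strand="+"):
        exons = []
        pos = start
        for _ in range(n_exons):
            exons.append((chrom, pos, pos + 99, strand))
            pos += 100 + 500  # 500-bp cis introns
        return GeneFeature(name, "PCG", exons=exons)

    feats = [
        cis_gene("rpl2", "mtChr1", 2),
        cis_gene("ccmFc", "mtChr1", 2, start=5000),
        cis_gene("rps3", "mtChr1", 2, start=9000),
        cis_gene("nad2", "mtChr2", 4, start=1000),
        cis_gene("nad4", "mtChr2", 4, start=9000),
        cis_gene("nad7", "mtChr3", 5, start=1000),
    ]
    # nad1: exon1 on mtChr2, exons 2-5 on mtChr1; the junction between the
    # two mtChr1 segments (exon3 -> exon4) is trans (distant, opposite strand)
    feats.append(
        GeneFeature(
            "nad1",
            "PCG",
            exons=[
                ("mtChr2", 50_000, 50_100, "+"),
                ("mtChr1", 20_000, 20_099, "+"),
                ("mtChr1", 20_600, 20_699, "+"),
                ("mtChr1", 80_000, 80_099, "-"),
                ("mtChr1", 80_600, 80_699, "-"),
            ],
        )
    )
    # nad5: exon3 on mtChr3, others on mtChr2 (two cis junctions there)
    feats.append(
        GeneFeature(
            "nad5",
            "PCG",
            exons=[
                ("mtChr2", 60_000, 60_099, "+"),
                ("mtChr2", 60_600, 60_699, "+"),
                ("mtChr3", 40_000, 40_099, "+"),
                ("mtChr2", 70_000, 70_099, "+"),
                ("mtChr2", 70_600, 70_699, "+"),
            ],
        )
    )
    return feats


class TestInventory:
    def test_cis_intron_histogram_matches_poplar_structure(self):
        inv = gene_inventory(intron_fixture())
        assert inv["intron_histogram"] == {1: 3, 2: 2, 3: 2, 4: 1}
        assert inv["total_cis_introns"] == 17

    def test_single_exon_gene_has_no_introns(self):
        inv = gene_inventory([GeneFeature("cox1", "PCG", exons=[("c", 1, 300, "+")])])
        assert inv["total_cis_introns"] == 0
        assert inv["intron_histogram"] == {}

    def test_duplicate_trna_names_reported(self):
        feats = [
            GeneFeature("trnM-CAU", "tRNA", exons=[("c", 1, 72, "+")]),
            GeneFeature("trnM-CAU", "tRNA", exons=[("c", 500, 571, "+")]),
            GeneFeature("trnP-UGG", "tRNA", exons=[("c", 1000, 1071, "+")]),
            GeneFeature("trnP-UGG", "tRNA", exons=[("c", 2000, 2071, "+")]),
            GeneFeature("trnC-GCA", "tRNA", exons=[("c", 3000, 3071, "+")]),
        ]
        inv = gene_inventory(feats)
        assert inv["duplicates"] == ["trnM-CAU", "trnP-UGG"]
        assert inv["counts"]["tRNA"] == 5
        assert inv["n_distinct_names"] == 3

    def test_codons_read_in_annotation_orientation(self):
        seq = "T" * 100 + "ATG" + "C" * 6 + "TAA" + "T" * 100
        chrom = SeqRecord("c", seq)
        feats = [GeneFeature("g", "PCG", exons=[("c", 101, 112, "+")])]
        inv = gene_inventory(feats, {"c": chrom})
        assert inv["codons"]["g"] == ("ATG", "TAA")
        rc = SeqRecord("c", revcomp(seq))
        start = len(seq) - 112 + 1
        feats_rc = [GeneFeature("g", "PCG", exons=[("c", start, start + 11, "-")])]
        assert gene_inventory(feats_rc, {"c": rc})["codons"]["g"] == ("ATG", "TAA")


class TestTransChromosomal:
    def test_poplar_fixture_exactly_nad1_nad5(self):
        trans = trans_chromosomal_genes(intron_fixture())
        assert set(trans) == {"nad1", "nad5"}
        assert trans["nad1"]["mtChr2"] == [1]
        assert trans["nad1"]["mtChr1"] == [2, 3, 4, 5]

    def test_single_chromosome_genes_empty(self):
        feats = [GeneFeature("cox1", "PCG", exons=[("c", 1, 300, "+")])]
        assert trans_chromosomal_genes(feats) == {}

    def test_three_way_split_reported_once(self):
        feat = GeneFeature(
            "g",
            "PCG",
            exons=[("c1", 1, 100, "+"), ("c2", 1, 100, "+"), ("c3", 1, 100, "+")],
        )
        trans = trans_chromosomal_genes([feat])
        assert list(trans) == ["g"]
        assert len(trans["g"]) == 3


class TestPresence:
    def poplar_inventories(self):
        core = ["cox1", "nad1", "rps14", "trnK-CUU", "atp1"]
        return {
            "P_alba": core,
            "P_tremula": core,
            "P_davidiana": core,
            "P_simonii": ["cox1", "nad1", "atp1"],  # rps14 and trnK-CUU lost
        }

    def test_rps14_and_trnK_lost_only_from_simonii(self):
        matrix = presence_matrix(self.poplar_inventories(), ["rps14", "trnK-CUU", "cox1"])
        assert list(matrix.loc["rps14"]) == [True, True, True, False]
        assert list(matrix.loc["trnK-CUU"]) == [True, True, True, False]
        assert matrix.loc["cox1"].all()

    def test_order_invariance(self):
        inv = self.poplar_inventories()
        m1 = presence_matrix(inv, ["rps14", "cox1"])
        m2 = presence_matrix(dict(reversed(list(inv.items()))), ["cox1", "rps14"])
        assert m1.loc["rps14", "P_simonii"] == m2.loc["rps14", "P_simonii"]

    def test_unknown_gene_row_of_absences(self):
        matrix = presence_matrix(self.poplar_inventories(), ["madeUpGene"])
        assert not matrix.loc["madeUpGene"].any()


class TestSharedPCGs:
    def make_taxa(self, rng, genes):
        inventories, sequences = {}, {}
        for taxon in ("t1", "t2"):
            feats, chrom_seq = [], random_seq(rng, 200)
            pos = len(chrom_seq) + 1
            for g in genes:
                cds = random_seq(rng, 30)
                chrom_seq += cds
                feats.append(
                    GeneFeature(g, "PCG", exons=[("c", pos, pos + 29, "+")])
                )
                pos += 30
            inventories[taxon] = feats
            sequences[taxon] = {"c": SeqRecord("c", chrom_seq)}
        return inventories, sequences

    def test_shared_genes_extracted_and_concatenated(self, rng):
        genes = [f"g{i:02d}" for i in range(22)]
        inventories, sequences = self.make_taxa(rng, genes)
        per_gene, concat = extract_shared_pcgs(inventories, sequences)
        assert len(per_gene) == 22
        for taxon in ("t1", "t2"):
            assert len(concat[taxon]) == sum(
                len(per_gene[g][taxon]) for g in per_gene
            )

    def test_no_shared_genes_warns_and_returns_empty(self, rng):
        inv, seqs = self.make_taxa(rng, ["a"])
        inv2, seqs2 = self.make_taxa(rng, ["b"])
        merged = {"t1": inv["t1"], "t2": inv2["t2"]}
        seqs_m = {"t1": seqs["t1"], "t2": seqs2["t2"]}
        with pytest.warns(UserWarning):
            per_gene, concat = extract_shared_pcgs(merged, seqs_m)
        assert per_gene == {}

    def test_inconsistent_duplicate_raises(self, rng):
        inv, seqs = self.make_taxa(rng, ["a"])
        dup = GeneFeature("a", "PCG", exons=[("c", 1, 30, "+")])
        inv["t1"] = inv["t1"] + [dup]
        with pytest.raises(ValueError, match="t1"):
            extract_shared_pcgs(inv, seqs)
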