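import numpy as np
import pytest

from mitocircles.datasets import dispersed_pairs_fixture
from mitocircles.io import SeqRecord, revcomp
from mitocircles.repeats import (
    SSRConfig,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    repeat_summary_table,
)
from oracles import dispersed_oracle, random_seq, ssr_oracle


def ssr_key(records):
    return {(r.motif, r.unit_length, r.copies, r.start, r.end) for r in records}


def pair_key(pairs):
    return {
        ((p.chrom1, p.start1), (p.chrom2, p.start2), p.length, p.orientation, p.mismatches)
        for p in pairs
    }


class TestSSR:
    @pytest.mark.parametrize(
        "seq,n_expected",
        [
            ("A" * 8 + "T", 1),  # mono threshold is 8 copies
            ("A" * 7 + "T", 0),
            ("ACACACAC" + "T", 1),  # di threshold is 4 copies
            ("ACACAC" + "T", 0),
            ("ACG" * 4 + "T", 1),
            ("ACGT" * 3 + "C", 1),
            ("ACGTA" * 3 + "C", 1),
            ("ACGTAG" * 3 + "C", 1),
        ],
    )
    def test_copy_thresholds(self, seq, n_expected):
        assert len(find_ssrs(SeqRecord("x", seq))) == n_expected

    def test_homopolymer_reports_as_primitive_mono_only(self):
        records = find_ssrs(SeqRecord("x", "G" * 12 + "T"))
        assert len(records) == 1
        assert (records[0].motif, records[0].copies) == ("G", 12)

    def test_matches_exhaustive_oracle_on_planted_sequences(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            seq = random_seq(rng, 500)
            # plant a few SSRs of assorted unit lengths
            for motif, copies in [("A", 9), ("AT", 5), ("ACG", 4), ("ACGT", 3)]:
                pos = int(rng.integers(0, 450))
                seq = seq[:pos] + motif * copies + seq[pos + len(motif) * copies :]
            assert ssr_key(find_ssrs(SeqRecord("t", seq))) == ssr_oracle(seq)

    def test_count_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            seq = random_seq(rng, 400) + "A" * 9 + random_seq(rng, 100)
            fwd = find_ssrs(SeqRecord("f", seq))
            rev = find_ssrs(SeqRecord("r", revcomp(seq)))
            assert len(fwd) == len(rev)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SSRConfig(min_repeats={1: 8})


class TestTandem:
    def test_13bp_unit_two_and_a_half_copies(self):
        unit = "ACGGTCATTGAAC"
        seq = "TT" + unit * 2 + unit[:7] + "GGCCGGCC"
        out = find_tandem_repeats(SeqRecord("t", seq))
        assert any(t.period == 13 and t.copies >= 2 for t in out)

    def test_seven_bp_copy_threshold(self):
        unit = "ACGTTGA"
        hit = find_tandem_repeats(SeqRecord("t", "CC" + unit * 3 + "GG"))
        assert any(t.period == 7 for t in hit)
        miss = find_tandem_repeats(SeqRecord("t", "CC" + unit + unit[:3] + "GG"))
        assert not miss

    def test_noisy_planted_tandems_recovered_with_correct_periods(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 1000)
        planted = []
        for period, copies, pos in [(11, 4, 100), (15, 3, 400), (20, 3, 700)]:
            unit = random_seq(rng, period)
            region = (unit * copies)[: period * copies]
            # ~5% divergence
            region = list(region)
            for _ in range(max(1, len(region) // 20)):
                i = int(rng.integers(0, len(region)))
                region[i] = "ACGT"[int(rng.integers(0, 4))]
            region = "".join(region)
            seq = seq[:pos] + region + seq[pos + len(region) :]
            planted.append((period, pos))
        out = find_tandem_repeats(SeqRecord("t", seq))
        for period, pos in planted:
            assert any(
                t.period == period and abs(t.start - 1 - pos) <= period
                for t in out
            ), (period, pos, out)


class TestDispersed:
    def test_planted_direct_pair_exact(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 2000)
        block = random_seq(rng, 40)
        # pin the flanking bases so the planted pair cannot extend by chance
        seq = seq[:299] + "A" + block + "A" + seq[341:1199] + "C" + block + "C" + seq[1241:]
        pairs = find_dispersed_repeats([SeqRecord("t", seq)], max_mismatch=0)
        assert [(p.start1, p.start2, p.length, p.mismatches, p.orientation) for p in pairs] == [
            (301, 1201, 40, 0, "direct")
        ]

    def test_planted_palindromic_pair(self):
        rng = np.random.default_rng(4)
        seq = random_seq(rng, 1500)
        block = random_seq(rng, 45)
        seq = (
            seq[:199] + "A" + block + "A" + seq[246:899]
            + "C" + revcomp(block) + "C" + seq[946:]
        )
        pairs = find_dispersed_repeats([SeqRecord("t", seq)], max_mismatch=0)
        assert [(p.start1, p.start2, p.length, p.orientation) for p in pairs] == [
            (201, 901, 45, "palindromic")
        ]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(8):
            seq = random_seq(rng, 500)
            block = random_seq(rng, 40)
            seq = seq[:100] + block + seq[140:300] + block + seq[340:]
            recs = [SeqRecord("t", seq)]
            assert pair_key(find_dispersed_repeats(recs)) == dispersed_oracle(recs)

    def test_cross_sequence_pairs(self):
        rng = np.random.default_rng(12)
        block = random_seq(rng, 50)
        r1 = SeqRecord("a", random_seq(rng, 400) + block + random_seq(rng, 100))
        r2 = SeqRecord("b", random_seq(rng, 200) + block + random_seq(rng, 300))
        pairs = find_dispersed_repeats([r1, r2], max_mismatch=0)
        assert any(p.chrom1 == "a" and p.chrom2 == "b" and p.length >= 50 for p in pairs)

    def test_monotonic_in_min_len_and_mismatch_budget(self):
        rng = np.random.default_rng(13)
        seq = random_seq(rng, 600)
        block = random_seq(rng, 60)
        seq = seq[:50] + block + seq[110:400] + block + seq[460:]
        recs = [SeqRecord("t", seq)]
        n = len(find_dispersed_repeats(recs, min_len=30, max_mismatch=3))
        assert len(find_dispersed_repeats(recs, min_len=50, max_mismatch=3)) <= n
        assert len(find_dispersed_repeats(recs, min_len=30, max_mismatch=1)) <= n

    def test_strand_invariance(self):
        rng = np.random.default_rng(14)
        seq = random_seq(rng, 500)
        block = random_seq(rng, 40)
        seq = seq[:100] + block + seq[140:300] + block + seq[340:]
        fwd = find_dispersed_repeats([SeqRecord("t", seq)])
        rev = find_dispersed_repeats([SeqRecord("t", revcomp(seq))])
        n = len(seq)
        mirrored = {
            tuple(
                sorted(
                    [
                        (p.chrom1, n - (p.start1 - 1 + p.length) + 1),
                        (p.chrom2, n - (p.start2 - 1 + p.length) + 1),
                    ]
                )
            )
            + (p.length, p.orientation)
            for p in rev
        }
        original = {
            tuple(sorted([(p.chrom1, p.start1), (p.chrom2, p.start2)]))
            + (p.length, p.orientation)
            for p in fwd
        }
        assert mirrored == original


class TestSummaryTable:
    def test_zero_repeats(self):
        table = repeat_summary_table({"g": ([], 1000)})
        row = table.loc["g"]
        assert row["n_repeats"] == 0
        assert row["proportion_pct"] == 0.0
        assert row["longest"] == 0

    def test_published_comparative_row(self):
        pairs, genome_len = dispersed_pairs_fixture("P_simonii")
        row = repeat_summary_table({"P_simonii": (pairs, genome_len)}).loc["P_simonii"]
        assert row["n_repeats"] == 322
        assert [row["30-49"], row["50-69"], row["70-99"], row["100-149"],
                row["150-199"], row["200-499"], row[">500"]] == [227, 49, 24, 11, 4, 7, 0]
        assert row["longest"] == 297
        assert row["total_repeat_length"] == 32_635
        assert row["proportion_pct"] == 4.18

    def test_union_never_exceeds_genome_length(self):
        for name in ("P_alba", "P_davidiana", "P_tremula"):
            pairs, genome_len = dispersed_pairs_fixture(name)
            row = repeat_summary_table({name: (pairs, genome_len)}).loc[name]
            assert row["total_repeat_length"] <= genome_len
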