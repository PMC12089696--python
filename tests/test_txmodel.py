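import random

import gffutils
import pandas as pd
import pytest

from slicetally.errors import GffStructureError, RefMismatchError, RegionBoundsError
from slicetally.regions import GenomicInterval
from slicetally.txmodel import (
    TranscriptModel, disjoint_bins, equivalence_class, fix_missing_txs,
    genomic_to_tx, project_gff3, transcript_models_from_gff, tx_to_genomic,
    variant_span,
)

from oracles import brute_force_eq_class, make_bam, random_transcript_model


def two_exon_tx(strand):
    return TranscriptModel(
        tx_id="T", gene_id="G", gene_name="G", contig="chr1", strand=strand,
        exons=(GenomicInterval("chr1", 101, 200, strand),
               GenomicInterval("chr1", 301, 400, strand)),
    )


class TestCoordinateProjection:
    @pytest.mark.parametrize("strand,gpos,tpos", [
        ("+", 350, 150), ("-", 350, 51),
        ("+", 101, 1), ("-", 400, 1),
        ("+", 400, 200), ("-", 101, 200),
    ])
    def test_genomic_to_tx(self, strand, gpos, tpos):
        assert genomic_to_tx(two_exon_tx(strand), gpos) == tpos

    def test_intronic_position_unmapped(self):
        assert genomic_to_tx(two_exon_tx("+"), 250) is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_tx_to_genomic_inverts(self, strand):
        tx = two_exon_tx(strand)
        assert tx_to_genomic(tx, genomic_to_tx(tx, 350)) == 350

    def test_first_transcript_base_plus_strand(self):
        assert tx_to_genomic(two_exon_tx("+"), 1) == 101

    def test_out_of_range_transcript_position(self):
        tx = two_exon_tx("+")
        with pytest.raises(RegionBoundsError):
            tx_to_genomic(tx, tx.tx_length + 1)

    def test_round_trip_on_random_models_both_strands(self):
        rng = random.Random(11)
        for _ in range(100):
            tx = random_transcript_model(rng)
            for exon in tx.exons:
                for g in range(exon.start, exon.end + 1):
                    assert tx_to_genomic(tx, genomic_to_tx(tx, g)) == g


GFF_TEMPLATE = """##gff-version 3
chr1\tt\tgene\t101\t400\t.\t{strand}\t.\tID=G;gene_name=G
chr1\tt\ttranscript\t101\t400\t.\t{strand}\t.\tID=T;Parent=G;transcript_id=T
chr1\tt\texon\t101\t200\t.\t{strand}\t.\tID=T.e1;Parent=T
chr1\tt\texon\t301\t400\t.\t{strand}\t.\tID=T.e2;Parent=T
"""


class TestProjectGff3:
    def _tx_attrs(self, out_path):
        db = gffutils.create_db(str(out_path), ":memory:",
                                merge_strategy="create_unique", keep_order=True)
        attrs = {}
        for exon in db.features_of_type("exon"):
            attrs[(exon.start, exon.end)] = (
                int(exon.attributes["tx_start"][0]),
                int(exon.attributes["tx_end"][0]),
            )
        return attrs

    def test_plus_strand_exon_intervals(self, tmp_path):
        src = tmp_path / "in.gff3"
        src.write_text(GFF_TEMPLATE.format(strand="+"))
        out = tmp_path / "out.gff3"
        project_gff3(src, out)
        attrs = self._tx_attrs(out)
        assert attrs[(101, 200)] == (1, 100)
        assert attrs[(301, 400)] == (101, 200)

    def test_minus_strand_exon_intervals_reversed(self, tmp_path):
        src = tmp_path / "in.gff3"
        src.write_text(GFF_TEMPLATE.format(strand="-"))
        out = tmp_path / "out.gff3"
        project_gff3(src, out)
        attrs = self._tx_attrs(out)
        assert attrs[(301, 400)] == (1, 100)
        assert attrs[(101, 200)] == (101, 200)

    def test_single_exon_identity(self, tmp_path):
        src = tmp_path / "in.gff3"
        src.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t1\t50\t.\t+\t.\tID=G;gene_name=G\n"
            "chr1\tt\ttranscript\t1\t50\t.\t+\t.\tID=T;Parent=G\n"
            "chr1\tt\texon\t1\t50\t.\t+\t.\tID=T.e1;Parent=T\n"
        )
        out = tmp_path / "out.gff3"
        project_gff3(src, out)
        assert self._tx_attrs(out)[(1, 50)] == (1, 50)

    def test_exon_outside_transcript_span_is_structural_error(self, tmp_path):
        src = tmp_path / "in.gff3"
        src.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t1\t500\t.\t+\t.\tID=G;gene_name=G\n"
            "chr1\tt\ttranscript\t1\t50\t.\t+\t.\tID=T;Parent=G\n"
            "chr1\tt\texon\t60\t90\t.\t+\t.\tID=T.e1;Parent=T\n"
        )
        with pytest.raises(GffStructureError):
            project_gff3(src, tmp_path / "out.gff3")

    def test_output_remains_standard_parseable_gff3(self, fixture_paths, tmp_path):
        out = tmp_path / "dual.gff3"
        project_gff3(fixture_paths["gff3"], out)
        db = gffutils.create_db(str(out), ":memory:",
                                merge_strategy="create_unique", keep_order=True)
        assert len(list(db.features_of_type("gene"))) == 2
        for exon in db.features_of_type("exon"):
            lo = int(exon.attributes["tx_start"][0])
            hi = int(exon.attributes["tx_end"][0])
            assert hi - lo == exon.end - exon.start  # length preserved


def pattern_gene():
    """Three single-exon transcripts in the containment pattern."""
    def tx(tx_id, start, end):
        return TranscriptModel(
            tx_id=tx_id, gene_id="G", gene_name="G", contig="chr1", strand="+",
            exons=(GenomicInterval("chr1", start, end, "+"),),
        )
    return [tx("T1", 100, 180), tx("T2", 100, 200), tx("T3", 140, 200)]


class TestDisjointBins:
    def test_containment_pattern_three_bins(self):
        bins = disjoint_bins(pattern_gene())
        got = [((b.genomic.start, b.genomic.end), sorted(b.tx_members)) for b in bins]
        assert got == [
            ((100, 139), ["T1", "T2"]),
            ((140, 180), ["T1", "T2", "T3"]),
            ((181, 200), ["T2", "T3"]),
        ]

    def test_single_transcript_one_bin_per_exon(self):
        tx = two_exon_tx("+")
        bins = disjoint_bins([tx])
        assert [(b.genomic.start, b.genomic.end) for b in bins] == [(101, 200), (301, 400)]
        assert all(b.tx_members == {"T"} for b in bins)

    def test_identical_transcripts_share_all_bins(self):
        a = two_exon_tx("+")
        b = TranscriptModel(tx_id="T2", gene_id="G", gene_name="G",
                            contig="chr1", strand="+", exons=a.exons)
        bins = disjoint_bins([a, b])
        assert all(bn.tx_members == {"T", "T2"} for bn in bins)

    def test_bins_tile_exons_and_match_per_base_membership(self):
        rng = random.Random(23)
        for _ in range(25):
            txs = [random_transcript_model(rng) for _ in range(rng.randint(1, 4))]
            bins = disjoint_bins(txs)
            # no overlaps between bins
            for x, y in zip(bins, bins[1:]):
                assert x.genomic.end < y.genomic.start
            by_id = {t.tx_id: t for t in txs}
            # per-base membership equals membership of the containing bin,
            # and bins cover exactly the exon union
            union = set()
            for t in txs:
                for e in t.exons:
                    union.update(range(e.start, e.end + 1))
            covered = set()
            for b in bins:
                for p in range(b.genomic.start, b.genomic.end + 1):
                    covered.add(p)
                    naive = {t.tx_id for t in txs
                             if any(e.start <= p <= e.end for e in t.exons)}
                    assert naive == set(b.tx_members)
            assert covered == union
            # each transcript's bins tile its exons via per-tx coordinates
            for b in bins:
                for txid in b.tx_members:
                    lo, hi = b.per_tx[txid]
                    assert hi - lo == b.genomic.end - b.genomic.start
                    assert 1 <= lo <= hi <= by_id[txid].tx_length


class TestEquivalenceClass:
    def test_snv_inside_all_three(self):
        txs = pattern_gene()
        ec = equivalence_class("chr1", 150, "A", "T", disjoint_bins(txs), txs)
        assert ec.tx_set == {"T1", "T2", "T3"}
        assert ec.per_tx_position == {"T1": 51, "T2": 51, "T3": 11}

    def test_deletion_spanning_two_bins_intersects(self):
        txs = pattern_gene()
        ref = "N" * 11  # anchored deletion spanning genomic 135..145
        ec = equivalence_class("chr1", 135, ref, ref[0], disjoint_bins(txs), txs)
        assert variant_span(135, ref, ref[0]) == (135, 145)
        assert ec.tx_set == {"T1", "T2"}

    def test_variant_outside_all_exons_empty(self):
        txs = pattern_gene()
        ec = equivalence_class("chr1", 50, "A", "T", disjoint_bins(txs), txs)
        assert ec.tx_set == frozenset()

    def test_span_beyond_exon_union_is_empty_not_partial(self):
        txs = pattern_gene()
        ref = "N" * 10  # spans 195..204, past the exon union end at 200
        ec = equivalence_class("chr1", 195, ref, ref[0], disjoint_bins(txs), txs)
        assert ec.tx_set == frozenset()

    def test_classes_match_brute_force_on_random_models(self):
        rng = random.Random(31)
        for _ in range(30):
            txs = [random_transcript_model(rng) for _ in range(rng.randint(1, 4))]
            bins = disjoint_bins(txs)
            lo = min(t.span.start for t in txs) - 5
            hi = max(t.span.end for t in txs) + 5
            for _ in range(20):
                pos = rng.randint(lo, hi)
                kind = rng.choice(["SNV", "DEL", "INS"])
                if kind == "SNV":
                    ref, alt = "A", "T"
                elif kind == "DEL":
                    ref, alt = "A" + "N" * rng.randint(1, 12), "A"
                else:
                    ref, alt = "A", "A" + "N" * rng.randint(1, 12)
                ec = equivalence_class("chr1", pos, ref, alt, bins, txs)
                span = variant_span(pos, ref, alt)
                assert set(ec.tx_set) == brute_force_eq_class(txs, "chr1", span)


class TestFixMissingTxs:
    def _setup(self, tmp_path):
        rng = random.Random(41)
        txs = pattern_gene()
        # per-transcript sequences share the genomic sequence of chr1:100-200
        genomic = "".join(rng.choice("ACGT") for _ in range(101))  # bases 100..200
        seqs = {"T1": genomic[0:81], "T2": genomic[0:101], "T3": genomic[40:101]}
        lengths = {k: len(v) for k, v in seqs.items()}
        ref_base = genomic[50]  # g=150 -> T2 position 51
        alt_base = "A" if ref_base != "A" else "C"
        reads = []
        for i in range(20):  # coverage on T2 only; 8 carry the alt
            seq = list(seqs["T2"][21: 81])
            if i < 8:
                seq[51 - 22] = alt_base
            reads.append({"name": f"t{i}", "contig": "T2", "start": 22,
                          "seq": "".join(seq), "cigar": [(0, 60)]})
        bam = make_bam(tmp_path / "tx.bam", lengths, reads)
        tally = pd.DataFrame([{
            "contig": "T2", "position": 51, "ref": ref_base, "alt": alt_base,
            "variant_type": "SNV", "alt_depth": 8, "ref_depth": 12,
            "total_depth": 20, "vaf": 0.4, "file_id": "s1",
        }])
        ec = equivalence_class("chr1", 150, ref_base, alt_base,
                               disjoint_bins(txs), txs)
        return txs, seqs, bam, tally, ec

    def test_missing_members_gain_retallied_rows(self, tmp_path):
        txs, seqs, bam, tally, ec = self._setup(tmp_path)
        out = fix_missing_txs(tally, [ec], {"s1": bam}, txs, tx_sequences=seqs)
        assert set(out.contig) == {"T1", "T2", "T3"}
        t1 = out[out.contig == "T1"].iloc[0]
        assert (t1.position, t1.total_depth, t1.vaf) == (51, 0, 0.0)  # zero kept
        t3 = out[out.contig == "T3"].iloc[0]
        assert t3.position == 11
        assert t3.total_depth == 0

    def test_all_members_present_table_unchanged(self, tmp_path):
        txs, seqs, bam, tally, ec = self._setup(tmp_path)
        full = pd.concat([tally] + [
            tally.assign(contig=t, position=p)
            for t, p in (("T1", 51), ("T3", 11))
        ], ignore_index=True)
        out = fix_missing_txs(full, [ec], {"s1": bam}, txs, tx_sequences=seqs)
        pd.testing.assert_frame_equal(
            out.sort_values(["contig"]).reset_index(drop=True),
            full.sort_values(["contig"]).reset_index(drop=True),
        )

    def test_transcript_absent_from_bam_header_is_error(self, tmp_path):
        txs, seqs, bam, tally, ec = self._setup(tmp_path)
        slim = make_bam(tmp_path / "slim.bam", {"T2": 101}, [])
        with pytest.raises(RefMismatchError):
            fix_missing_txs(tally, [ec], {"s1": slim}, txs, tx_sequences=seqs)
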