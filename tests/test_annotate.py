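import pandas as pd
import pysam
import pytest

from slicetally.annotate import (
    export_maf, parse_vep_csq, predict_consequence, predict_consequence_tx,
    read_maf_variants, read_vcf_variants, to_vep_vcf,
)
from slicetally.errors import CsqFormatError, RefMismatchError
from slicetally.regions import GenomicInterval
from slicetally.txmodel import (
    TranscriptModel, genomic_to_tx, variant_to_tx,
)


# A plus-strand toy transcript: exon chr1:6-25, CDS chr1:11-19 (ATG GCC TAA)
GENOME = {"chr1": "AACCGTTGGA" + "ATGGCCTAA" + "GGTTACCGGA" + "ACGT" * 5}


def toy_tx():
    return TranscriptModel(
        tx_id="TOY", gene_id="G", gene_name="TOYGENE", contig="chr1", strand="+",
        exons=(GenomicInterval("chr1", 6, 25, "+"),),
        cds=(GenomicInterval("chr1", 11, 19, "+"),),
    )


class TestPredictConsequence:
    def test_missense_codon_substitution(self):
        rec = predict_consequence("chr1", 14, "G", "A", toy_tx(), GENOME)
        assert (rec.ref_codon, rec.alt_codon) == ("GCC", "ACC")
        assert (rec.ref_aa, rec.alt_aa, rec.protein_position) == ("A", "T", 2)
        assert rec.consequence == "missense"
        assert rec.hgvsp == "p.A2T"
        assert rec.aa_change == "A 2 T"

    def test_synonymous_third_position(self):
        rec = predict_consequence("chr1", 16, "C", "G", toy_tx(), GENOME)
        assert (rec.ref_codon, rec.alt_codon) == ("GCC", "GCG")
        assert rec.consequence == "synonymous"

    def test_stop_lost(self):
        rec = predict_consequence("chr1", 18, "A", "C", toy_tx(), GENOME)
        assert rec.consequence == "stop_lost"
        assert rec.region_label == "stop_codon"

    def test_start_lost(self):
        rec = predict_consequence("chr1", 11, "A", "G", toy_tx(), GENOME)
        assert rec.consequence == "start_lost"
        assert rec.region_label == "start_codon"

    def test_nonsense(self):
        genome = {"chr1": "AACCGTTGGA" + "ATGTACTAA" + "GGTTACCGGA"}
        rec = predict_consequence("chr1", 16, "C", "A", toy_tx(), genome)
        assert rec.alt_codon == "TAA"
        assert rec.consequence == "nonsense"

    def test_inframe_vs_frameshift_insertion(self):
        rec3 = predict_consequence("chr1", 14, "G", "GTTT", toy_tx(), GENOME)
        assert rec3.consequence == "inframe_insertion"
        rec2 = predict_consequence("chr1", 14, "G", "GTT", toy_tx(), GENOME)
        assert rec2.consequence == "frameshift"

    def test_inframe_deletion(self):
        # delete genomic 15..17 (CCT): anchored at 14
        rec = predict_consequence("chr1", 14, "GCCT", "G", toy_tx(), GENOME)
        assert rec.consequence == "inframe_deletion"

    def test_five_prime_utr(self):
        rec = predict_consequence("chr1", 8, "G", "C", toy_tx(), GENOME)
        assert (rec.region_label, rec.consequence) == ("five_prime_UTR", "utr_variant")

    def test_three_prime_utr(self):
        rec = predict_consequence("chr1", 22, "T", "A", toy_tx(), GENOME)
        assert (rec.region_label, rec.consequence) == ("three_prime_UTR", "utr_variant")

    def test_noncoding_transcript(self):
        tx = TranscriptModel(
            tx_id="NC", gene_id="G", gene_name="G", contig="chr1", strand="+",
            exons=(GenomicInterval("chr1", 6, 25, "+"),),
        )
        rec = predict_consequence("chr1", 14, "G", "A", tx, GENOME)
        assert (rec.region_label, rec.consequence) == ("noncoding", "noncoding_variant")

    def test_ref_mismatch_guards_coordinate_bugs(self):
        with pytest.raises(RefMismatchError):
            predict_consequence("chr1", 14, "T", "A", toy_tx(), GENOME)

    def test_intronic_position(self):
        tx = TranscriptModel(
            tx_id="T2E", gene_id="G", gene_name="G", contig="chr1", strand="+",
            exons=(GenomicInterval("chr1", 6, 12, "+"),
                   GenomicInterval("chr1", 20, 25, "+")),
        )
        rec = predict_consequence("chr1", 15, "C", "G", tx, GENOME)
        assert rec.region_label == "intronic"


class TestDualPathAgreement:
    """Genomic-space and transcript-space predictions must coincide."""

    def test_spiked_cds_variants_agree(self, fixture_paths, study_spec):
        from slicetally.synthdata import gene_models

        truth = pd.read_csv(fixture_paths["truth_genomic"], sep="\t")
        models = [m for m in gene_models(study_spec) if m.cds]
        genome = str(fixture_paths["reference"])
        tx_fa = pysam.FastaFile(str(fixture_paths["tx_fasta"]))
        checked = 0
        for _, v in truth.iterrows():
            for tx in models:
                if genomic_to_tx(tx, int(v.position)) is None:
                    continue
                g_rec = predict_consequence(
                    str(v.contig), int(v.position), str(v.ref), str(v.alt),
                    tx, genome,
                )
                tx_seq = tx_fa.fetch(tx.tx_id)
                tpos, t_ref, t_alt = variant_to_tx(
                    tx, int(v.position), str(v.ref), str(v.alt), tx_seq=tx_seq
                )
                t_rec = predict_consequence_tx(tx, tpos, t_ref, t_alt,
                                               {tx.tx_id: tx_seq})
                assert g_rec.consequence == t_rec.consequence, tx.tx_id
                assert g_rec.region_label == t_rec.region_label
                assert g_rec.protein_position == t_rec.protein_position
                assert (g_rec.ref_aa, g_rec.alt_aa) == (t_rec.ref_aa, t_rec.alt_aa)
                checked += 1
        tx_fa.close()
        assert checked >= 3  # all three spikes hit coding transcripts


class TestVepVcf:
    def _table(self):
        return pd.DataFrame([
            {"contig": "chr2", "position": 50, "ref": "AT", "alt": "A",
             "variant_type": "DEL", "file_id": "s1"},
            {"contig": "chr1", "position": 10, "ref": "G", "alt": "C",
             "variant_type": "SNV", "file_id": "s1"},
            {"contig": "chr1", "position": 10, "ref": "G", "alt": "C",
             "variant_type": "SNV", "file_id": "s2"},  # duplicate across samples
        ])

    def test_round_trip_sorted_deduplicated(self, tmp_path):
        out = tmp_path / "v.vcf"
        to_vep_vcf(self._table(), out)
        keys = read_vcf_variants(out)
        assert keys == [("chr1", 10, "G", "C"), ("chr2", 50, "AT", "A")]

    def test_empty_table_header_only(self, tmp_path):
        out = tmp_path / "e.vcf"
        to_vep_vcf(self._table().iloc[0:0], out)
        assert read_vcf_variants(out) == []
        assert out.read_text().startswith("##fileformat=VCF")


CSQ_VCF = """##fileformat=VCFv4.2
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: Allele|Consequence|IMPACT|SYMBOL">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t100\t.\tA\tT\t.\t.\tCSQ=T|missense_variant|MODERATE|GENEA,T|synonymous_variant||
"""


class TestParseCsq:
    def test_entries_exploded_one_row_each(self, tmp_path):
        p = tmp_path / "csq.vcf"
        p.write_text(CSQ_VCF)
        df = parse_vep_csq(p)
        assert len(df) == 2
        assert list(df.columns) == ["contig", "position", "ref", "alt",
                                    "Allele", "Consequence", "IMPACT", "SYMBOL"]
        assert df.iloc[0].Consequence == "missense_variant"

    def test_empty_subfields_become_empty_strings(self, tmp_path):
        p = tmp_path / "csq.vcf"
        p.write_text(CSQ_VCF)
        df = parse_vep_csq(p)
        assert df.iloc[1].IMPACT == ""
        assert df.iloc[1].SYMBOL == ""

    def test_missing_csq_declaration_is_format_error(self, tmp_path):
        p = tmp_path / "plain.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tT\t.\t.\t.\n"
        )
        with pytest.raises(CsqFormatError):
            parse_vep_csq(p)


class TestExportMaf:
    def _row(self, **kw):
        base = {
            "contig": "chr1", "position": 14, "ref": "G", "alt": "A",
            "variant_type": "SNV", "gene_name": "TOYGENE",
            "consequence": "missense", "region_label": "CDS",
            "hgvsp": "p.A2T", "aa_change": "A 2 T", "file_id": "s1",
            "alt_depth": 10, "ref_depth": 30, "total_depth": 40,
        }
        base.update(kw)
        return base

    def test_missense_snv_mapping(self, tmp_path):
        out = tmp_path / "m.maf"
        export_maf(pd.DataFrame([self._row()]), out)
        df = pd.read_csv(out, sep="\t")
        row = df.iloc[0]
        assert row.Variant_Type == "SNP"
        assert row.Variant_Classification == "Missense_Mutation"
        assert (row.Start_Position, row.End_Position) == (14, 14)
        assert (row.t_depth, row.t_ref_count, row.t_alt_count) == (40, 30, 10)

    def test_deletion_anchor_stripped(self, tmp_path):
        out = tmp_path / "d.maf"
        export_maf(pd.DataFrame([self._row(
            position=100, ref="AT", alt="A", variant_type="DEL",
            consequence="frameshift",
        )]), out)
        row = pd.read_csv(out, sep="\t").iloc[0]
        assert row.Start_Position == 101
        assert row.Reference_Allele == "T"
        assert row.Tumor_Seq_Allele2 == "-"
        assert row.Variant_Classification == "Frame_Shift_Del"

    def test_insertion_convention(self, tmp_path):
        out = tmp_path / "i.maf"
        export_maf(pd.DataFrame([self._row(
            position=100, ref="A", alt="ATTG", variant_type="INS",
            consequence="inframe_insertion",
        )]), out)
        row = pd.read_csv(out, sep="\t").iloc[0]
        assert (row.Start_Position, row.End_Position) == (100, 101)
        assert row.Reference_Allele == "-"
        assert row.Tumor_Seq_Allele2 == "TTG"

    def test_empty_input_header_only(self, tmp_path):
        out = tmp_path / "e.maf"
        export_maf(pd.DataFrame(columns=["contig", "position", "ref", "alt"]), out)
        df = pd.read_csv(out, sep="\t")
        assert df.empty
        assert "Hugo_Symbol" in df.columns

    def test_unknown_consequence_classified_unknown(self, tmp_path):
        out = tmp_path / "u.maf"
        export_maf(pd.DataFrame([self._row(consequence="mystery")]), out)
        assert pd.read_csv(out, sep="\t").iloc[0].Variant_Classification == "Unknown"

    def test_round_trip_variant_keys_with_reference(self, tmp_path):
        genome = {"chr1": "A" * 99 + "GTACGTACGT" + "C" * 100}
        rows = [
            self._row(position=14, ref="A", alt="T"),
            self._row(position=100, ref="GT", alt="G", variant_type="DEL",
                      consequence="frameshift"),
            self._row(position=105, ref="T", alt="TAC", variant_type="INS",
                      consequence="frameshift"),
        ]
        out = tmp_path / "rt.maf"
        export_maf(pd.DataFrame(rows), out)
        keys = read_maf_variants(out, reference=genome)
        assert keys == [("chr1", 14, "A", "T"), ("chr1", 100, "GT", "G"),
                        ("chr1", 105, "T", "TAC")]
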