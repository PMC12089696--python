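"""Consequence prediction and VCF/MAF interchange.

Predicts coding consequences of tallied variants directly from the gene
models and reference sequence — codon substitution through the standard
genetic code for SNVs, the length-mod-3 rule for indels, and UTR /
start-codon / stop-codon awareness — and converts tallies to the standard
interchange formats: a sites-only VCF suitable as VEP input, ingestion of
VEP's CSQ INFO annotations, and MAF export for cancer-genomics tooling.

Prediction works in either coordinate space: from genomic coordinates plus a
genome FASTA, or from transcript coordinates plus a transcript FASTA (for
variants tallied on transcriptome-aligned BAMs). Both routes classify the
same way, so they must agree for any exonic variant — a useful end-to-end
check of the coordinate projection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import pysam
from Bio.Seq import Seq

from .errors import CsqFormatError, RefMismatchError
from .txmodel import TranscriptModel, genomic_to_tx, variant_to_tx

logger = logging.getLogger(__name__)

REGION_LABELS = (
    "CDS", "five_prime_UTR", "three_prime_UTR", "start_codon", "stop_codon",
    "noncoding", "intronic",
)

# consequence -> MAF Variant_Classification (indels resolved by variant type)
MAF_CLASSIFICATION = {
    "synonymous": "Silent",
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "stop_lost": "Nonstop_Mutation",
    "start_lost": "Translation_Start_Site",
    "frameshift_INS": "Frame_Shift_Ins",
    "frameshift_DEL": "Frame_Shift_Del",
    "inframe_insertion": "In_Frame_Ins",
    "inframe_deletion": "In_Frame_Del",
    "utr_variant_five_prime_UTR": "5'UTR",
    "utr_variant_three_prime_UTR": "3'UTR",
    "noncoding_variant": "RNA",
    "intronic_variant": "Intron",
}

MAF_COLUMNS = [
    "Hugo_Symbol", "Chromosome", "Start_Position", "End_Position",
    "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
    "Variant_Type", "HGVSp_Short", "Protein_Change", "Tumor_Sample_Barcode",
    "t_depth", "t_ref_count", "t_alt_count",
]


@dataclass(frozen=True)
class ConsequenceRecord:
    """Predicted effect of one variant on one transcript."""

    contig: str
    position: int
    ref: str
    alt: str
    tx_id: str
    gene_name: str
    region_label: str
    consequence: str
    ref_codon: str = ""
    alt_codon: str = ""
    ref_aa: str = ""
    alt_aa: str = ""
    protein_position: int = 0
    aa_change: str = ""   # compact, e.g. "A 2 T" or "V 114 VNHL"
    hgvsp: str = ""       # e.g. "p.A2T", "p.K28fs"
    note: str = ""


class SequenceSource:
    """Uniform 1-based closed fetch over a FASTA path, pysam handle or dict."""

    def __init__(self, source: Union[str, pysam.FastaFile, Mapping[str, str]]):
        self._dict: Optional[Mapping[str, str]] = None
        self._fasta: Optional[pysam.FastaFile] = None
        if isinstance(source, Mapping):
            self._dict = source
        elif isinstance(source, pysam.FastaFile):
            self._fasta = source
        else:
            self._fasta = pysam.FastaFile(str(source))

    def fetch(self, contig: str, start: int, end: int) -> str:
        if self._dict is not None:
            return self._dict[contig][start - 1: end].upper()
        return self._fasta.fetch(contig, start - 1, end).upper()


def spliced_tx_sequence(tx: TranscriptModel, genome: SequenceSource) -> str:
    """Transcript sequence: exons concatenated 5'->3' (revcomp on '-')."""
    seq = "".join(
        genome.fetch(tx.contig, e.start, e.end)
        for e in sorted(tx.exons, key=lambda e: e.start)
    )
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def cds_tx_interval(tx: TranscriptModel) -> Optional[tuple[int, int]]:
    """The CDS as a 1-based closed interval in transcript coordinates."""
    if not tx.cds:
        return None
    positions = []
    for c in tx.cds:
        positions.append(genomic_to_tx(tx, c.start))
        positions.append(genomic_to_tx(tx, c.end))
    return min(positions), max(positions)


def _classify_tx(
    tx: TranscriptModel,
    tx_seq: str,
    tpos: int,
    t_ref: str,
    t_alt: str,
    contig: str,
    position: int,
    ref: str,
    alt: str,
    note: str = "",
) -> ConsequenceRecord:
    """Classify a transcript-space variant against the spliced sequence."""
    base = dict(contig=contig, position=position, ref=ref, alt=alt,
                tx_id=tx.tx_id, gene_name=tx.gene_name, note=note)
    cds = cds_tx_interval(tx)
    is_snv = len(t_ref) == len(t_alt) == 1
    if cds is None:
        return ConsequenceRecord(
            region_label="noncoding", consequence="noncoding_variant", **base
        )
    cds_lo, cds_hi = cds
    if tpos < cds_lo:
        return ConsequenceRecord(
            region_label="five_prime_UTR", consequence="utr_variant", **base
        )
    if tpos > cds_hi:
        return ConsequenceRecord(
            region_label="three_prime_UTR", consequence="utr_variant", **base
        )
    cds_seq = tx_seq[cds_lo - 1: cds_hi]
    cds_pos = tpos - cds_lo + 1
    region_label = "CDS"
    if cds_pos <= 3:
        region_label = "start_codon"
    elif cds_pos > len(cds_seq) - 3:
        region_label = "stop_codon"
    protein_position = math.ceil(cds_pos / 3)

    if is_snv:
        codon_idx = (cds_pos - 1) // 3
        within = (cds_pos - 1) % 3
        ref_codon = cds_seq[codon_idx * 3: codon_idx * 3 + 3]
        if len(ref_codon) < 3:  # CDS truncated by annotation; cannot translate
            return ConsequenceRecord(
                region_label=region_label, consequence="noncoding_variant",
                protein_position=protein_position, **base,
            )
        alt_codon = ref_codon[:within] + t_alt + ref_codon[within + 1:]
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            consequence = "synonymous"
        elif alt_aa == "*":
            consequence = "nonsense"
        elif ref_aa == "*":
            consequence = "stop_lost"
        elif codon_idx == 0 and ref_codon == "ATG":
            consequence = "start_lost"
        else:
            consequence = "missense"
        return ConsequenceRecord(
            region_label=region_label, consequence=consequence,
            ref_codon=ref_codon, alt_codon=alt_codon,
            ref_aa=ref_aa, alt_aa=alt_aa, protein_position=protein_position,
            aa_change=f"{ref_aa} {protein_position} {alt_aa}",
            hgvsp=f"p.{ref_aa}{protein_position}{alt_aa}"
            if consequence != "synonymous" else f"p.{ref_aa}{protein_position}=",
            **base,
        )

    # indel
    delta = abs(len(t_ref) - len(t_alt))
    is_ins = len(t_alt) > len(t_ref)
    if delta % 3 != 0:
        consequence = "frameshift"
        codon_idx = (cds_pos - 1) // 3
        ref_codon = cds_seq[codon_idx * 3: codon_idx * 3 + 3]
        ref_aa = str(Seq(ref_codon).translate()) if len(ref_codon) == 3 else ""
        return ConsequenceRecord(
            region_label=region_label, consequence=consequence,
            ref_codon=ref_codon, ref_aa=ref_aa,
            protein_position=protein_position,
            aa_change=f"{ref_aa} {protein_position} fs",
            hgvsp=f"p.{ref_aa}{protein_position}fs",
            **base,
        )
    consequence = "inframe_insertion" if is_ins else "inframe_deletion"
    codon_idx = (cds_pos - 1) // 3
    ref_codon = cds_seq[codon_idx * 3: codon_idx * 3 + 3]
    ref_aa = str(Seq(ref_codon).translate()) if len(ref_codon) == 3 else ""
    mut_cds = (
        cds_seq[:cds_pos - 1] + t_alt + cds_seq[cds_pos - 1 + len(t_ref):]
    )
    n_codons = 1 + (delta // 3 if is_ins else 0)
    alt_codon = mut_cds[codon_idx * 3: codon_idx * 3 + 3 * n_codons]
    alt_aa = str(Seq(alt_codon).translate()) if len(alt_codon) % 3 == 0 else ""
    return ConsequenceRecord(
        region_label=region_label, consequence=consequence,
        ref_codon=ref_codon, alt_codon=alt_codon,
        ref_aa=ref_aa, alt_aa=alt_aa, protein_position=protein_position,
        aa_change=f"{ref_aa} {protein_position} {alt_aa}",
        hgvsp=f"p.{ref_aa}{protein_position}"
        + (f"delins{alt_aa}" if not is_ins or alt_aa[:1] != ref_aa
           else f"ins{alt_aa[1:]}"),
        **base,
    )


def predict_consequence(
    contig: str,
    position: int,
    ref: str,
    alt: str,
    tx: TranscriptModel,
    genome,
) -> ConsequenceRecord:
    """Predict the consequence of a genomic-space variant on one transcript.

    The ref allele is validated against the reference sequence (a mismatch
    raises :class:`RefMismatchError` — it almost always means a coordinate
    bug upstream). Variants inside the transcript span but not exonic are
    labelled ``intronic``; a CDS indel whose span leaves exon space gets a
    ``splice_region`` note instead of a bespoke splice model.
    """
    source = genome if isinstance(genome, SequenceSource) else SequenceSource(genome)
    observed = source.fetch(contig, position, position + len(ref) - 1)
    if observed != ref.upper():
        raise RefMismatchError(
            f"ref allele {ref!r} does not match reference {observed!r} at "
            f"{contig}:{position}"
        )
    tpos = genomic_to_tx(tx, position)
    if tpos is None:
        return ConsequenceRecord(
            contig=contig, position=position, ref=ref, alt=alt,
            tx_id=tx.tx_id, gene_name=tx.gene_name,
            region_label="intronic", consequence="noncoding_variant",
        )
    tx_seq = spliced_tx_sequence(tx, source)
    note = ""
    span_end = position + len(ref) - 1
    if len(ref) > 1 and genomic_to_tx(tx, span_end) is None:
        note = "splice_region"
        t_ref, t_alt = ref, alt  # span leaves exon space; classify by length only
        tpos_eff = tpos
    else:
        tpos_eff, t_ref, t_alt = variant_to_tx(tx, position, ref, alt, tx_seq=tx_seq)
    return _classify_tx(
        tx, tx_seq, tpos_eff, t_ref, t_alt, contig, position, ref, alt, note=note
    )


def predict_consequences(
    contig: str, position: int, ref: str, alt: str,
    transcripts: Sequence[TranscriptModel], genome,
) -> list[ConsequenceRecord]:
    """One :class:`ConsequenceRecord` per transcript whose span contains the variant."""
    source = genome if isinstance(genome, SequenceSource) else SequenceSource(genome)
    out = []
    for tx in transcripts:
        if tx.span.contains(contig, position):
            out.append(predict_consequence(contig, position, ref, alt, tx, source))
    return out


def predict_consequence_tx(
    tx: TranscriptModel,
    tpos: int,
    t_ref: str,
    t_alt: str,
    tx_fasta,
) -> ConsequenceRecord:
    """Predict from transcript coordinates and a transcript FASTA directly.

    This is the route for variants tallied on transcriptome-aligned BAMs;
    the transcript sequence comes from the FASTA the reads were aligned to
    (keyed by transcript id), not from the genome.
    """
    source = tx_fasta if isinstance(tx_fasta, SequenceSource) else SequenceSource(tx_fasta)
    tx_seq = source.fetch(tx.tx_id, 1, tx.tx_length)
    observed = tx_seq[tpos - 1: tpos - 1 + len(t_ref)]
    if observed != t_ref.upper():
        raise RefMismatchError(
            f"transcript ref allele {t_ref!r} does not match {observed!r} at "
            f"{tx.tx_id}:{tpos}"
        )
    return _classify_tx(
        tx, tx_seq, tpos, t_ref, t_alt, tx.tx_id, tpos, t_ref, t_alt
    )


# ---------------------------------------------------------------------------
# VCF / CSQ / MAF interchange
# ---------------------------------------------------------------------------

def to_vep_vcf(table: pd.DataFrame, out_vcf) -> None:
    """Write unique variants as a sorted sites-only VCF (VEP-ready input).

    One record per distinct (contig, position, ref, alt) across all samples;
    unsorted input is sorted, never rejected.
    """
    header = pysam.VariantHeader()
    header.add_line('##source=slicetally')
    contigs = sorted(set(table["contig"])) if len(table) else []
    for c in contigs:
        header.contigs.add(str(c))
    keys = sorted(
        {(str(r.contig), int(r.position), str(r.ref), str(r.alt))
         for r in table.itertuples()}
    ) if len(table) else []
    with pysam.VariantFile(str(out_vcf), "w", header=header) as vcf:
        for contig, pos, ref, alt in keys:
            rec = vcf.new_record(
                contig=contig, start=pos - 1, stop=pos - 1 + len(ref),
                alleles=(ref, alt),
            )
            vcf.write(rec)


def read_vcf_variants(vcf_path) -> list[tuple[str, int, str, str]]:
    """Variant keys (contig, pos, ref, alt) from a VCF, expanded per alt."""
    out = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                out.append((rec.contig, rec.pos, rec.ref, alt))
    return out


def parse_vep_csq(vep_vcf) -> pd.DataFrame:
    """Explode VEP's CSQ INFO field into one row per variant per annotation.

    The CSQ subfield names come from the header's ``Format:`` declaration;
    comma separates annotation entries, pipe separates subfields within an
    entry. Empty subfields become empty strings.
    """
    with pysam.VariantFile(str(vep_vcf)) as vcf:
        info = vcf.header.info.get("CSQ")
        if info is None:
            raise CsqFormatError("VCF header does not declare a CSQ INFO field")
        desc = info.description or ""
        if "Format:" not in desc:
            raise CsqFormatError(
                "CSQ INFO description lacks the 'Format:' subfield list"
            )
        fields = desc.split("Format:", 1)[1].strip().strip('"').split("|")
        fields = [f.strip() for f in fields]
        rows = []
        for rec in vcf:
            csq = rec.info.get("CSQ")
            if csq is None:
                continue
            entries = csq if isinstance(csq, (tuple, list)) else (csq,)
            for entry in entries:
                parts = entry.split("|")
                parts += [""] * (len(fields) - len(parts))
                row = {
                    "contig": rec.contig, "position": rec.pos,
                    "ref": rec.ref, "alt": (rec.alts or ("",))[0],
                }
                row.update(dict(zip(fields, parts)))
                rows.append(row)
    cols = ["contig", "position", "ref", "alt"] + fields
    return pd.DataFrame(rows, columns=cols)


def _maf_classification(row) -> str:
    cons = row.get("consequence", "")
    if cons == "frameshift":
        key = f"frameshift_{row.get('variant_type', '')}"
    elif cons == "utr_variant":
        key = f"utr_variant_{row.get('region_label', '')}"
    elif cons == "noncoding_variant" and row.get("region_label") == "intronic":
        key = "intronic_variant"
    else:
        key = cons
    cls = MAF_CLASSIFICATION.get(key)
    if cls is None:
        logger.warning("unannotated or unknown consequence %r -> Unknown", cons)
        return "Unknown"
    return cls


def export_maf(table: pd.DataFrame, out_maf) -> None:
    """Write an annotated tally table as a Mutation Annotation Format file.

    Applies the MAF indel convention: the shared anchor base is stripped, a
    deletion starts one past the anchor with Tumor_Seq_Allele2 ``-``, and an
    insertion spans the two flanking bases with Reference_Allele ``-``.
    Rows lacking annotation are classified ``Unknown`` with a warning.
    """
    out_rows = []
    for _, row in table.iterrows():
        ref, alt, pos = str(row["ref"]), str(row["alt"]), int(row["position"])
        vtype = row.get("variant_type", "SNV")
        if vtype == "SNV":
            maf_type, start, end = "SNP", pos, pos
            maf_ref, maf_alt = ref, alt
        elif vtype == "DEL":
            deleted = ref[1:]
            maf_type, start, end = "DEL", pos + 1, pos + len(deleted)
            maf_ref, maf_alt = deleted, "-"
        else:
            inserted = alt[1:]
            maf_type, start, end = "INS", pos, pos + 1
            maf_ref, maf_alt = "-", inserted
        out_rows.append({
            "Hugo_Symbol": row.get("gene_name", ""),
            "Chromosome": row["contig"],
            "Start_Position": start,
            "End_Position": end,
            "Reference_Allele": maf_ref,
            "Tumor_Seq_Allele2": maf_alt,
            "Variant_Classification": _maf_classification(row),
            "Variant_Type": maf_type,
            "HGVSp_Short": row.get("hgvsp", ""),
            "Protein_Change": row.get("aa_change", ""),
            "Tumor_Sample_Barcode": row.get("file_id", ""),
            "t_depth": row.get("total_depth", 0),
            "t_ref_count": row.get("ref_depth", 0),
            "t_alt_count": row.get("alt_depth", 0),
        })
    pd.DataFrame(out_rows, columns=MAF_COLUMNS).to_csv(out_maf, sep="\t", index=False)


def read_maf_variants(maf_path, reference=None) -> list[tuple[str, int, str, str]]:
    """Recover anchored (contig, pos, ref, alt) keys from a MAF file.

    Indels need ``reference`` (FASTA path/handle/dict) to restore the anchor
    base the MAF convention strips; SNPs round-trip without it.
    """
    df = pd.read_csv(maf_path, sep="\t", keep_default_na=False)
    src = None
    if reference is not None:
        src = reference if isinstance(reference, SequenceSource) else SequenceSource(reference)
    out = []
    for _, row in df.iterrows():
        contig = str(row["Chromosome"])
        start = int(row["Start_Position"])
        ref, alt = str(row["Reference_Allele"]), str(row["Tumor_Seq_Allele2"])
        if row["Variant_Type"] == "SNP":
            out.append((contig, start, ref, alt))
        elif row["Variant_Type"] == "DEL":
            anchor_pos = start - 1
            anchor = src.fetch(contig, anchor_pos, anchor_pos) if src else "N"
            out.append((contig, anchor_pos, anchor + ref, anchor))
        else:
            anchor = src.fetch(contig, start, start) if src else "N"
            out.append((contig, start, anchor, anchor + alt))
    return out
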