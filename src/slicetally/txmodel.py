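"""Dual-coordinate transcript annotation.

Projects GFF3 features into transcript coordinates, builds per-gene disjoint
exon bins, computes transcript equivalence classes for variants, and re-tallies
equivalence-class transcripts missing from a transcriptome tally.

Transcript coordinates are 1-based and closed, counted 5'->3' along the
transcript: on the minus strand position 1 is the transcript base at the
highest genomic coordinate. This matches BAM files aligned to a transcript
FASTA, where each transcript id is a reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd

from .errors import GffStructureError, RegionBoundsError
from .regions import GenomicInterval, open_gff

UNMAPPED = None  # sentinel for intronic / out-of-span positions


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its exon and CDS structure in genomic coordinates.

    ``exons`` are ordered 5'->3' along the transcript (descending genomic
    coordinate on the minus strand); they must be pairwise non-overlapping.
    ``cds`` intervals are base-wise contained in the exons.
    """

    tx_id: str
    gene_id: str
    gene_name: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        ivs = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise GffStructureError(
                    f"transcript {self.tx_id}: overlapping exons {a} and {b}"
                )
        exon_bases = set()
        for e in self.exons:
            exon_bases.update(range(e.start, e.end + 1))
        for c in self.cds:
            if not set(range(c.start, c.end + 1)) <= exon_bases:
                raise GffStructureError(
                    f"transcript {self.tx_id}: CDS {c} not contained in exons"
                )

    @property
    def tx_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    def exons_5to3(self) -> list[GenomicInterval]:
        """Exons ordered along the transcript (reverse genomic order on '-')."""
        return sorted(self.exons, key=lambda e: e.start, reverse=self.strand == "-")


def genomic_to_tx(tx: TranscriptModel, gpos: int) -> Optional[int]:
    """Map a genomic position to a 1-based transcript coordinate.

    Returns ``None`` for intronic or out-of-span positions (not an error).
    """
    offset = 0
    for exon in tx.exons_5to3():
        if exon.start <= gpos <= exon.end:
            if tx.strand == "-":
                return offset + (exon.end - gpos) + 1
            return offset + (gpos - exon.start) + 1
        offset += len(exon)
    return UNMAPPED


def tx_to_genomic(tx: TranscriptModel, tpos: int) -> int:
    """Map a 1-based transcript coordinate back to its genomic position.

    Exact inverse of :func:`genomic_to_tx` on exonic bases; out-of-range
    ``tpos`` raises :class:`RegionBoundsError`.
    """
    if tpos < 1 or tpos > tx.tx_length:
        raise RegionBoundsError(
            f"transcript position {tpos} outside [1, {tx.tx_length}] for {tx.tx_id}"
        )
    offset = 0
    for exon in tx.exons_5to3():
        if tpos <= offset + len(exon):
            within = tpos - offset - 1
            if tx.strand == "-":
                return exon.end - within
            return exon.start + within
        offset += len(exon)
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# GFF3 ingestion and dual-coordinate projection
# ---------------------------------------------------------------------------

_TX_TYPES = ("mRNA", "transcript")
_TX_SCOPED = ("exon", "CDS", "five_prime_UTR", "three_prime_UTR", "start_codon", "stop_codon")


def _tx_feature_id(feat) -> str:
    ids = feat.attributes.get("transcript_id") or feat.attributes.get("ID") or [feat.id]
    return ids[0]


def transcript_models_from_gff(annotation, gene_names: Optional[Sequence[str]] = None,
                               ) -> list[TranscriptModel]:
    """Build :class:`TranscriptModel` objects from a (GENCODE-dialect) GFF3."""
    db = open_gff(annotation)
    wanted = set(gene_names) if gene_names else None
    models = []
    for gene in db.features_of_type("gene"):
        names = gene.attributes.get("gene_name", []) or gene.attributes.get("Name", [])
        gene_name = names[0] if names else gene.id
        if wanted is not None and gene_name not in wanted:
            continue
        gene_id = (gene.attributes.get("gene_id") or [gene.id])[0]
        for tx in db.children(gene, level=1):
            if tx.featuretype not in _TX_TYPES:
                continue
            exons = [
                GenomicInterval(e.seqid, e.start, e.end, tx.strand)
                for e in db.children(tx, featuretype="exon")
            ]
            if not exons:
                continue
            cds = [
                GenomicInterval(c.seqid, c.start, c.end, tx.strand)
                for c in db.children(tx, featuretype="CDS")
            ]
            for e in exons:
                if not (tx.start <= e.start and e.end <= tx.end):
                    raise GffStructureError(
                        f"exon {e} outside span of transcript {_tx_feature_id(tx)}"
                    )
            models.append(
                TranscriptModel(
                    tx_id=_tx_feature_id(tx),
                    gene_id=gene_id,
                    gene_name=gene_name,
                    contig=tx.seqid,
                    strand=tx.strand,
                    exons=tuple(sorted(exons, key=lambda e: e.start)),
                    cds=tuple(sorted(cds, key=lambda c: c.start)),
                )
            )
    return models


def project_gff3(gff3_in, gff3_out) -> None:
    """Write a dual-coordinate GFF3: each transcript-scoped feature gains
    ``tx_id``, ``tx_start`` and ``tx_end`` attributes carrying its 1-based
    closed interval on the parent transcript. Hierarchy, feature order and
    original attributes are preserved, and the output stays valid GFF3.
    """
    db = open_gff(gff3_in)
    tx_by_id: dict[str, TranscriptModel] = {}
    for gene in db.features_of_type("gene"):
        for tx in db.children(gene, level=1):
            if tx.featuretype not in _TX_TYPES:
                continue
            exons = [
                GenomicInterval(e.seqid, e.start, e.end, tx.strand)
                for e in db.children(tx, featuretype="exon")
            ]
            if not exons:
                continue
            for e in exons:
                if not (tx.start <= e.start and e.end <= tx.end):
                    raise GffStructureError(
                        f"exon {e} outside span of transcript {_tx_feature_id(tx)}"
                    )
            tx_by_id[tx.id] = TranscriptModel(
                tx_id=_tx_feature_id(tx),
                gene_id=gene.id,
                gene_name=gene.id,
                contig=tx.seqid,
                strand=tx.strand,
                exons=tuple(sorted(exons, key=lambda e: e.start)),
            )

    with open(gff3_out, "w") as out:
        out.write("##gff-version 3\n")
        for feat in db.all_features(order_by=("seqid", "start")):
            if feat.featuretype in _TX_SCOPED:
                parents = feat.attributes.get("Parent", [])
                for pid in parents:
                    model = tx_by_id.get(pid)
                    if model is None:
                        continue
                    t1 = genomic_to_tx(model, feat.start)
                    t2 = genomic_to_tx(model, feat.end)
                    if t1 is None or t2 is None:
                        raise GffStructureError(
                            f"{feat.featuretype} {feat.id or feat.start} not exonic "
                            f"in transcript {model.tx_id}"
                        )
                    lo, hi = sorted((t1, t2))
                    feat.attributes["tx_id"] = [model.tx_id]
                    feat.attributes["tx_start"] = [str(lo)]
                    feat.attributes["tx_end"] = [str(hi)]
                    break
            out.write(str(feat) + "\n")


# ---------------------------------------------------------------------------
# Disjoint bins and equivalence classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisjointBin:
    """A maximal exon segment of one gene with constant transcript membership."""

    genomic: GenomicInterval
    tx_members: frozenset[str]
    per_tx: Mapping[str, tuple[int, int]] = field(hash=False, default_factory=dict)


@dataclass(frozen=True)
class EquivalenceClass:
    """Transcripts whose exons contain a variant's full genomic span."""

    contig: str
    position: int
    ref: str
    alt: str
    tx_set: frozenset[str]
    per_tx_position: Mapping[str, int] = field(hash=False, default_factory=dict)


def disjoint_bins(transcripts: Sequence[TranscriptModel]) -> list[DisjointBin]:
    """Disjoin the exon union of one gene into maximal constant-membership bins.

    Segments are cut at every exon boundary, then genomically contiguous
    segments with identical transcript membership are merged, so each bin is
    the maximal run over which the set of overlapping transcripts is constant.
    Per-transcript coordinates of every bin are filled for all members.
    """
    if not transcripts:
        return []
    contig = transcripts[0].contig
    cuts: set[int] = set()
    for tx in transcripts:
        for e in tx.exons:
            cuts.add(e.start)
            cuts.add(e.end + 1)
    bounds = sorted(cuts)
    raw: list[tuple[int, int, frozenset[str]]] = []
    for lo, hi_excl in zip(bounds, bounds[1:]):
        members = frozenset(
            tx.tx_id
            for tx in transcripts
            if any(e.start <= lo and hi_excl - 1 <= e.end for e in tx.exons)
        )
        if members:
            raw.append((lo, hi_excl - 1, members))
    merged: list[tuple[int, int, frozenset[str]]] = []
    for seg in raw:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] + 1 == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    by_id = {tx.tx_id: tx for tx in transcripts}
    bins = []
    for lo, hi, members in merged:
        per_tx = {}
        for txid in sorted(members):
            t1 = genomic_to_tx(by_id[txid], lo)
            t2 = genomic_to_tx(by_id[txid], hi)
            per_tx[txid] = (min(t1, t2), max(t1, t2))
        bins.append(DisjointBin(GenomicInterval(contig, lo, hi), members, per_tx))
    return bins


def variant_span(position: int, ref: str, alt: str) -> tuple[int, int]:
    """Genomic span a variant occupies for equivalence-class membership.

    SNV: the single substituted base. Deletion (anchored, ref longer than
    alt): anchor through the last deleted base. Insertion (anchored, alt
    longer than ref): anchor base plus the following base, so an insertion at
    an exon-exon junction is assigned only to transcripts containing both
    flanking bases.
    """
    if len(ref) == len(alt) == 1:
        return position, position
    if len(ref) > len(alt):  # deletion
        return position, position + len(ref) - 1
    return position, position + 1  # insertion


def equivalence_class(
    contig: str,
    position: int,
    ref: str,
    alt: str,
    bins: Sequence[DisjointBin],
    transcripts: Optional[Sequence[TranscriptModel]] = None,
) -> EquivalenceClass:
    """Equivalence class of a variant from a gene's disjoint bins.

    The class is the intersection of ``tx_members`` over all bins overlapping
    the variant span; if any spanned base falls outside every bin (intron or
    beyond the exon union) the class is empty, so the result always equals
    the set of transcripts whose exons contain the entire span.
    """
    lo, hi = variant_span(position, ref, alt)
    covered = 0
    tx_set: Optional[frozenset[str]] = None
    for b in bins:
        if b.genomic.contig != contig or b.genomic.end < lo or b.genomic.start > hi:
            continue
        covered += min(hi, b.genomic.end) - max(lo, b.genomic.start) + 1
        tx_set = b.tx_members if tx_set is None else tx_set & b.tx_members
    if tx_set is None or covered < hi - lo + 1:
        tx_set = frozenset()
    per_tx_position: dict[str, int] = {}
    if transcripts:
        by_id = {t.tx_id: t for t in transcripts}
        for txid in sorted(tx_set):
            tx = by_id.get(txid)
            if tx is not None:
                tpos = genomic_to_tx(tx, position)
                if tpos is not None:
                    per_tx_position[txid] = tpos
    return EquivalenceClass(contig, position, ref, alt, tx_set, per_tx_position)


def variant_to_tx(
    tx: TranscriptModel, position: int, ref: str, alt: str, tx_seq: Optional[str] = None
) -> tuple[int, str, str]:
    """Re-express an anchored genomic variant in transcript coordinates.

    Returns ``(tx_position, tx_ref, tx_alt)``. On the minus strand alleles
    are reverse-complemented and indels re-anchored so that the transcript
    representation is again left-anchored. ``tx_seq`` (the spliced transcript
    sequence) is required to fill the anchor base of minus-strand indels.
    """
    from Bio.Seq import Seq

    if len(ref) == len(alt) == 1:  # SNV
        tpos = genomic_to_tx(tx, position)
        if tpos is None:
            raise RegionBoundsError(f"position {position} not exonic in {tx.tx_id}")
        if tx.strand == "-":
            return tpos, str(Seq(ref).reverse_complement()), str(Seq(alt).reverse_complement())
        return tpos, ref, alt

    if tx.strand == "+":
        tpos = genomic_to_tx(tx, position)
        if tpos is None:
            raise RegionBoundsError(f"anchor {position} not exonic in {tx.tx_id}")
        return tpos, ref, alt

    # minus strand indel: payload reverse-complemented, new anchor is the
    # transcript base just 5' of the reverse-complemented payload
    payload = ref[1:] if len(ref) > len(alt) else alt[1:]
    rc = str(Seq(payload).reverse_complement())
    if len(ref) > len(alt):  # deletion of genomic [position+1, position+d]
        d = len(payload)
        t_after = genomic_to_tx(tx, position + d)  # 5'-most deleted base on tx
        if t_after is None:
            raise RegionBoundsError(f"deletion span not exonic in {tx.tx_id}")
        anchor_t = t_after - 1
        if anchor_t < 1 or tx_seq is None:
            raise RegionBoundsError(
                f"cannot anchor minus-strand deletion in {tx.tx_id} (need tx_seq)"
            )
        anchor_base = tx_seq[anchor_t - 1]
        return anchor_t, anchor_base + rc, anchor_base
    # insertion between genomic position and position+1
    t_next = genomic_to_tx(tx, position + 1)
    if t_next is None:
        raise RegionBoundsError(f"insertion flank not exonic in {tx.tx_id}")
    anchor_t = t_next - 1
    if anchor_t < 1 or tx_seq is None:
        raise RegionBoundsError(
            f"cannot anchor minus-strand insertion in {tx.tx_id} (need tx_seq)"
        )
    anchor_base = tx_seq[anchor_t - 1]
    return anchor_t, anchor_base, anchor_base + rc


def fix_missing_txs(
    tx_tally: pd.DataFrame,
    eq_classes: Iterable[EquivalenceClass],
    tx_bams: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    tx_sequences: Optional[Mapping[str, str]] = None,
    min_mapq: int = 0,
    min_base_quality: int = 0,
) -> pd.DataFrame:
    """Add re-tallied rows for equivalence-class transcripts absent from a tally.

    ``tx_tally`` is keyed by (file_id, contig=tx_id, position=transcript
    coordinate). For every (variant, sample), each member transcript with no
    row gains one whose depths come from re-piling the transcriptome BAM at
    the computed transcript coordinate; zero-depth rows are retained so
    transcripts with few or no mapped reads still get annotated.
    """
    import pysam

    from .tally import compute_vaf, position_coverage

    by_id = {t.tx_id: t for t in transcripts}
    new_rows = []
    file_ids = sorted(tx_bams)
    for ec in eq_classes:
        for file_id in file_ids:
            bam_path = tx_bams[file_id]
            with pysam.AlignmentFile(str(bam_path)) as bam:
                refs = set(bam.references)
                for txid in sorted(ec.tx_set):
                    tx = by_id[txid]
                    if txid not in refs:
                        from .errors import RefMismatchError

                        raise RefMismatchError(
                            f"transcript {txid} absent from BAM header of {bam_path}"
                        )
                    tpos, t_ref, t_alt = variant_to_tx(
                        tx, ec.position, ec.ref, ec.alt,
                        tx_seq=(tx_sequences or {}).get(txid),
                    )
                    present = tx_tally[
                        (tx_tally["contig"] == txid)
                        & (tx_tally["position"] == tpos)
                        & (tx_tally["alt"] == t_alt)
                        & (tx_tally["file_id"] == file_id)
                    ]
                    if len(present):
                        continue
                    total = position_coverage(
                        bam, txid, tpos, min_mapq=min_mapq,
                    )
                    alt_depth = _alt_depth_at(
                        bam, txid, tpos, t_ref, t_alt, min_mapq, min_base_quality
                    )
                    new_rows.append(
                        {
                            "contig": txid,
                            "position": tpos,
                            "ref": t_ref,
                            "alt": t_alt,
                            "variant_type": _variant_type(t_ref, t_alt),
                            "alt_depth": alt_depth,
                            "ref_depth": max(total - alt_depth, 0),
                            "total_depth": total,
                            "vaf": compute_vaf(alt_depth, total),
                            "file_id": file_id,
                        }
                    )
    if not new_rows:
        return tx_tally.copy()
    added = pd.DataFrame(new_rows)
    out = pd.concat([tx_tally, added], ignore_index=True)
    return out.sort_values(
        ["contig", "position", "alt", "file_id"], kind="mergesort"
    ).reset_index(drop=True)


def _variant_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    return "DEL" if len(ref) > len(alt) else "INS"


def _alt_depth_at(bam, contig, pos, ref, alt, min_mapq, min_base_quality) -> int:
    """Count reads supporting one specific allele at a single position."""
    from .tally import TallyParams, tally_reads_open

    rows = tally_reads_open(
        bam,
        GenomicInterval(contig, pos, pos),
        TallyParams(min_mapq=min_mapq, min_base_quality=min_base_quality),
    )
    for r in rows:
        if r["position"] == pos and r["ref"] == ref and r["alt"] == alt:
            return r["alt_depth"]
    return 0
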