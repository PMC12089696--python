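"""Genomic region model and gene-to-exon-region extraction.

Coordinates are 1-based and closed throughout the public API, matching GFF3,
samtools region syntax, and pileup conventions. Region strings of the form
``contig:start-end`` (hyphen or en-dash) are the unit of targeted slicing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .errors import GeneLookupError, RegionBoundsError, RegionParseError

_REGION_RE = re.compile(r"^([^:\s]+):(\d+)[-–—](\d+)$")

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contig-anchored 1-based closed interval.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded). ``start`` and
    ``end`` are both inclusive; a single base has ``start == end``.
    """

    contig: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self):
        if not self.contig:
            raise RegionParseError("contig name must be non-empty")
        if self.start < 1:
            raise RegionBoundsError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise RegionBoundsError(
                f"start > end in {self.contig}:{self.start}-{self.end} "
                "(intervals are not silently swapped)"
            )
        if self.strand not in VALID_STRANDS:
            raise RegionParseError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, contig: str, pos: int) -> bool:
        return self.contig == contig and self.start <= pos <= self.end


def parse_region(text: str) -> GenomicInterval:
    """Parse ``contig:start-end`` into a :class:`GenomicInterval`.

    Both ASCII hyphen and en-dash separate the bounds; thousands separators
    are rejected. ``start > end`` raises :class:`RegionBoundsError` rather
    than being swapped.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(f"malformed region string: {text!r} (expected contig:start-end)")
    contig, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    return GenomicInterval(contig, start, end)


def format_region(interval: GenomicInterval) -> str:
    """Render an interval as ``contig:start-end`` (inverse of :func:`parse_region`)."""
    return f"{interval.contig}:{interval.start}-{interval.end}"


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Coalesce overlapping or book-ended intervals on the same contig.

    Returns the merged union sorted by (contig, start). Strand is dropped
    (merged intervals are unstranded).
    """
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    out: list[GenomicInterval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda i: (i.start, i.end))
        cur_start, cur_end = None, None
        for iv in ivs:
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start <= cur_end + 1:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            out.append(GenomicInterval(contig, cur_start, cur_end))
    return out


def open_gff(annotation) -> gffutils.FeatureDB:
    """Return a gffutils FeatureDB from a path or pass an existing DB through."""
    if isinstance(annotation, gffutils.FeatureDB):
        return annotation
    return gffutils.create_db(
        str(Path(annotation)),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


def _gene_features_by_name(db: gffutils.FeatureDB, gene_names: Sequence[str]):
    wanted = set(gene_names)
    found: dict[str, list] = {}
    for gene in db.features_of_type("gene"):
        names = gene.attributes.get("gene_name", []) or gene.attributes.get("Name", [])
        for name in names:
            if name in wanted:
                found.setdefault(name, []).append(gene)
    missing = [n for n in gene_names if n not in found]
    if missing:
        raise GeneLookupError(missing)
    return found


def exon_regions_for_genes(annotation, gene_names: Sequence[str]) -> list[GenomicInterval]:
    """Merged union of exon intervals of all transcripts of the named genes.

    Exons are unioned per gene (overlapping/adjacent exons coalesced), then
    the per-gene lists are concatenated and sorted by contig then start.
    Unknown gene symbols raise :class:`GeneLookupError` naming the offenders.
    """
    if not gene_names:
        return []
    db = open_gff(annotation)
    found = _gene_features_by_name(db, gene_names)
    per_gene: list[GenomicInterval] = []
    for name in gene_names:
        exons: list[GenomicInterval] = []
        for gene in found[name]:
            for exon in db.children(gene, featuretype="exon"):
                exons.append(GenomicInterval(exon.seqid, exon.start, exon.end))
        per_gene.extend(merge_intervals(exons))
    # final pass keeps the output pairwise non-overlapping even when genes overlap
    return merge_intervals(per_gene)
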