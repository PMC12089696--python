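"""Pileup-based variant tallying.

Walks pileup columns over requested regions and emits one row per
(sample, site, alt allele) with read-count evidence: ``alt_depth`` (reads
supporting the alternate allele), ``ref_depth``, ``total_depth`` and
``vaf = alt_depth / total_depth``.

Semantics
---------
* Reads flagged unmapped/duplicate/secondary/supplementary/QC-fail are
  excluded, as are reads below ``min_mapq``.
* For SNVs, bases below ``min_base_quality`` are excluded from both the alt
  and the total count; ``total_depth`` at an SNV site is the number of reads
  contributing a passing base.
* Indels are anchored VCF-style: position is the base before the event, a
  deletion's ref includes the deleted bases, an insertion's alt includes the
  inserted bases. An indel call requires its anchor base to pass
  ``min_base_quality`` (this is how the samtools pileup engine masks reads).
* Overlapping mate pairs are counted independently (no overlap correction),
  so a naive per-read scan reproduces the counts exactly.

Because a multi-base deletion makes the reference depth at the event
ambiguous, :func:`fix_indel_ref_counts` rescans the BAM around each indel and
replaces ``total_depth`` with either the covering-read depth at the anchor
(``at_start``) or the mean flanking coverage (``flank_mean``).
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .errors import ContigError, ParameterError
from .regions import GenomicInterval

# UNMAP | SECONDARY | QCFAIL | DUP | SUPPLEMENTARY
EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800

TALLY_COLUMNS = [
    "contig", "position", "ref", "alt", "variant_type",
    "alt_depth", "ref_depth", "total_depth", "vaf", "file_id",
]


@dataclass(frozen=True)
class TallyParams:
    """Quality thresholds and parallelism degrees for tallying."""

    min_mapq: int = 0
    min_base_quality: int = 0
    max_depth_cap: int = 1_000_000
    workers_files: int = 1
    workers_ranges: int = 1

    def __post_init__(self):
        if self.min_mapq < 0 or self.min_base_quality < 0:
            raise ParameterError("quality thresholds must be >= 0")
        if self.workers_files < 1 or self.workers_ranges < 1:
            raise ParameterError("worker counts must be >= 1")


@dataclass(frozen=True)
class VariantTally:
    """One allele observation in one sample."""

    contig: str
    position: int
    ref: str
    alt: str
    variant_type: str  # SNV | INS | DEL
    alt_depth: int
    ref_depth: int
    total_depth: int
    vaf: float
    file_id: str


@dataclass(frozen=True)
class FilterSpec:
    """Strict lower bounds on VAF and total depth for variant filtering."""

    min_vaf: float = 0.15
    min_total_depth: int = 8

    def __post_init__(self):
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ParameterError(f"min_vaf must lie in [0, 1], got {self.min_vaf}")


def compute_vaf(alt_depth: int, total_depth: int) -> float:
    """Variant allele frequency alt_depth / total_depth; 0 when depth is 0."""
    if total_depth < 0:
        raise ParameterError("total_depth must be >= 0")
    if alt_depth > total_depth:
        raise ParameterError(
            f"alt_depth {alt_depth} exceeds total_depth {total_depth}"
        )
    if total_depth == 0:
        return 0.0
    return alt_depth / total_depth


def _normalize_bams(bams) -> list[tuple[str, str]]:
    """Accept a list of paths, (file_id, path) pairs, or a mapping."""
    if isinstance(bams, Mapping):
        return [(fid, str(p)) for fid, p in sorted(bams.items())]
    out = []
    for item in bams:
        if isinstance(item, (tuple, list)):
            out.append((str(item[0]), str(item[1])))
        else:
            out.append((Path(item).stem, str(item)))
    return out


def tally_reads_open(
    bam: pysam.AlignmentFile,
    region: GenomicInterval,
    params: TallyParams,
    reference: Optional[pysam.FastaFile] = None,
) -> list[dict]:
    """Tally one region of one open BAM; returns unsorted row dicts.

    When ``reference`` is None the MD-tag-free path is used: the reference
    base is taken from the pileup consensus of reads without the variant,
    which requires a reference for correctness — so a reference FASTA is
    strongly recommended and required for genomic BAMs. For transcriptome
    BAMs whose reference sequences are not at hand, the majority base is
    used as ref (adequate at high depth).
    """
    if region.contig not in bam.references:
        raise ContigError(
            f"contig {region.contig!r} absent from BAM header of {bam.filename.decode() if isinstance(bam.filename, bytes) else bam.filename}"
        )
    if reference is not None and region.contig not in reference.references:
        raise ContigError(
            f"contig {region.contig!r} present in BAM but absent from reference "
            f"{reference.filename}"
        )
    rows: list[dict] = []
    for col in bam.pileup(
        region.contig,
        region.start - 1,
        region.end,
        truncate=True,
        stepper="samtools",
        min_base_quality=params.min_base_quality,
        min_mapping_quality=params.min_mapq,
        ignore_overlaps=False,
        ignore_orphans=False,
        flag_filter=EXCLUDE_FLAGS,
        max_depth=params.max_depth_cap,
    ):
        pos1 = col.reference_pos + 1
        base_counts: dict[str, int] = {}
        ins_counts: dict[str, int] = {}
        del_counts: dict[int, int] = {}
        total = 0
        for pr in col.pileups:
            if pr.is_refskip:
                continue
            if not pr.is_del:
                base = pr.alignment.query_sequence[pr.query_position].upper()
                if base != "N":
                    total += 1
                    base_counts[base] = base_counts.get(base, 0) + 1
                if pr.indel > 0:
                    qpos = pr.query_position
                    seq = pr.alignment.query_sequence[qpos + 1: qpos + 1 + pr.indel].upper()
                    ins_counts[seq] = ins_counts.get(seq, 0) + 1
                elif pr.indel < 0:
                    dlen = -pr.indel
                    del_counts[dlen] = del_counts.get(dlen, 0) + 1
        if total == 0 and not ins_counts and not del_counts:
            continue
        if reference is not None:
            ref_base = reference.fetch(region.contig, pos1 - 1, pos1).upper()
        else:
            ref_base = max(base_counts, key=lambda b: (base_counts[b], b)) if base_counts else "N"
        ref_count = base_counts.get(ref_base, 0)
        for alt_base in sorted(base_counts):
            if alt_base == ref_base:
                continue
            rows.append({
                "contig": region.contig, "position": pos1,
                "ref": ref_base, "alt": alt_base, "variant_type": "SNV",
                "alt_depth": base_counts[alt_base], "ref_depth": ref_count,
                "total_depth": total,
                "vaf": compute_vaf(base_counts[alt_base], total),
            })
        for seq in sorted(ins_counts):
            alt_depth = ins_counts[seq]
            rows.append({
                "contig": region.contig, "position": pos1,
                "ref": ref_base, "alt": ref_base + seq, "variant_type": "INS",
                "alt_depth": alt_depth,
                "ref_depth": max(total - alt_depth, 0), "total_depth": total,
                "vaf": compute_vaf(min(alt_depth, total), total),
            })
        for dlen in sorted(del_counts):
            if reference is not None:
                deleted = reference.fetch(region.contig, pos1, pos1 + dlen).upper()
            else:
                deleted = "N" * dlen
            alt_depth = del_counts[dlen]
            rows.append({
                "contig": region.contig, "position": pos1,
                "ref": ref_base + deleted, "alt": ref_base, "variant_type": "DEL",
                "alt_depth": alt_depth,
                "ref_depth": max(total - alt_depth, 0), "total_depth": total,
                "vaf": compute_vaf(min(alt_depth, total), total),
            })
    return rows


def tally_reads(
    bams,
    regions: Sequence[GenomicInterval],
    reference: Union[str, Path, None],
    params: Optional[TallyParams] = None,
) -> pd.DataFrame:
    """Tally SNVs and small indels over regions across one or more BAMs.

    ``bams`` may be a list of paths (file ids default to the path stem), a
    list of ``(file_id, path)`` pairs, or a mapping ``file_id -> path``.
    Returns a DataFrame with one row per (sample, site, alt allele) carrying
    any alt support, deterministically ordered by
    (contig, position, alt, file_id) regardless of worker configuration.
    """
    params = params or TallyParams()
    pairs = _normalize_bams(bams)

    def work(item):
        (file_id, path), region = item
        with pysam.AlignmentFile(path) as bam:
            ref = pysam.FastaFile(str(reference)) if reference else None
            try:
                rows = tally_reads_open(bam, region, params, ref)
            finally:
                if ref is not None:
                    ref.close()
        for r in rows:
            r["file_id"] = file_id
        return rows

    tasks = [(pair, region) for pair in pairs for region in regions]
    n_workers = min(params.workers_files * params.workers_ranges, max(len(tasks), 1))
    all_rows: list[dict] = []
    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            for rows in pool.map(work, tasks):
                all_rows.extend(rows)
    else:
        for t in tasks:
            all_rows.extend(work(t))
    if not all_rows:
        return pd.DataFrame(columns=TALLY_COLUMNS)
    df = pd.DataFrame(all_rows)[TALLY_COLUMNS]
    df = df.sort_values(["contig", "position", "alt", "file_id"], kind="mergesort")
    return df.reset_index(drop=True)


def position_coverage(
    bam: pysam.AlignmentFile, contig: str, pos: int, min_mapq: int = 0
) -> int:
    """Reads with an aligned base at 1-based ``pos`` (no base-quality filter).

    Reads carrying a deletion over ``pos`` are not counted (they have no base
    there); reads anchoring an indel at ``pos`` are.
    """
    for col in bam.pileup(
        contig, pos - 1, pos,
        truncate=True, stepper="samtools",
        min_base_quality=0, min_mapping_quality=min_mapq,
        ignore_overlaps=False, ignore_orphans=False,
        flag_filter=EXCLUDE_FLAGS, max_depth=1_000_000,
    ):
        return sum(
            1 for pr in col.pileups if not pr.is_del and not pr.is_refskip
        )
    return 0


def fix_indel_ref_counts(
    table: pd.DataFrame,
    bams,
    mode: str = "at_start",
    flank_width: int = 10,
    min_mapq: int = 0,
) -> pd.DataFrame:
    """Re-estimate total depth (hence ref depth and VAF) for indel rows.

    ``at_start`` replaces ``total_depth`` with the covering-read depth at the
    indel's anchor base; ``flank_mean`` uses the mean per-base coverage over
    ``flank_width`` bases on each side of the event, rounded to the nearest
    integer (ties to even). In both modes ``ref_depth`` becomes
    ``max(total_depth - alt_depth, 0)`` and VAF is recomputed. SNV rows are
    returned bit-identical.
    """
    if mode not in ("at_start", "flank_mean"):
        raise ParameterError(f"unknown indel ref-count mode: {mode!r}")
    if flank_width < 1:
        raise ParameterError("flank_width must be >= 1")
    by_id = dict(_normalize_bams(bams))
    out = table.copy()
    handles: dict[str, pysam.AlignmentFile] = {}
    try:
        for idx, row in table.iterrows():
            if row["variant_type"] not in ("INS", "DEL"):
                continue
            fid = row["file_id"]
            if fid not in handles:
                handles[fid] = pysam.AlignmentFile(by_id[fid])
            bam = handles[fid]
            contig, pos = row["contig"], int(row["position"])
            if mode == "at_start":
                total = position_coverage(bam, contig, pos, min_mapq)
            else:
                if row["variant_type"] == "DEL":
                    ev_start, ev_end = pos, pos + len(row["ref"]) - 1
                else:
                    ev_start, ev_end = pos, pos + 1
                covs = []
                for p in range(max(ev_start - flank_width, 1), ev_start):
                    covs.append(position_coverage(bam, contig, p, min_mapq))
                for p in range(ev_end + 1, ev_end + flank_width + 1):
                    covs.append(position_coverage(bam, contig, p, min_mapq))
                total = round(sum(covs) / len(covs)) if covs else 0
            alt = int(row["alt_depth"])
            out.at[idx, "total_depth"] = total
            out.at[idx, "ref_depth"] = max(total - alt, 0)
            out.at[idx, "vaf"] = compute_vaf(min(alt, total), total)
    finally:
        for h in handles.values():
            h.close()
    return out


def filter_variants(table: pd.DataFrame, spec: Optional[FilterSpec] = None) -> pd.DataFrame:
    """Keep rows with vaf > min_vaf AND total_depth > min_total_depth.

    Both comparisons are strict, so a row at exactly the threshold is removed.
    """
    spec = spec or FilterSpec()
    if table.empty:
        return table.copy()
    mask = (table["vaf"] > spec.min_vaf) & (table["total_depth"] > spec.min_total_depth)
    return table[mask].reset_index(drop=True)
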