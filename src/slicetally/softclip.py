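"""Soft-clip tallying and ITD hotspot screening.

Internal tandem duplications (ITDs) — e.g. the 45–95 bp in-frame insertions
at the 3' end of UBTF exon 13 seen in AML — are longer than an aligner will
place as an insertion, so junction-spanning reads are emitted with their
unalignable tail soft-clipped (CIGAR ``S``). The clipped ends pile up at the
duplication boundaries, so per-position counts of soft-clipped read ends
("sc-counts") form sharp hotspots that screen for ITD carriers without any
breakpoint assembly.

Conventions: a left clip is counted at the read's first aligned reference
position, a right clip at one past its last aligned position (the clip
boundary); hard clips (``H``) are ignored; one read clipped on both ends
contributes two positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pysam

from .errors import ContigError, ParameterError
from .regions import GenomicInterval
from .tally import EXCLUDE_FLAGS

CIGAR_SOFT_CLIP = 4


@dataclass(frozen=True)
class SoftClipTally:
    """Count of reads soft-clipped at one clip-boundary position."""

    sample_id: str
    contig: str
    position: int  # 1-based clip boundary
    sc_count: int


@dataclass(frozen=True)
class ItdScreenSpec:
    """Screening thresholds for ITD hotspot detection.

    ``count_threshold`` is the sc-count a position must exceed (strictly) to
    qualify as a hotspot; ``min_hotspots`` is how many distinct hotspot
    positions a sample needs before it is flagged (ITDs produce clips at
    both duplication boundaries, hence the default of 2 — a lone high
    position is more often an alignment artifact); ``min_clip_len`` drops
    short incidental clips.
    """

    region: GenomicInterval
    count_threshold: int = 25
    min_hotspots: int = 2
    min_clip_len: int = 5

    def __post_init__(self):
        if min(self.count_threshold, self.min_hotspots, self.min_clip_len) < 1:
            raise ParameterError("all ITD screen thresholds must be >= 1")


@dataclass(frozen=True)
class ItdFlag:
    """A flagged sample with its qualifying hotspot positions and counts."""

    sample_id: str
    hotspots: tuple[tuple[int, int], ...]  # (position, sc_count), count-desc

    @property
    def max_count(self) -> int:
        return max(c for _, c in self.hotspots)


def tally_softclips(
    bam_path,
    region: GenomicInterval,
    min_clip_len: int = 5,
    min_mapq: int = 0,
    sample_id: str | None = None,
) -> list[SoftClipTally]:
    """Per-position counts of soft-clipped read ends within a region.

    Only clip boundaries falling inside ``region`` are reported; rows are
    sorted by position and carry counts >= 1.
    """
    sample = sample_id if sample_id is not None else str(bam_path)
    counts: dict[int, int] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if region.contig not in bam.references:
            raise ContigError(
                f"contig {region.contig!r} absent from BAM header of {bam_path}"
            )
        for read in bam.fetch(region.contig, region.start - 1, region.end):
            if read.flag & EXCLUDE_FLAGS or read.mapping_quality < min_mapq:
                continue
            cig = read.cigartuples
            if not cig:
                continue
            if cig[0][0] == CIGAR_SOFT_CLIP and cig[0][1] >= min_clip_len:
                pos = read.reference_start + 1  # first aligned base, 1-based
                if region.start <= pos <= region.end:
                    counts[pos] = counts.get(pos, 0) + 1
            if len(cig) > 1 and cig[-1][0] == CIGAR_SOFT_CLIP and cig[-1][1] >= min_clip_len:
                pos = read.reference_end + 1  # one past last aligned base
                if region.start <= pos <= region.end:
                    counts[pos] = counts.get(pos, 0) + 1
    return [
        SoftClipTally(sample, region.contig, pos, counts[pos])
        for pos in sorted(counts)
    ]


def screen_itd(
    tallies: Mapping[str, Sequence[SoftClipTally]],
    spec: ItdScreenSpec,
) -> list[ItdFlag]:
    """Flag samples with clustered high soft-clip counts in the screen region.

    A sample is flagged iff it has at least ``min_hotspots`` distinct
    positions whose sc_count strictly exceeds ``count_threshold`` inside the
    region. Flagged samples are returned sorted by their maximum hotspot
    count, descending; each flag lists all qualifying positions, also sorted
    by count descending.
    """
    flags = []
    for sample_id in sorted(tallies):
        hot = [
            (t.position, t.sc_count)
            for t in tallies[sample_id]
            if t.sc_count > spec.count_threshold
            and spec.region.contains(t.contig, t.position)
        ]
        if len(hot) >= spec.min_hotspots:
            hot.sort(key=lambda pc: (-pc[1], pc[0]))
            flags.append(ItdFlag(sample_id, tuple(hot)))
    flags.sort(key=lambda f: (-f.max_count, f.sample_id))
    return flags
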