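"""Independent brute-force oracles and tiny fixture builders for the tests.

Everything here deliberately avoids the package's own pileup/bin/projection
code paths: the pileup oracle walks each read's CIGAR by hand, the interval
oracles enumerate bases one at a time, and the equivalence-class oracle
checks transcript containment exon by exon.
"""

from __future__ import annotations

import random

import pysam

from slicetally.regions import GenomicInterval
from slicetally.tally import EXCLUDE_FLAGS
from slicetally.txmodel import TranscriptModel

# ---------------------------------------------------------------------------
# BAM construction
# ---------------------------------------------------------------------------

def make_bam(path, contig_lengths: dict[str, int], reads: list[dict]) -> str:
    """Write a sorted, indexed BAM from plain read dicts.

    Each read dict: name, contig, start (1-based), seq, cigar (list of
    (op, len)), and optional mapq (default 60), flag (default 0),
    quals (string of chars, default flat Q35).
    """
    path = str(path)
    names = list(contig_lengths)
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": contig_lengths[n]} for n in names],
    }
    with pysam.AlignmentFile(path + ".unsorted", "wb", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r["name"]
            a.query_sequence = r["seq"]
            a.flag = r.get("flag", 0)
            a.reference_id = names.index(r["contig"])
            a.reference_start = r["start"] - 1
            a.mapping_quality = r.get("mapq", 60)
            a.cigartuples = r["cigar"]
            quals = r.get("quals") or chr(35 + 33) * len(r["seq"])
            a.query_qualities = pysam.qualitystring_to_array(quals)
            out.write(a)
    pysam.sort("-o", path, path + ".unsorted")
    pysam.index(path)
    return path


def make_random_bam(path, refseq: str, contig: str, n_reads: int, rng: random.Random,
                    indels: bool = True) -> str:
    """Random reads over one contig with random qualities, mapq, and indels."""
    reads = []
    for i in range(n_reads):
        length = rng.randint(30, 60)
        start0 = rng.randint(0, len(refseq) - length - 10)
        seq = list(refseq[start0: start0 + length])
        cigar = [(0, length)]
        draw = rng.random()
        if indels and draw < 0.2:
            at = rng.randint(5, length - 6)
            ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            seq = seq[:at] + list(ins) + seq[at:]
            cigar = [(0, at), (1, len(ins)), (0, length - at)]
        elif indels and draw < 0.4:
            at = rng.randint(5, length - 10)
            d = rng.randint(1, 4)
            seq = seq[:at] + seq[at + d:]
            cigar = [(0, at), (2, d), (0, length - at - d)]
        for _ in range(3):  # sprinkle mismatches
            j = rng.randint(0, len(seq) - 1)
            seq[j] = rng.choice("ACGT")
        reads.append({
            "name": f"r{i}", "contig": contig, "start": start0 + 1,
            "seq": "".join(seq), "cigar": cigar,
            "mapq": rng.randint(0, 60),
            "quals": "".join(chr(rng.randint(2, 40) + 33) for _ in seq),
        })
    return make_bam(path, {contig: len(refseq)}, reads)


# ---------------------------------------------------------------------------
# Pileup oracle: per-read CIGAR walk
# ---------------------------------------------------------------------------

def naive_pileup(bam_path, refseq_by_contig: dict[str, str],
                 region: GenomicInterval, min_mapq: int, min_bq: int,
                 ) -> list[tuple[int, str, str, int, int]]:
    """(pos, ref, alt, alt_depth, total_depth) rows by brute-force read walk.

    Mirrors the tally contract: duplicate/secondary/supplementary/QC-fail
    and sub-mapq reads excluded; bases (and indel anchors) below min_bq
    excluded; indels anchored at the last M base before the event.
    """
    refseq = refseq_by_contig[region.contig]
    total: dict[int, int] = {}
    bases: dict[int, dict[str, int]] = {}
    ins: dict[int, dict[str, int]] = {}
    dels: dict[int, dict[int, int]] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for r in bam.fetch(region.contig, region.start - 1, region.end):
            if r.flag & EXCLUDE_FLAGS or r.mapping_quality < min_mapq:
                continue
            q, quals, cig = r.query_sequence, r.query_qualities, r.cigartuples
            ref, qi = r.reference_start, 0
            for ci, (op, ln) in enumerate(cig):
                if op == 0:  # M
                    for k in range(ln):
                        pos = ref + k + 1
                        in_region = region.start <= pos <= region.end
                        if quals[qi + k] < min_bq:
                            continue
                        b = q[qi + k].upper()
                        if in_region and b != "N":
                            total[pos] = total.get(pos, 0) + 1
                            bases.setdefault(pos, {}).setdefault(b, 0)
                            bases[pos][b] += 1
                        if k == ln - 1 and ci + 1 < len(cig) and in_region:
                            nop, nln = cig[ci + 1]
                            if nop == 1:
                                s = q[qi + ln: qi + ln + nln].upper()
                                ins.setdefault(pos, {}).setdefault(s, 0)
                                ins[pos][s] += 1
                            elif nop == 2:
                                dels.setdefault(pos, {}).setdefault(nln, 0)
                                dels[pos][nln] += 1
                    ref += ln
                    qi += ln
                elif op == 1 or op == 4:  # I, S
                    qi += ln
                elif op == 2 or op == 3:  # D, N
                    ref += ln
    rows = []
    for pos in sorted(set(total) | set(ins) | set(dels)):
        ref_base = refseq[pos - 1].upper()
        t = total.get(pos, 0)
        for b, c in sorted(bases.get(pos, {}).items()):
            if b != ref_base:
                rows.append((pos, ref_base, b, c, t))
        for s, c in sorted(ins.get(pos, {}).items()):
            rows.append((pos, ref_base, ref_base + s, c, t))
        for d, c in sorted(dels.get(pos, {}).items()):
            deleted = refseq[pos: pos + d].upper()
            rows.append((pos, ref_base + deleted, ref_base, c, t))
    return rows


def naive_softclip_scan(bam_path, region: GenomicInterval, min_clip_len: int,
                        min_mapq: int = 0) -> dict[int, int]:
    """Brute-force CIGAR scan counting soft-clipped read ends per position."""
    counts: dict[int, int] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for r in bam.fetch(region.contig, region.start - 1, region.end):
            if r.flag & EXCLUDE_FLAGS or r.mapping_quality < min_mapq:
                continue
            cig = r.cigartuples or []
            if cig and cig[0][0] == 4 and cig[0][1] >= min_clip_len:
                p = r.reference_start + 1
                if region.start <= p <= region.end:
                    counts[p] = counts.get(p, 0) + 1
            if len(cig) > 1 and cig[-1][0] == 4 and cig[-1][1] >= min_clip_len:
                p = r.reference_end + 1
                if region.start <= p <= region.end:
                    counts[p] = counts.get(p, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Interval / transcript oracles
# ---------------------------------------------------------------------------

def per_base_union(intervals) -> set[tuple[str, int]]:
    """The per-base set covered by intervals, enumerated one base at a time."""
    out = set()
    for iv in intervals:
        for p in range(iv.start, iv.end + 1):
            out.add((iv.contig, p))
    return out


def brute_force_eq_class(transcripts, contig: str, span: tuple[int, int]) -> set[str]:
    """{tx : every base of span lies in an exon of tx}, by enumeration."""
    out = set()
    for tx in transcripts:
        if tx.contig != contig:
            continue
        exon_bases = set()
        for e in tx.exons:
            exon_bases.update(range(e.start, e.end + 1))
        if all(p in exon_bases for p in range(span[0], span[1] + 1)):
            out.add(tx.tx_id)
    return out


def brute_force_slice(bam_path, regions) -> set[tuple]:
    """Full-scan read keys whose reference span overlaps any region."""
    keys = set()
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for r in bam.fetch(until_eof=True):
            if r.is_unmapped:
                continue
            for reg in regions:
                if (bam.get_reference_name(r.reference_id) == reg.contig
                        and r.reference_start < reg.end
                        and r.reference_end > reg.start - 1):
                    keys.add((r.query_name, r.flag, r.reference_id,
                              r.reference_start, r.cigarstring))
                    break
    return keys


def random_transcript_model(rng: random.Random, contig: str = "chr1",
                            strand: str | None = None) -> TranscriptModel:
    """A random multi-exon transcript model (no CDS)."""
    strand = strand or rng.choice("+-")
    n_exons = rng.randint(1, 5)
    pos = rng.randint(1, 500)
    exons = []
    for _ in range(n_exons):
        length = rng.randint(5, 120)
        exons.append(GenomicInterval(contig, pos, pos + length - 1, strand))
        pos += length + rng.randint(2, 150)
    return TranscriptModel(
        tx_id=f"TX{rng.randint(0, 10**6)}", gene_id="G", gene_name="G",
        contig=contig, strand=strand, exons=tuple(exons),
    )
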