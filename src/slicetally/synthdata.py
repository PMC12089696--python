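"""Deterministic synthetic fixtures: reference, gene models, reads.

Everything a targeted-slicing study consumes is generated from one seeded
spec: a small multi-contig reference, overlapping multi-transcript gene
models (including a containment pattern where one exon disjoins into three
bins), reads spiked with SNVs/indels at configured VAFs and depths in either
genomic or transcriptome alignment space, and ITD-bearing reads whose
unalignable tails appear as clustered soft clips at the duplication
boundaries. A truth table of spiked variants is written alongside each BAM
so recovery can be asserted end to end.

Reads are single-end with flat base qualities; sequencing error is injected
as uniform per-base substitution (default 0.1%). Every read covering a spike
position carries the alternate allele independently with probability
``target_vaf``, so the tallied VAF at coverage n is Binomial(n, vaf)/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .errors import ParameterError, RefMismatchError
from .regions import GenomicInterval
from .txmodel import TranscriptModel, genomic_to_tx, variant_to_tx

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Spike:
    """One variant to plant into simulated reads at a target VAF."""

    contig: str
    position: int
    kind: str  # SNV | INS | DEL
    target_vaf: float
    depth: int = 50
    alt_base: Optional[str] = None  # SNV; None -> deterministic non-ref choice
    ins_seq: str = ""
    del_len: int = 0

    def __post_init__(self):
        if not 0 < self.target_vaf <= 1:
            raise ParameterError("target_vaf must lie in (0, 1]")
        if self.kind not in ("SNV", "INS", "DEL"):
            raise ParameterError(f"unknown spike kind {self.kind!r}")
        if self.kind == "INS" and not self.ins_seq:
            raise ParameterError("INS spike needs ins_seq")
        if self.kind == "DEL" and self.del_len < 1:
            raise ParameterError("DEL spike needs del_len >= 1")


@dataclass(frozen=True)
class ItdSpec:
    """An internal tandem duplication: segment [position-length+1, position]
    duplicated; ``supporting_reads`` junction-spanning read ends are emitted
    per clip boundary (one right-clip cluster at position+1, one left-clip
    cluster at the segment start)."""

    contig: str
    position: int
    length: int = 60  # typical ITD insert lengths run 45-95 bp
    supporting_reads: int = 40

    def __post_init__(self):
        if self.length < 1:
            raise ParameterError("ITD length must be >= 1")


@dataclass(frozen=True)
class GeneLayout:
    """Exon/CDS structure of one synthetic gene."""

    gene_name: str
    gene_id: str
    contig: str
    strand: str
    transcripts: dict[str, tuple[tuple[int, int], ...]]
    cds: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)


def fig_pattern_gene(contig: str = "chr1", offset: int = 1000) -> GeneLayout:
    """A three-transcript gene whose first exon disjoins into three bins
    with memberships {T1,T2}, {T1,T2,T3}, {T2,T3} (containment pattern)."""
    o = offset
    return GeneLayout(
        gene_name="GENEA", gene_id="GENEA.1", contig=contig, strand="+",
        transcripts={
            "T1": ((o + 100, o + 180), (o + 400, o + 499)),
            "T2": ((o + 100, o + 200), (o + 400, o + 499)),
            "T3": ((o + 140, o + 200), (o + 400, o + 499)),
        },
        cds={
            "T1": ((o + 149, o + 180), (o + 400, o + 460)),   # 32+61 = 93 nt
            "T2": ((o + 150, o + 200), (o + 400, o + 441)),   # 51+42 = 93 nt
        },
    )


def minus_strand_gene(contig: str = "chr2", offset: int = 2000) -> GeneLayout:
    o = offset
    return GeneLayout(
        gene_name="GENEB", gene_id="GENEB.1", contig=contig, strand="-",
        transcripts={"T4": ((o + 100, o + 199), (o + 400, o + 459))},
        cds={"T4": ((o + 120, o + 199), (o + 400, o + 451))},  # 80+52 = 132 nt
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic study fixture."""

    seed: int = 0
    contigs: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000, "chr2": 8_000}
    )
    genes: tuple[GeneLayout, ...] = field(
        default_factory=lambda: (fig_pattern_gene(), minus_strand_gene())
    )
    spikes: tuple[Spike, ...] = ()
    itd: Optional[ItdSpec] = None
    read_length: int = 100
    base_quality: int = 35
    error_rate: float = 0.001
    background_depth: int = 30


# ---------------------------------------------------------------------------
# Reference and gene models
# ---------------------------------------------------------------------------

def make_reference(spec: SyntheticSpec, out_dir) -> Path:
    """Write a seeded random genome FASTA (+ .fai) for ``spec.contigs``."""
    for name, length in spec.contigs.items():
        if length < 1000:
            raise ParameterError(f"contig {name} shorter than 1000 bp")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    path = out_dir / "genome.fa"
    with open(path, "w") as fh:
        for name, length in spec.contigs.items():
            seq = "".join(BASES[rng.integers(0, 4, size=length)])
            fh.write(f">{name}\n")
            for i in range(0, length, 60):
                fh.write(seq[i: i + 60] + "\n")
    pysam.faidx(str(path))
    return path


def gene_models(spec: SyntheticSpec) -> list[TranscriptModel]:
    """The gene layouts of ``spec`` as :class:`TranscriptModel` objects."""
    models = []
    for g in spec.genes:
        for tx_id, exons in g.transcripts.items():
            models.append(
                TranscriptModel(
                    tx_id=tx_id, gene_id=g.gene_id, gene_name=g.gene_name,
                    contig=g.contig, strand=g.strand,
                    exons=tuple(
                        GenomicInterval(g.contig, s, e, g.strand) for s, e in exons
                    ),
                    cds=tuple(
                        GenomicInterval(g.contig, s, e, g.strand)
                        for s, e in g.cds.get(tx_id, ())
                    ),
                )
            )
    return models


def make_gene_models(spec: SyntheticSpec, out_dir, reference_fasta) -> tuple[Path, Path]:
    """Write the genes of ``spec`` as GFF3 plus the matching transcript FASTA.

    The transcript FASTA contains each transcript's spliced exon sequence
    (reverse-complemented on the minus strand) under its transcript id, as a
    transcriptome aligner would use. Returns (gff3_path, tx_fasta_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gff_path = out_dir / "annotation.gff3"
    txfa_path = out_dir / "transcripts.fa"
    with pysam.FastaFile(str(reference_fasta)) as genome, \
            open(gff_path, "w") as gff, open(txfa_path, "w") as txfa:
        gff.write("##gff-version 3\n")
        for g in spec.genes:
            all_exons = [iv for exons in g.transcripts.values() for iv in exons]
            gstart = min(s for s, _ in all_exons)
            gend = max(e for _, e in all_exons)
            gff.write(
                f"{g.contig}\tsynthetic\tgene\t{gstart}\t{gend}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_id={g.gene_id};gene_name={g.gene_name}\n"
            )
            for tx_id in g.transcripts:
                exons = sorted(g.transcripts[tx_id])
                tstart, tend = exons[0][0], exons[-1][1]
                gff.write(
                    f"{g.contig}\tsynthetic\ttranscript\t{tstart}\t{tend}\t.\t"
                    f"{g.strand}\t.\tID={tx_id};Parent={g.gene_id};"
                    f"transcript_id={tx_id};gene_name={g.gene_name}\n"
                )
                for i, (s, e) in enumerate(exons, 1):
                    gff.write(
                        f"{g.contig}\tsynthetic\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={tx_id}.exon{i};Parent={tx_id};transcript_id={tx_id}\n"
                    )
                for i, (s, e) in enumerate(sorted(g.cds.get(tx_id, ())), 1):
                    gff.write(
                        f"{g.contig}\tsynthetic\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                        f"ID={tx_id}.cds{i};Parent={tx_id};transcript_id={tx_id}\n"
                    )
                seq = "".join(
                    genome.fetch(g.contig, s - 1, e).upper() for s, e in exons
                )
                if g.strand == "-":
                    seq = str(Seq(seq).reverse_complement())
                txfa.write(f">{tx_id}\n")
                for i in range(0, len(seq), 60):
                    txfa.write(seq[i: i + 60] + "\n")
    if any(g.transcripts for g in spec.genes):
        pysam.faidx(str(txfa_path))
    return gff_path, txfa_path


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _spike_alt(spike: Spike, ref_base: str, ref_fetch) -> tuple[str, str]:
    """Anchored (ref, alt) allele strings for a spike."""
    if spike.kind == "SNV":
        alt = spike.alt_base
        if alt is None:
            alt = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        return ref_base, alt
    if spike.kind == "INS":
        return ref_base, ref_base + spike.ins_seq.upper()
    deleted = ref_fetch(spike.contig, spike.position + 1,
                        spike.position + spike.del_len)
    return ref_base + deleted, ref_base


def _make_read(name, contig_id, start0, seq, cigar, mapq, bq) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment()
    a.query_name = name
    a.query_sequence = seq
    a.flag = 0
    a.reference_id = contig_id
    a.reference_start = start0
    a.mapping_quality = mapq
    a.cigartuples = cigar
    a.query_qualities = pysam.qualitystring_to_array(chr(bq + 33) * len(seq))
    return a


def simulate_bam(
    spec: SyntheticSpec,
    space: str,
    out_dir,
    reference_fasta,
    tx_fasta=None,
) -> tuple[Path, Path]:
    """Simulate a sorted, indexed BAM plus its spiked-variant truth table.

    ``space`` is ``"genomic"`` (reads against the genome FASTA, over every
    gene span, spike neighborhood and ITD region) or ``"transcriptome"``
    (reads against the transcript FASTA; genomic spikes are re-expressed in
    the coordinates of every transcript whose exons contain them).
    Returns (bam_path, truth_tsv_path). Deterministic under ``spec.seed``.
    """
    if space not in ("genomic", "transcriptome"):
        raise ParameterError(f"unknown alignment space {space!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng((spec.seed, 1 if space == "genomic" else 2))
    fasta_path = reference_fasta if space == "genomic" else tx_fasta
    if fasta_path is None:
        raise ParameterError("transcriptome simulation requires tx_fasta")
    bam_path = out_dir / f"reads_{space}.bam"
    truth_path = out_dir / f"truth_{space}.tsv"

    with pysam.FastaFile(str(fasta_path)) as fa:
        refs = {name: fa.fetch(name).upper() for name in fa.references}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in refs.items()],
    }
    ref_ids = {n: i for i, n in enumerate(refs)}

    def fetch(contig, start, end):  # 1-based closed
        return refs[contig][start - 1: end]

    models = gene_models(spec)
    L = spec.read_length

    # --- resolve spikes into (contig-in-space, pos, ref, alt, vaf, depth) ---
    truth_rows = []
    placed: list[dict] = []
    for sp in spec.spikes:
        ref_base = fetch(sp.contig, sp.position, sp.position) if space == "genomic" \
            else None
        if space == "genomic":
            ref_allele, alt_allele = _spike_alt(sp, ref_base, fetch)
            placed.append({
                "contig": sp.contig, "position": sp.position,
                "ref": ref_allele, "alt": alt_allele, "kind": sp.kind,
                "vaf": sp.target_vaf, "depth": sp.depth,
            })
        else:
            # express the genomic spike on every transcript containing it
            g_ref = None
            for tx in models:
                tpos = genomic_to_tx(tx, sp.position)
                if tpos is None or tx.tx_id not in refs:
                    continue
                if g_ref is None:
                    # anchored genomic alleles from the genome FASTA
                    with pysam.FastaFile(str(reference_fasta)) as genome_fa:
                        anchor = genome_fa.fetch(
                            sp.contig, sp.position - 1, sp.position
                        ).upper()

                        def gfetch(c, s, e, _fa=genome_fa):
                            return _fa.fetch(c, s - 1, e).upper()

                        g_ref, g_alt = _spike_alt(sp, anchor, gfetch)
                t_pos, t_ref, t_alt = variant_to_tx(
                    tx, sp.position, g_ref, g_alt, tx_seq=refs[tx.tx_id]
                )
                kind = sp.kind
                placed.append({
                    "contig": tx.tx_id, "position": t_pos,
                    "ref": t_ref, "alt": t_alt, "kind": kind,
                    "vaf": sp.target_vaf, "depth": sp.depth,
                })
    for p in placed:
        if fetch(p["contig"], p["position"],
                 p["position"] + len(p["ref"]) - 1) != p["ref"]:
            raise RefMismatchError(
                f"spike ref {p['ref']!r} disagrees with reference at "
                f"{p['contig']}:{p['position']}"
            )
        truth_rows.append({**p, "space": space})

    # --- decide read placements -------------------------------------------
    placements: list[tuple[str, int]] = []  # (contig, 1-based start)
    if space == "genomic":
        spans = [(m.span.contig, m.span.start, m.span.end) for m in models]
        if spec.itd is not None:
            it = spec.itd
            spans.append((it.contig, it.position - it.length - 2 * L,
                          it.position + 2 * L))
    else:
        spans = [(n, 1, len(s)) for n, s in refs.items()]
    if spec.background_depth > 0:
        for contig, lo, hi in spans:
            lo = max(lo, 1)
            hi = min(hi, len(refs[contig]))
            n = int(np.ceil(spec.background_depth * (hi - lo + 1) / L))
            starts = rng.integers(max(lo - L + 1, 1), hi + 1, size=n)
            placements.extend((contig, int(s)) for s in starts)
    for p in placed:
        lo = max(p["position"] - L + 1, 1)
        starts = rng.integers(lo, p["position"] + 1, size=p["depth"])
        placements.extend((p["contig"], int(s)) for s in starts)

    # --- build reads -------------------------------------------------------
    reads: list[pysam.AlignedSegment] = []
    spikes_by_contig: dict[str, list[dict]] = {}
    for p in placed:
        spikes_by_contig.setdefault(p["contig"], []).append(p)
    for i, (contig, start) in enumerate(placements):
        clen = len(refs[contig])
        start = min(start, max(clen - L + 1, 1))
        reads_seq, cigar, _carried = _compose_read(
            refs[contig], start, L, spikes_by_contig.get(contig, []), rng
        )
        seq = _inject_errors(reads_seq, spec.error_rate, rng)
        reads.append(_make_read(
            f"sim{space[0]}{i}", ref_ids[contig], start - 1, seq, cigar,
            60, spec.base_quality,
        ))

    # --- ITD-bearing soft-clipped reads (genomic space only) --------------
    if space == "genomic" and spec.itd is not None:
        it = spec.itd
        dup_start = it.position - it.length + 1
        for j in range(it.supporting_reads):
            # right-clipped at the duplication end: aligned tail ends at
            # it.position, clipped bases restart the duplicated segment
            aligned = int(rng.integers(L - 60, L - 19))
            clip = L - aligned
            s = it.position - aligned + 1
            seq = (fetch(it.contig, s, it.position)
                   + fetch(it.contig, dup_start, dup_start + clip - 1))
            reads.append(_make_read(
                f"itdR{j}", ref_ids[it.contig], s - 1, seq,
                [(0, aligned), (4, clip)], 60, spec.base_quality,
            ))
            # left-clipped at the duplication start: clipped bases are the
            # end of the first copy, alignment resumes at dup_start
            aligned2 = int(rng.integers(L - 60, L - 19))
            clip2 = L - aligned2
            seq2 = (fetch(it.contig, it.position - clip2 + 1, it.position)
                    + fetch(it.contig, dup_start, dup_start + aligned2 - 1))
            reads.append(_make_read(
                f"itdL{j}", ref_ids[it.contig], dup_start - 1, seq2,
                [(4, clip2), (0, aligned2)], 60, spec.base_quality,
            ))

    unsorted = out_dir / f"reads_{space}.unsorted.bam"
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as out:
        for r in reads:
            out.write(r)
    pysam.sort("-o", str(bam_path), str(unsorted))
    pysam.index(str(bam_path))
    unsorted.unlink()

    pd.DataFrame(
        truth_rows,
        columns=["contig", "position", "ref", "alt", "kind", "vaf", "depth", "space"],
    ).to_csv(truth_path, sep="\t", index=False)
    return bam_path, truth_path


def _compose_read(ref_seq: str, start: int, L: int, spikes: Sequence[dict], rng):
    """Build one read's sequence and CIGAR, rolling spike carriage.

    SNV spikes substitute in place; at most one indel spike is carried per
    read (applied only when the anchor and following base both sit strictly
    inside the aligned span). Returns (seq, cigartuples, carried spikes).
    """
    carried = []
    indel = None
    for p in sorted(spikes, key=lambda q: q["position"]):
        if p["kind"] == "SNV":
            inside = start <= p["position"] <= start + L - 1
        else:  # indel anchor plus following base must be strictly inside
            inside = start <= p["position"] - 1 and p["position"] + 1 <= start + L - 1
        if not inside:
            continue
        if rng.random() < p["vaf"]:
            if p["kind"] == "SNV":
                carried.append(p)
            elif indel is None:
                indel = p
                carried.append(p)
    if indel is None:
        seq = list(ref_seq[start - 1: start - 1 + L])
        for p in carried:
            seq[p["position"] - start] = p["alt"]
        return "".join(seq), [(0, len(seq))], carried
    pos = indel["position"]
    if indel["kind"] == "INS":
        ins = indel["alt"][1:]
        left = ref_seq[start - 1: pos]           # through the anchor
        room = L - len(left) - len(ins)
        if room < 1:  # insertion won't fit; drop it from this read
            carried.remove(indel)
            seq = list(ref_seq[start - 1: start - 1 + L])
            for p in carried:
                if p["kind"] == "SNV":
                    seq[p["position"] - start] = p["alt"]
            return "".join(seq), [(0, len(seq))], carried
        right = ref_seq[pos: pos + room]
        seq = list(left + ins + right)
        cigar = [(0, len(left)), (1, len(ins)), (0, len(right))]
    else:  # DEL
        d = len(indel["ref"]) - 1
        left = ref_seq[start - 1: pos]
        right = ref_seq[pos + d: pos + d + (L - len(left))]
        if not right:  # deletion would end the read; drop it
            carried.remove(indel)
            seq = list(ref_seq[start - 1: start - 1 + L])
            for p in carried:
                if p["kind"] == "SNV":
                    seq[p["position"] - start] = p["alt"]
            return "".join(seq), [(0, len(seq))], carried
        seq = list(left + right)
        cigar = [(0, len(left)), (2, d), (0, len(right))]
    # apply SNV spikes that fall inside aligned (M) segments
    for p in carried:
        if p["kind"] != "SNV":
            continue
        off = p["position"] - start
        if indel["kind"] == "INS":
            qoff = off if p["position"] <= pos else off + len(indel["alt"]) - 1
        else:
            d = len(indel["ref"]) - 1
            if pos < p["position"] <= pos + d:
                continue  # base deleted from this read
            qoff = off if p["position"] <= pos else off - d
        if 0 <= qoff < len(seq):
            seq[qoff] = p["alt"]
    return "".join(seq), cigar, carried


def _inject_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = choices[int(rng.integers(0, 3))].encode()
    return arr.tobytes().decode()


def make_fixture(spec: SyntheticSpec, out_dir, spaces: Sequence[str] = ("genomic",)):
    """Generate the full fixture tree (reference, models, BAMs, truth) under
    one directory. Returns a dict of output paths."""
    out_dir = Path(out_dir)
    ref = make_reference(spec, out_dir)
    gff, txfa = make_gene_models(spec, out_dir, ref)
    out = {"reference": ref, "gff3": gff, "tx_fasta": txfa}
    for space in spaces:
        bam, truth = simulate_bam(spec, space, out_dir, ref, tx_fasta=txfa)
        out[f"bam_{space}"] = bam
        out[f"truth_{space}"] = truth
    return out
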