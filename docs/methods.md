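# Methods

Definitions and conventions used throughout slicetally. All coordinates are
1-based and closed unless stated otherwise; region strings take the form
`contig:start-end` with `start <= end` (reversed bounds are rejected, not
swapped).

## Slicing

`slice_local` extracts reads overlapping a set of regions from an indexed
BAM. Reads touching several requested regions are emitted once
(deduplication key: query name, flag, reference, position, CIGAR); output is
coordinate-sorted and indexed. The remote client (`download_sliced`) speaks a
GDC-style REST dialect — `GET /slicing/view/<file_id>?region=...` with an
`X-Auth-Token` header — and writes the served bytes unmodified. Each file in
a manifest is handled independently: authentication and HTTP errors are
recorded per file without aborting the run, transient transport errors are
retried, and downloads are validated by BGZF magic and the 28-byte BGZF EOF
marker. Files that already exist and pass the integrity check are skipped on
re-runs, so repeated invocations are idempotent and make no new requests.

## Tallying

`tally_reads` runs a pileup per region with samtools-compatible semantics:
duplicate, secondary, supplementary, QC-fail and unmapped reads are excluded;
`min_mapq` filters alignments and `min_base_quality` masks individual read
bases per column. SNVs are counted at their position; insertions and
deletions are counted at their anchor — the last aligned base before the
event, as in VCF — and an indel is only counted when its anchor base passes
the quality mask. For every (position, alt) the table reports `alt_depth`,
`ref_depth`, `total_depth` and `vaf = alt_depth / total_depth` (0 when depth
is 0). The engine is verified against an independent per-read CIGAR-walk
pileup on randomized alignments.

Deletions remove reference-supporting bases from the columns they span, so
indel rows can understate reference depth. `fix_indel_ref_counts` rescans
the BAM and replaces `total_depth` with either the covering-read depth at the
anchor (`at_start`) or the mean coverage over flanking windows of width *w*
on each side (`flank_mean`, rounded half-to-even), then sets
`ref_depth = max(total - alt, 0)` and recomputes the VAF. The rescan counts
covering reads without the base-quality mask, since a deleted base has no
quality to test.

`filter_variants` applies strict thresholds: a row survives iff
`vaf > min_vaf` **and** `total_depth > min_depth` (defaults 0.15 and 8;
boundary values are excluded).

## Transcript coordinates and equivalence classes

A transcript position is the 1-based offset along the spliced transcript in
5'→3' orientation; on the minus strand the exon walk is reversed.
`genomic_to_tx` returns nothing for intronic or flanking bases, and
`tx_to_genomic` inverts it exactly on every exonic base. `project_gff3`
writes `tx_id`/`tx_start`/`tx_end` attributes onto every transcript-scoped
feature while preserving the file as valid GFF3.

For one gene, `disjoint_bins` cuts the exon union at every exon boundary and
merges contiguous segments with identical transcript membership, yielding
maximal constant-membership bins. The *equivalence class* of a variant is
the set of transcripts whose exons contain its entire genomic span:

* SNV — the substituted base;
* deletion (left-anchored) — the anchor through the last deleted base;
* insertion (left-anchored) — the anchor base plus the following base, so an
  insertion at an exon–exon junction belongs only to transcripts containing
  both flanking bases.

The class is computed as the intersection of bin memberships over the span,
with an explicit full-coverage check so any base falling outside the exon
union empties the class; this equals brute-force per-transcript enumeration.
`variant_to_tx` re-expresses anchored variants in transcript coordinates,
reverse-complementing alleles and re-anchoring indels on the minus strand so
the transcript representation is again left-anchored.

## Consequence prediction

Within a transcript, the CDS interval in transcript coordinates determines
the region label (5'/3' UTR, start/stop codon, CDS, noncoding, intronic).
SNVs substitute one codon: synonymous, missense, nonsense, stop-lost or
start-lost. Indels follow the mod-3 rule — frameshift unless the net length
change is a multiple of 3 (inframe insertion/deletion). Protein position is
`ceil(cds_position / 3)`. Predictions are implemented twice, from genomic
coordinates against the genome and from transcript coordinates against the
spliced transcript sequence, and the two routes are required to agree.
Reference alleles are checked against the sequence; mismatches raise rather
than silently annotate the wrong base.

Interchange: sites-only VCF for VEP input (sorted, deduplicated), VEP CSQ
parsing driven by the `Format:` declaration in the VCF header, and MAF
export with standard conventions (anchor stripped; deletions start one past
the anchor with `-` as the tumor allele; insertions span anchor to anchor+1
with `-` as the reference allele). MAF rows can be read back to anchored
variant keys given the reference.

## ITD screening

Soft-clip tallies count clipped read ends per position: a left clip at the
first aligned base, a right clip one past the last aligned base; clips
shorter than `min_clip_len` (default 5) are ignored. A sample is flagged
when at least `min_hotspots` positions (default 2) in the screened region
have counts strictly above `count_threshold` (default 25) — a tandem
duplication produces clip clusters at both junctions, while coverage noise
rarely produces even one. Tallies equal a direct CIGAR scan by
construction, and screening is validated on simulated duplications with
insert lengths of 45–95 bp against equal-depth variant-free controls.

## Synthetic data

The generator is fully deterministic under a single seed (read simulation
and error injection use separately derived streams). It writes a random
genome, GFF3 gene models with spliced transcript FASTA, and aligned reads at
a configurable background depth. Spiked variants are carried by each
covering read independently with probability `target_vaf`, so recovered VAFs
are binomially distributed around the target. ITDs are emitted as two
clusters of junction-spanning reads, soft-clipped at the duplication
boundaries. A truth table accompanies every BAM, in genomic and (optionally)
transcriptome space.
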