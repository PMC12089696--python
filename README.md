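# slicetally

Targeted BAM slicing, variant tallying, and transcript-aware annotation for
large sequencing cohorts.

## The problem

Cohort-scale variant analysis of specific genes rarely needs whole BAM files.
A study of a handful of loci across hundreds of RNA-Seq or DNA samples can be
served by *slices*: the reads overlapping the regions of interest, extracted
locally or fetched from a remote slicing endpoint. Once sliced, the questions
are the classic ones — which alleles are present at each position, at what
variant allele frequency (VAF), on which transcripts, and with what protein
consequence — plus one that pileups miss entirely: internal tandem
duplications (ITDs), which surface not as mismatches but as clusters of
soft-clipped read ends.

slicetally covers that workflow end to end:

* **Slicing** — extract reads for regions or gene symbols from local BAMs, or
  download slices from a GDC-style REST endpoint (token auth, per-file error
  reporting, integrity checks, idempotent re-runs). A mock endpoint is
  bundled so the remote path is testable offline.
* **Tallying** — pileup-based SNV and small-indel counting with per-column
  mapping/base-quality filters, `VAF = alt_depth / total_depth`, a rescan
  step that corrects indel reference depths, and strict VAF/depth filtering.
* **Transcript awareness** — project annotation onto transcript coordinates,
  disjoin a gene's exons into constant-membership bins, and report each
  variant's *equivalence class*: the set of transcripts whose exons contain
  its full span, with per-transcript coordinates.
* **Consequences** — codon-level predictions (missense, nonsense,
  frameshift, inframe indels, UTR/noncoding, ...) computed independently in
  genomic and transcript space, plus VCF, VEP-CSQ, and MAF interchange.
* **ITD screening** — per-position soft-clip tallies and a hotspot rule that
  flags samples with clustered clipped read ends.
* **Synthetic data** — a seeded generator producing a genome, gene models,
  aligned reads with spiked variants/ITDs at target VAFs, and a truth table;
  every test and the acceptance script run on generated data only.

## Worked example

Generate a study fixture: two genes (three plus-strand transcripts with
nested first exons, one minus-strand transcript), a spiked SNV at VAF 0.5, a
4 bp deletion at VAF 0.4, and a 60 bp ITD supported by 40 reads:

```sh
$ slicetally simulate --seed 11 \
    --spike chr1:1150:SNV:0.5:200 --spike chr2:2150:DEL:0.4:100:4 \
    --itd chr1:5000:60:40 --out-dir fixture
reference	fixture/genome.fa
gff3	fixture/annotation.gff3
tx_fasta	fixture/transcripts.fa
bam_genomic	fixture/reads_genomic.bam
truth_genomic	fixture/truth_genomic.tsv
```

Tally alleles over the two genes' exons and keep calls passing the strict
filters (VAF > 0.15 and depth > 8):

```sh
$ slicetally tally --bam fixture/reads_genomic.bam \
    --genes GENEA,GENEB --gff3 fixture/annotation.gff3 \
    --reference fixture/genome.fa --min-base-quality 20 --out tally.tsv
37 variant rows -> tally.tsv
$ slicetally filter --table tally.tsv --out kept.tsv
2/37 rows kept -> kept.tsv
$ cat kept.tsv
contig	position	ref	alt	variant_type	alt_depth	ref_depth	total_depth	vaf	file_id
chr1	1150	C	G	SNV	129	145	274	0.4708029197080292	reads_genomic
chr2	2150	CACAC	C	DEL	44	68	112	0.3928571428571428	reads_genomic
```

Both planted variants come back at their target VAFs; the 35 background rows
(sequencing-error singletons) are filtered away. Annotate against every
transcript (the genome is random sequence, so codons are arbitrary):

```sh
$ slicetally annotate --table kept.tsv --gff3 fixture/annotation.gff3 \
    --reference fixture/genome.fa --out annotated.tsv
4 consequence rows -> annotated.tsv
```

| contig | position | ref | alt | tx_id | consequence | region_label | hgvsp | vaf |
|---|---|---|---|---|---|---|---|---|
| chr1 | 1150 | C | G | T1 | missense | start_codon | p.P1R | 0.4708 |
| chr1 | 1150 | C | G | T2 | missense | start_codon | p.Q1E | 0.4708 |
| chr1 | 1150 | C | G | T3 | noncoding_variant | noncoding | | 0.4708 |
| chr2 | 2150 | CACAC | C | T4 | frameshift | CDS | p.R33fs | 0.3929 |

The same SNV is coding on T1 and T2 but noncoding on T3 — its equivalence
class makes the transcript structure explicit:

```sh
$ slicetally eqclass --gff3 fixture/annotation.gff3 --gene GENEA \
    --variant chr1:1150:C:G
{
  "tx_set": ["T1", "T2", "T3"],
  "per_tx_position": {"T1": 51, "T2": 51, "T3": 11}
}
```

Screen for ITDs: the planted duplication produces two soft-clip hotspots, one
at each junction, each supported by exactly the 40 planted reads:

```sh
$ slicetally softclip --bam fixture/reads_genomic.bam \
    --region chr1:4600-5400 --out softclips.tsv
FLAGGED reads_genomic: 4941:40, 5001:40
```

Export for downstream tools:

```sh
$ slicetally vep-vcf --table kept.tsv --out sites.vcf   # sites-only VCF
$ slicetally maf --table annotated.tsv --out out.maf    # MAF with depths
```

`out.maf` carries the usual conventions (anchor base stripped, `-` alleles,
`Frame_Shift_Del` etc.):

```
Hugo_Symbol Chromosome Start_Position Reference_Allele Tumor_Seq_Allele2 Variant_Classification Variant_Type t_depth t_alt_count
GENEB       chr2       2151           ACAC             -                 Frame_Shift_Del        DEL          112     44
```

The same steps are available as a Python API (`slicetally.tally_reads`,
`slicetally.equivalence_class`, `slicetally.predict_consequences`, ...); the
remote path (`query_available`, `build_manifest`, `download_sliced`) can be
exercised offline against `slicetally.mockgdc.MockGdcServer`. See
`docs/methods.md` for the definitions behind each step.

## Reproducing results

The test suite builds all of its fixtures programmatically and checks the
implementation against independent brute-force oracles (a per-read CIGAR-walk
pileup, enumerated transcript containment, a direct CIGAR scan for soft
clips):

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end contracts (pileup/oracle
equivalence on random BAMs, VAF recovery within 99% binomial intervals,
coordinate round trips, equivalence-class enumeration, dual-path annotation
agreement, filter boundary semantics, ITD flagging, format round trips, and
the remote byte-exactness/auth/idempotency contract).

The headline quantities can be recomputed in one shot; all randomness derives
from `--seed`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The output maps each quantity to `{"value": ..., "n": ...}` where `n` is the
number of units it was computed over (fixtures, variants, bases, samples or
files, as appropriate).
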