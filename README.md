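# isoscope

Isoform discovery from error-prone long-read amplicon sequencing.

Full-length cDNA amplicons sequenced with 1D nanopore reads carry the
entire structure of each transcript isoform in a single read — but at
~10% base error, too noisy to place exon boundaries. `isoscope`
implements **reference-guided self-correction** for this setting, aimed
at anyone cataloguing the isoforms of a single amplified locus (e.g. the
transcripts of one promoter) from MinION-class data: reads are grouped by
a *loose* exon structure derived from their genome alignments, errors are
corrected by consensus *within* each group (so correction never borrows
sequence across isoforms and cannot skew the catalog toward abundant
ones), and the corrected reads are matched base-pair-exactly against an
elected exon catalog.

## Method

For reads $r_1, \dots, r_n$ spliced-aligned to the locus:

1. **Blocks and groups.** Merge all aligned exons into maximal
   overlapping genomic blocks $B_1 < \dots < B_m$; group reads by their
   signature, the ordered set of blocks their exon chain touches.
2. **Star consensus, two rounds.** Within each multi-member group, align
   every member to the medoid member and take a per-column majority over
   match/substitution/indel events; every member receives the consensus.
   Re-align the round-1 consensi, re-derive groups on the now
   boundary-accurate blocks, and re-correct the *original raw reads*
   within the round-2 groups, so round-1 mis-grouping does not bias the
   output. Unaligned reads and single-member groups pass through
   uncorrected — correction is partial by design.
3. **Exon catalog.** After primer filtering, elect per block the most
   frequent boundary pair $(s, e)$ as the representative exon ("rex"),
   and admit any alternative pair supported by more than 5% of the
   block's exon-containing reads as a boundary variant, written
   `L{d5}:R{d3}` (positive = extension, negative = truncation). An exon
   with $\ell \equiv 0 \pmod 3$ is *symmetric*: skipping it preserves the
   reading frame. Exons are classed **stable** (>90% of exact-match
   reads), **variable** (10–90%) or **rare** (0.01–10%).
4. **Isoforms.** A read counts toward an isoform only if its whole chain
   equals a combination of representatives and variants exactly. Isoforms
   with ≥20 supporting reads are high-confidence; ≥3, minimum evidence.

A ground-truth simulator (locus, isoform mixture over exon classes,
error-laden barcoded reads, off-target fraction) makes the entire
pipeline testable with no external data. See `docs/methods.md` for the
full model and parameter discussion.

## Worked example

Simulate an 8-exon locus (2 variable, 1 rare exon), a 6-isoform mixture
and 600 reads at ~9% error over three barcoded replicates, then run the
full pipeline importing the simulator's truth alignments:

```sh
isoscope simulate --n-exons 8 --n-variable 2 --n-rare 1 --n-isoforms 6 \
    --n-reads 600 --seed 42 --out-dir sim
isoscope run --reads sim/rep1.fastq --reads sim/rep2.fastq \
    --reads sim/rep3.fastq --reference sim/reference.fasta \
    --aligner import --alignments sim/truth_alignments.bed12 \
    --seed 42 --out-dir out
```

prints the read funnel and summary:

```
input: 600
aligned: 569
corrected: 569
primer_filtered: 569
exact_matched: 566
exons: 8, variants: 1, isoforms: 5
```

600 reads enter; 569 align (the rest are the simulated off-target
fraction), survive correction and primer filtering, and 566 match the
catalog exactly. `out/exons.tsv` holds the elected catalog:

```
name	chrom	start	end	length	symmetric	frequency	state	annotation
rex01	locus	100	172	72	True	1.0	stable	unannotated
rex02	locus	553	797	244	False	0.572438	variable	unannotated
...
rex06	locus	2266	2531	265	False	0.074205	rare	unannotated
...
```

— every boundary equals the simulated truth; the planted rare exon
(rex06) is recovered at 7.4% frequency, inside the rare band. The isoform
matrix `out/isoforms.tsv` ranks isoforms by pooled support with
per-replicate counts:

```
isoform	rank	total	tier	rep1	rep2	rep3
rex01,rex02,rex03,rex05,rex07,rex08	1	264	high_confidence	95	90	79
rex01,rex03,rex04,rex05,rex07,rex08	2	179	high_confidence	51	67	61
...
```

All five simulated isoforms with more than a handful of reads are
recovered with their true exon chains; the sixth, drawn at 3 reads, is
below the correctable depth. `out/junctions.tsv` and the `report`
subcommand give exon–exon junction counts and cumulative coverage by
rank.

The same pipeline runs on real data by pointing `--reads` at
demultiplexed FASTQ files, `--reference` at the locus FASTA, and either
using the built-in aligner (`--aligner builtin`, desk-scale loci) or
importing primary spliced alignments from an external aligner (SAM/BAM,
PAF or BED12) via `--aligner import`.

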