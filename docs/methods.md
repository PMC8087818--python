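# Methods

## Problem and approach

Amplicon sequencing of full-length cDNA with 1D nanopore reads yields
complete isoform structures but with ~10% base error, enough to blur exon
boundaries beyond use. `isoscope` implements a reference-guided
self-correction strategy for this setting: errors are corrected *within
groups of reads that share a loose exon structure*, so that correction
never mixes information across isoforms and therefore cannot skew the
catalog toward abundant isoforms the way plain self-correction or
short-read hybrid correction can.

The pipeline, over one amplified locus:

1. **Spliced alignment.** Reads are aligned to the locus either with the
   built-in anchor-chain aligner (desk scale) or by importing an external
   aligner's primary alignments (SAM/BAM, PAF, or BED12). Secondary and
   supplementary records are discarded. Coordinates are uniformly 0-based
   half-open on the forward strand; exon chains are genomic-ascending with
   a strand flag, so isoform identity is orientation-invariant.
2. **Grouping.** All aligned exons are merged into maximal overlapping
   genomic blocks; a read's signature is the ordered set of blocks its
   exons touch. Reads with equal signatures form a group. Signatures are
   deliberately coarse: boundary jitter from residual errors does not
   split a group.
3. **Consensus correction, two rounds.** Within each multi-member group, a
   star consensus is built: the medoid member (highest mean pairwise edit
   identity; ties broken by length then read id) serves as template, all
   members are aligned to it with edlib, and a per-template-column
   majority vote over match/substitution/deletion events — plus a
   majority-of-members vote for insertions at each junction — produces one
   consensus assigned to every member. The round-1 consensi are re-aligned
   (their boundaries are now accurate), groups are re-derived on the
   refined blocks, and the *original raw reads* are re-corrected inside
   the round-2 groups, so any round-1 mis-grouping does not propagate into
   the final sequences. Reads that fail alignment, or sit in single-member
   groups, pass through uncorrected and are excluded from corrected
   counts; correction is partial by design, as with real amplicon data.
4. **Exon catalog.** Corrected reads are aligned, filtered to chains
   overlapping both primer-target intervals, and their exons merged into
   blocks again. Per block the most frequent (start, end) pair is elected
   representative ("rex01", "rex02", ... in genomic order; ties toward the
   smaller start, then end). Any other pair supported by strictly more
   than `variant_frac` of that block's exon-containing reads is admitted
   as a boundary variant, named by an `L{d5}:R{d3}` pattern where positive
   values extend and negative values truncate the 5'/3' ends relative to
   the representative.
5. **Isoform calling.** A read is assigned an isoform only if its entire
   chain equals, base-pair-exactly, a sequence of catalog elements from
   strictly ascending blocks (block skipping allowed — exon skipping is
   the object of study). Records are ranked by pooled read total and
   tiered: >= `high_conf_reads` supporting reads is high-confidence,
   >= `min_evidence_reads` minimum-evidence, below that singleton-zone.
   Junction counts, cumulative coverage by rank, and Spearman replicate
   correlations are derived from the matched keys.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `variant_frac` | 0.05 | boundary variant admitted above this fraction of the block's exon-containing reads (strict >) |
| `stable_frac` / `variable_frac` / `rare_min_frac` | 0.90 / 0.10 / 0.0001 | exon state bands: stable above 90%, variable 10–90%, rare 0.01–10% of exact-match reads; below 0.01% excluded |
| `high_conf_reads` / `min_evidence_reads` | 20 / 3 | isoform confidence tiers (reads) |
| `anchor_k` | 12 | exact k-mer anchor size of the built-in aligner |
| `error_rates` | (0.04, 0.03, 0.03) | simulation substitution/insertion/deletion probabilities per base (~10% total) |
| `match_tolerance` | 0 | bp slack in isoform matching; exactness is the default and the point |

`stable_frac` = 0.90 is a judgment call — "present in nearly all reads" is
not a number — and is configurable. Exon *frequency* uses exact-match
reads as denominator; variant *support* uses reads containing any exon of
the block. The two denominators are different on purpose and both logged.

## Built-in aligner internals

Exact k-mer anchors are chained colinearly (weighted LIS with a bounded
lookback of 64 anchors). A genomic gap >= 30 bp with a read gap < 30 bp
between adjacent anchors opens an intron. The junction inside each such
gap is placed by scoring every split of the unplaced read bases between
the flanking exons, with a +2 bonus per side when the implied intron
starts GT / ends AG, so ties from ambiguous flanking bases resolve onto
the canonical motif; 8 bp of each flanking anchor are softened during this
search because a chance k-mer match can overlap the true junction by a few
bases. A residual joint shift of up to ±6 bp onto a motif handles indels
near the junction. Reads whose chained anchors cover < 25% of their length
are rejected as off-target. These heuristics are tuned for a single locus
of up to a few hundred kb; the aligner is not a general-purpose spliced
aligner, and external alignments bypass it entirely (the two sources are
never mixed in one run).

## Consensus corrector

The corrector is pluggable behind `correct_group(reads) -> reads`; the
built-in star consensus replaces any external correction tool. One
corrected sequence is emitted *per input read* (the group consensus,
preserving read ids), emulating read-level correction. Medoid election
subsamples groups larger than 30 members (seeded) to keep the pairwise
identity matrix quadratic in 30, not in group size. Majority ties at a
template column resolve toward the template's own base, then
lexicographically; insertion strings need a strict majority of members.
Consensus is idempotent: a group of identical sequences is returned
unchanged.

A consequence of one-consensus-per-group correction: round 2 can merge
round-1 groups (over-segmented isoforms re-unite once their consensi align
identically) but can never split one round-1 group into two. The
round-over-round guarantee is therefore *agreement*, not group count:
round-2 groups agree with true isoform labels at least as well as round-1
groups (measured by adjusted Rand index on simulations), which is what the
test suite asserts.

## Simulator

`make_locus` draws a random locus with ascending exons (default 50–300 bp,
optionally one multi-kb exon) separated by GT...AG introns (>= 34 bp).
`make_isoforms` samples structures over stable/variable/rare exon classes
— stable and the two primer-anchored terminal exons always included,
variable with probability 0.5, rare with probability 0.08 — resampling
until every exon is expressed by at least one isoform (a locus exon no
transcript uses is not an exon of the mixture). Frequencies are Dirichlet
weights, down-weighted per included rare exon and floored at 0.01, the
bottom of the rare band, so every isoform is observable at realistic
depths. `simulate_reads` applies i.i.d. per-base substitutions, insertions
and deletions, assigns reads round-robin to barcoded replicates, and draws
an `offtarget_frac` (default 5%) of reads from unrelated random sequence.
Ground truth (isoform of origin, true alignment, sample) is emitted for
every read, and truth alignments can be imported so correction and calling
are tested independently of aligner quality.

What the error model does *not* emulate: homopolymer-biased indels,
quality-correlated errors, chimeric reads, or PCR amplification bias.
Passing recovery tests therefore demonstrate the correctness of grouping,
consensus and calling under the stated error magnitude — not robustness to
every artifact of real nanopore data.

## Benchmark problem sizes

The standard recovery benchmark (`recovery_mixture`) uses a 20-exon locus
(14 stable, 3 variable, 3 rare; one 800 bp exon), 12 isoforms, 2000 reads
at 7% total error across three replicates with 5% off-target reads. At
these sizes a full pipeline run takes well under a minute on one CPU while
still exercising two correction rounds, variant detection and tier
assignment; recovered representatives equal the true boundaries exactly
and recovered isoform frequencies track the truth (Spearman > 0.9).

## Published-catalog data

The published 29-exon TACC2 p10 catalog and its 21 boundary variants ship
as package data. Only names, coordinates, states, annotation status and
pattern strings are primary; lengths, symmetry flags and variant
arithmetic are always recomputed from the coordinates, and the printed
flags in the variant table serve purely as an independent cross-check. A
variation's symmetric flag means the *length change* is a multiple of 3
(the swap preserves the downstream reading frame); an exon's symmetric
flag means its own length is (skipping it preserves frame). The two
notions differ: a variant of an asymmetric exon can itself be a
frame-preserving change.

## Known limitations

- The built-in aligner assumes one locus and canonical splice motifs;
  non-canonical junctions are placed by edit distance only.
- Star consensus degrades for groups of 2–4 members (majority is weak);
  such isoforms survive but with more residual error, and singleton
  isoforms are never corrected, mirroring the method's inherent attrition.
- Isoform quantification across samples is reported but not normalized;
  no differential-usage statistics are attempted.
- Annotation matching is exact-boundary or any-overlap; no tolerance tier
  in between, and no assembly liftover.
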