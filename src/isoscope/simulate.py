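"""Synthetic amplicon data with full ground truth.

Emulates the study design end to end: a multi-exon locus with canonical
GT...AG intron motifs, an isoform mixture built over stable / variable /
rare exon classes, and barcoded replicate read sets carrying ~10% combined
substitution/indel error plus a fraction of off-target reads from unrelated
sequence (non-specific priming). Every read's isoform of origin and true
spliced alignment are recorded so recovery can be scored exactly, and the
truth alignments can be fed back through ``--aligner import`` to test
correction and calling independently of aligner quality.

The error process is i.i.d. per base — substitution, insertion and deletion
probabilities applied independently — which reproduces the overall error
magnitude of 1D nanopore reads but none of their homopolymer structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import export_bed12, write_fastq
from .model import ErrorRates, GenomeInterval, LongRead, SplicedAlignment

BASES = np.array(list("ACGT"))

DEFAULT_ERROR_RATES: ErrorRates = (0.04, 0.03, 0.03)


@dataclass
class Locus:
    """A simulated amplified locus with its true exons."""

    chrom: str
    reference: str
    exons: List[GenomeInterval]


@dataclass
class ReadProvenance:
    isoform: Optional[int]  # index into true isoforms; None = off-target
    sample_id: str
    alignment: Optional[SplicedAlignment]


@dataclass
class SimTruth:
    """Everything needed to score recovery of the simulated mixture."""

    locus: Locus
    classes: List[str]
    isoforms: List[Tuple[Tuple[int, ...], float]]
    reads: List[LongRead] = field(default_factory=list)
    per_read: Dict[str, ReadProvenance] = field(default_factory=dict)

    def truth_alignments(self) -> Dict[str, SplicedAlignment]:
        return {
            rid: prov.alignment
            for rid, prov in self.per_read.items()
            if prov.alignment is not None
        }

    def isoform_chain(self, index: int) -> Tuple[Tuple[int, int], ...]:
        incl, _ = self.isoforms[index]
        return tuple(
            (self.locus.exons[i].start, self.locus.exons[i].end) for i in incl
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_locus(
    n_exons: int,
    seed: int,
    exon_length_range: Tuple[int, int] = (50, 300),
    intron_length_range: Tuple[int, int] = (80, 400),
    long_exon: Optional[Tuple[int, int]] = None,
    flank: int = 100,
    chrom: str = "locus",
) -> Locus:
    """Random locus with ``n_exons`` ascending exons and GT...AG introns.

    ``long_exon`` = (index, length) plants one oversized exon, mirroring
    loci with a single multi-kb exon among ordinary ones.
    """
    if n_exons < 2:
        raise ValueError("need at least 2 exons")
    lo, hi = exon_length_range
    ilo, ihi = intron_length_range
    if lo < 1 or ilo < 34:
        raise ValueError("exon >= 1 bp and intron >= 34 bp required")
    rng = np.random.default_rng(seed)
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_exons)]
    if long_exon is not None:
        idx, ln = long_exon
        lengths[idx] = ln
    parts: List[str] = [_random_seq(rng, flank)]
    exons: List[GenomeInterval] = []
    pos = flank
    for i, ln in enumerate(lengths):
        exons.append(GenomeInterval(chrom, pos, pos + ln))
        parts.append(_random_seq(rng, ln))
        pos += ln
        if i < n_exons - 1:
            iln = int(rng.integers(ilo, ihi + 1))
            intron = "GT" + _random_seq(rng, iln - 4) + "AG"
            parts.append(intron)
            pos += iln
    parts.append(_random_seq(rng, flank))
    return Locus(chrom=chrom, reference="".join(parts), exons=exons)


def make_isoforms(
    locus: Locus,
    classes: Sequence[str],
    n_isoforms: int,
    seed: int,
    variable_p: float = 0.5,
    rare_p: float = 0.08,
    rare_weight: float = 0.05,
    min_frac: float = 0.01,
    exhaustive: bool = False,
) -> List[Tuple[Tuple[int, ...], float]]:
    """Sample an isoform mixture over the exon classes.

    Stable exons (and the first/last, primer-anchored exons) are always
    included; variable exons per-isoform with probability ``variable_p``;
    rare exons with probability ``rare_p``. Duplicate structures merge, and
    the mixture is resampled until every exon is expressed by at least one
    isoform — a locus exon that no transcript uses is not an exon of the
    mixture. Frequencies are Dirichlet-distributed, down-weighted by
    ``rare_weight`` per included rare exon so rare exons land in the rare
    frequency band, then floored at ``min_frac`` (the bottom of that band)
    so every isoform is actually observable at realistic read depths.
    ``exhaustive`` instead enumerates every variable-exon combination
    (no rare exons), yielding exactly 2^n_variable isoforms.
    """
    if len(classes) != len(locus.exons):
        raise ValueError("one class label per exon required")
    rng = np.random.default_rng(seed)
    n = len(classes)
    always = {0, n - 1}
    structures: List[Tuple[int, ...]] = []
    if exhaustive:
        variable = [i for i, c in enumerate(classes) if c == "variable"]
        for mask in range(2 ** len(variable)):
            chosen = {v for b, v in enumerate(variable) if mask >> b & 1}
            structures.append(
                tuple(
                    i
                    for i, c in enumerate(classes)
                    if i in always or c == "stable" or i in chosen
                )
            )
    else:
        optional = [i for i, c in enumerate(classes)
                    if i not in always and c != "stable"]
        for _ in range(200):
            structures = []
            tries = 0
            while len(structures) < n_isoforms and tries < 200 * n_isoforms:
                tries += 1
                incl = []
                for i, c in enumerate(classes):
                    if i in always or c == "stable":
                        incl.append(i)
                    elif c == "variable" and rng.random() < variable_p:
                        incl.append(i)
                    elif c == "rare" and rng.random() < rare_p:
                        incl.append(i)
                s = tuple(incl)
                if s not in structures:
                    structures.append(s)
            covered = {i for s in structures for i in s}
            if all(i in covered for i in optional):
                break
    if not structures:
        raise ValueError("no isoforms generated")
    weights = np.asarray(rng.dirichlet(np.full(len(structures), 1.5)))
    if not exhaustive:
        for j, s in enumerate(structures):
            n_rare = sum(1 for i in s if classes[i] == "rare")
            weights[j] *= rare_weight ** n_rare
        weights /= weights.sum()
        weights = np.maximum(weights, min_frac)
    weights /= weights.sum()
    order = np.argsort(-weights)
    return [(structures[int(j)], float(weights[int(j)])) for j in order]


def _apply_errors(
    seq: str, rates: ErrorRates, rng: np.random.Generator
) -> str:
    p_sub, p_ins, p_del = rates
    out: List[str] = []
    for base in seq:
        if rng.random() < p_del:
            pass  # deletion
        elif rng.random() < p_sub:
            out.append(str(rng.choice(BASES[BASES != base])))
        else:
            out.append(base)
        if rng.random() < p_ins:
            out.append(str(rng.choice(BASES)))
    return "".join(out)


def simulate_reads(
    locus: Locus,
    isoforms: List[Tuple[Tuple[int, ...], float]],
    n_reads: int,
    seed: int,
    error_rates: ErrorRates = DEFAULT_ERROR_RATES,
    n_samples: int = 3,
    offtarget_frac: float = 0.05,
    classes: Optional[Sequence[str]] = None,
) -> SimTruth:
    """Draw error-laden barcoded reads from the isoform mixture.

    Reads are assigned round-robin to ``n_samples`` barcoded replicates;
    ``offtarget_frac`` of them come from random non-locus sequence instead,
    emulating non-specific priming. Deterministic for a fixed seed.
    """
    if n_reads < 1:
        raise ValueError("n_reads >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.array([f for _, f in isoforms])
    freqs = freqs / freqs.sum()
    truth = SimTruth(
        locus=locus,
        classes=list(classes) if classes is not None else ["stable"] * len(locus.exons),
        isoforms=isoforms,
    )
    spliced = [
        "".join(locus.reference[locus.exons[i].start : locus.exons[i].end] for i in incl)
        for incl, _ in isoforms
    ]
    mean_len = int(np.mean([len(s) for s in spliced]))
    for r in range(n_reads):
        read_id = f"read{r:06d}"
        sample_id = f"rep{r % n_samples + 1}"
        if rng.random() < offtarget_frac:
            seq = _apply_errors(_random_seq(rng, max(60, mean_len)), error_rates, rng)
            truth.per_read[read_id] = ReadProvenance(None, sample_id, None)
        else:
            iso = int(rng.choice(len(isoforms), p=freqs))
            seq = _apply_errors(spliced[iso], error_rates, rng)
            aln = SplicedAlignment(
                read_id=read_id,
                chrom=locus.chrom,
                strand="+",
                exons=[locus.exons[i] for i in isoforms[iso][0]],
            )
            truth.per_read[read_id] = ReadProvenance(iso, sample_id, aln)
        truth.reads.append(LongRead(read_id, sample_id, seq))
    return truth


def write_truth(truth: SimTruth, outdir) -> Dict[str, Path]:
    """Write reference FASTA, per-sample FASTQ, truth BED12 and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    ref = outdir / "reference.fasta"
    with open(ref, "w") as fh:
        fh.write(f">{truth.locus.chrom}\n")
        seq = truth.locus.reference
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    paths["reference"] = ref
    by_sample: Dict[str, List[LongRead]] = {}
    for r in truth.reads:
        by_sample.setdefault(r.sample_id, []).append(r)
    for sample, reads in sorted(by_sample.items()):
        p = outdir / f"{sample}.fastq"
        write_fastq(reads, p)
        paths[sample] = p
    bed = outdir / "truth_alignments.bed12"
    export_bed12(
        [truth.per_read[r.read_id].alignment
         for r in truth.reads
         if truth.per_read[r.read_id].alignment is not None],
        bed,
    )
    paths["alignments"] = bed
    iso_tsv = outdir / "truth_isoforms.tsv"
    with open(iso_tsv, "w") as fh:
        fh.write("isoform\texons\tfrequency\n")
        for j, (incl, freq) in enumerate(truth.isoforms):
            fh.write(f"{j}\t{','.join(map(str, incl))}\t{freq:.6g}\n")
    paths["isoforms"] = iso_tsv
    reads_tsv = outdir / "truth_reads.tsv"
    with open(reads_tsv, "w") as fh:
        fh.write("read_id\tsample\tisoform\n")
        for r in truth.reads:
            prov = truth.per_read[r.read_id]
            iso = "offtarget" if prov.isoform is None else str(prov.isoform)
            fh.write(f"{r.read_id}\t{r.sample_id}\t{iso}\n")
    paths["reads"] = reads_tsv
    return paths


def recovery_mixture(seed: int, n_reads: int = 2000) -> SimTruth:
    """The standard recovery benchmark: a 20-exon locus (14 stable, 3
    variable, 3 rare exons), a 12-isoform mixture, and ``n_reads`` reads at
    7% total error across three barcoded replicates."""
    classes = (
        ["stable"] * 4 + ["variable"] + ["stable"] * 3 + ["rare"]
        + ["stable"] * 2 + ["variable"] + ["rare"] + ["stable"] * 2
        + ["variable"] + ["rare"] + ["stable"] * 3
    )
    assert len(classes) == 20
    locus = make_locus(20, seed=seed, long_exon=(5, 800))
    isoforms = make_isoforms(locus, classes, n_isoforms=12, seed=seed + 1)
    return simulate_reads(
        locus,
        isoforms,
        n_reads=n_reads,
        seed=seed + 2,
        error_rates=(0.03, 0.02, 0.02),
        n_samples=3,
        offtarget_frac=0.05,
        classes=classes,
    )
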