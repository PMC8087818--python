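"""Readers and writers for the standard formats the pipeline touches.

FASTQ via Bio.SeqIO, FASTA via pyfaidx, SAM/BAM via pysam; PAF and BED12 are
parsed directly from their tab-separated fields. All coordinates are
normalized to 0-based half-open on the forward genome strand, and intron
gaps ('N' CIGAR operations, or BED12 block gaps) split the exon chain.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Union

import pysam
from Bio import SeqIO

from .model import GenomeInterval, LongRead, SplicedAlignment

PathLike = Union[str, os.PathLike]


class ParseError(ValueError):
    """A malformed record in an input file."""


def _open_text(path: PathLike):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: PathLike, sample_id: Optional[str] = None) -> Iterator[LongRead]:
    """Stream LongReads from a (possibly gzipped) FASTQ file.

    ``sample_id`` defaults to the filename stem, the usual layout for
    demultiplexed per-barcode files.
    """
    if sample_id is None:
        sample_id = Path(str(path).removesuffix(".gz")).stem
    n = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                n += 1
                yield LongRead(
                    read_id=rec.id,
                    sample_id=sample_id,
                    sequence=str(rec.seq),
                    qualities=rec.letter_annotations.get("phred_quality"),
                )
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed FASTQ near line {4 * n + 1}: {exc}"
            ) from exc


def write_fastq(reads: Iterable[LongRead], path: PathLike) -> None:
    with _open_text_w(path) as fh:
        for r in reads:
            quals = r.qualities
            if quals is None:
                qual_str = "I" * len(r.sequence)
            else:
                qual_str = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual_str}\n")


def _open_text_w(path: PathLike):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def read_reference(path: PathLike, contig: Optional[str] = None) -> str:
    """Load one contig (default: the first) of a FASTA file as a string."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    keys = list(fa.keys())
    if not keys:
        raise ParseError(f"{path}: empty FASTA")
    name = contig if contig is not None else keys[0]
    return str(fa[name][:])


# --- alignment import -------------------------------------------------------

_SAM_REF_CONSUMERS = set("MDN=X")
_SAM_EXON_CONSUMERS = set("MD=X")


def _exons_from_cigar(
    chrom: str, pos: int, cigar: Iterable[tuple]
) -> List[GenomeInterval]:
    """Walk (op, length) pairs; 'N' ops split exons, M/=/X/D extend them."""
    exons: List[GenomeInterval] = []
    exon_start = pos
    cur = pos
    for op, length in cigar:
        if op in _SAM_EXON_CONSUMERS:
            cur += length
        elif op == "N":
            if cur > exon_start:
                exons.append(GenomeInterval(chrom, exon_start, cur))
            cur += length
            exon_start = cur
    if cur > exon_start:
        exons.append(GenomeInterval(chrom, exon_start, cur))
    return exons


_CIGAR_CODES = "MIDNSHP=X"


def _import_sam(path: PathLike) -> List[SplicedAlignment]:
    out: List[SplicedAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cigar = [(_CIGAR_CODES[op], ln) for op, ln in rec.cigartuples or []]
            exons = _exons_from_cigar(rec.reference_name, rec.reference_start, cigar)
            if not exons:
                continue
            identity = 1.0
            if rec.has_tag("NM"):
                aligned = sum(ln for op, ln in cigar if op in set("MI=X"))
                if aligned > 0:
                    identity = max(0.0, 1.0 - rec.get_tag("NM") / aligned)
            out.append(
                SplicedAlignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    exons=exons,
                    identity=identity,
                )
            )
    return out


def _parse_paf_cigar(cg: str) -> List[tuple]:
    ops, num = [], ""
    for ch in cg:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def _import_paf(path: PathLike) -> List[SplicedAlignment]:
    out: List[SplicedAlignment] = []
    with _open_text(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{ln_no}: PAF record with <12 fields")
            tags = dict(
                (f.split(":", 2)[0], f.split(":", 2)[2]) for f in fields[12:] if ":" in f
            )
            if tags.get("tp", "P") != "P":  # secondary/inversion records
                continue
            tstart = int(fields[7])
            nmatch, alnlen = int(fields[9]), int(fields[10])
            cg = tags.get("cg")
            if cg:
                exons = _exons_from_cigar(fields[5], tstart, _parse_paf_cigar(cg))
            else:
                exons = [GenomeInterval(fields[5], tstart, int(fields[8]))]
            out.append(
                SplicedAlignment(
                    read_id=fields[0],
                    chrom=fields[5],
                    strand=fields[4],
                    exons=exons,
                    identity=nmatch / alnlen if alnlen else 0.0,
                )
            )
    return out


def _import_bed12(path: PathLike) -> List[SplicedAlignment]:
    out: List[SplicedAlignment] = []
    with _open_text(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{ln_no}: BED12 record with <12 fields")
            chrom, chrom_start = f[0], int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ParseError(f"{path}:{ln_no}: blockCount mismatch")
            exons = [
                GenomeInterval(chrom, chrom_start + s, chrom_start + s + sz)
                for s, sz in zip(starts, sizes)
            ]
            out.append(
                SplicedAlignment(
                    read_id=f[3],
                    chrom=chrom,
                    strand=f[5] if f[5] in "+-" else "+",
                    exons=exons,
                )
            )
    return out


def import_alignments(path: PathLike, format: str) -> List[SplicedAlignment]:
    """Import primary spliced alignments from SAM/BAM, PAF or BED12.

    Secondary and supplementary records are discarded; only the aligner's
    best placement of each read enters grouping.
    """
    importers = {"sam": _import_sam, "bam": _import_sam,
                 "paf": _import_paf, "bed12": _import_bed12}
    if format not in importers:
        raise ValueError(f"unknown alignment format {format!r}")
    return importers[format](path)


def export_bed12(
    alignments: Sequence[SplicedAlignment], path: PathLike
) -> None:
    """Write exon chains as BED12; lossless round-trip with import."""
    with _open_text_w(path) as fh:
        for aln in alignments:
            start, end = aln.start, aln.end
            sizes = ",".join(str(e.length) for e in aln.exons)
            starts = ",".join(str(e.start - start) for e in aln.exons)
            fh.write(
                "\t".join(
                    [
                        aln.chrom, str(start), str(end), aln.read_id, "0",
                        aln.strand, str(start), str(end), "0",
                        str(len(aln.exons)), sizes, starts,
                    ]
                )
                + "\n"
            )


# --- annotation -------------------------------------------------------------


def load_annotation(path: PathLike, format: Optional[str] = None) -> List[GenomeInterval]:
    """Load annotated exons from a GTF or BED12 gene-model file."""
    if format is None:
        format = "gtf" if str(path).rstrip(".gz").endswith((".gtf", ".gff")) else "bed12"
    if format == "bed12":
        exons = []
        for aln in _import_bed12(path):
            exons.extend(aln.exons)
        return sorted(set(exons))
    if format != "gtf":
        raise ValueError(f"unknown annotation format {format!r}")
    exons = set()
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8 or f[2].lower() != "exon":
                continue
            # GTF is 1-based inclusive; convert to 0-based half-open
            exons.add(GenomeInterval(f[0], int(f[3]) - 1, int(f[4])))
    return sorted(exons)
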