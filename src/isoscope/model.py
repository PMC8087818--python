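"""Core domain types shared by every pipeline stage.

Coordinates are 0-based half-open on the forward genome strand throughout,
so ``length = end - start`` and adjacent intervals share a boundary without
overlap. Exon chains are always stored in genomic (ascending) order even for
reverse-strand alignments; a ``strand`` flag records the orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class LongRead:
    """A single long read with optional per-base qualities."""

    read_id: str
    sample_id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.read_id}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SplicedAlignment:
    """A read's ordered exon chain on the genome.

    ``exons`` are non-overlapping and strictly ascending; this is the atom of
    grouping, correction and isoform matching.
    """

    read_id: str
    chrom: str
    strand: str
    exons: Tuple[GenomeInterval, ...]
    is_primary: bool = True
    identity: float = 1.0

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        if not self.exons:
            raise ValueError(f"alignment {self.read_id}: no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"alignment {self.read_id}: bad strand {self.strand!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"alignment {self.read_id}: identity {self.identity}")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom != b.chrom or b.start < a.end:
                raise ValueError(
                    f"alignment {self.read_id}: exon chain not ascending/"
                    f"non-overlapping at {a}..{b}"
                )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def aligned_length(self) -> int:
        return sum(e.length for e in self.exons)

    def chain(self) -> Tuple[Tuple[int, int], ...]:
        """Exon chain as plain (start, end) tuples, the grouping key."""
        return tuple((e.start, e.end) for e in self.exons)


@dataclass(frozen=True)
class ExonBlock:
    """A maximal run of mutually overlapping aligned exons, merged."""

    block_id: int
    interval: GenomeInterval


@dataclass
class ReadGroup:
    """Reads sharing one exon-block signature within a correction round."""

    signature: Tuple[int, ...]
    members: list
    round: int = 1


ErrorRates = Tuple[float, float, float]  # substitution, insertion, deletion


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline.

    Defaults follow the published analysis: boundary variants need more than
    5% of exon-containing reads; exons in >10% of reads are at least
    variable, those present in nearly all (>90%) stable, and those down to
    0.01% rare; isoforms with >=20 reads are high-confidence and >=3 reads
    minimum-evidence. The simulation error budget is ~10% split across
    substitutions/insertions/deletions, matching 1D nanopore reads.
    """

    variant_frac: float = 0.05
    variable_frac: float = 0.10
    rare_min_frac: float = 0.0001
    stable_frac: float = 0.90
    high_conf_reads: int = 20
    min_evidence_reads: int = 3
    primer_intervals: Optional[Tuple[GenomeInterval, GenomeInterval]] = None
    anchor_k: int = 12
    error_rates: ErrorRates = (0.04, 0.03, 0.03)
    seed: int = 0
    # optional outer boundaries of the first/last amplified exons taken from
    # a known gene model (the primer-design model); None elects them like
    # any other block
    primer_model_boundaries: Optional[Tuple[int, int]] = None
    match_tolerance: int = 0  # bp slack for isoform matching; 0 = bp-exact

    def __post_init__(self) -> None:
        if not (0 < self.rare_min_frac < self.variable_frac < self.stable_frac < 1):
            raise ValueError(
                "need 0 < rare_min_frac < variable_frac < stable_frac < 1"
            )
        if not (self.high_conf_reads >= self.min_evidence_reads >= 1):
            raise ValueError("need high_conf_reads >= min_evidence_reads >= 1")
        if not 0 < self.variant_frac < 1:
            raise ValueError("variant_frac must be in (0, 1)")
        if any(not 0 <= r < 1 for r in self.error_rates):
            raise ValueError("error rates must be in [0, 1)")
        if self.anchor_k < 4:
            raise ValueError("anchor_k too small to anchor anything")

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)
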