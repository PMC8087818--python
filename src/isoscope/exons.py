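"""Representative-exon election, boundary variants, and exon classification.

Aligned exons falling in one merged genomic block are treated as observations
of the same underlying exon region ("rex"). The most frequent (start, end)
pair is elected as the representative boundary; alternative pairs supported
by more than ``variant_frac`` of the block's exon-containing reads are
admitted as boundary variants and named by an "L{d5}:R{d3}" pattern
(positive = extension, negative = truncation, L = 5'/left on the forward
strand, R = 3'/right).

An exon whose length is a multiple of 3 is *symmetric*: skipping it leaves
the downstream reading frame intact. A variant whose length change is a
multiple of 3 likewise preserves frame relative to the representative.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import ExonBlock, GenomeInterval, PipelineConfig, SplicedAlignment

STATE_STABLE = "stable"
STATE_VARIABLE = "variable"
STATE_RARE = "rare"

ANNOT_KNOWN = "known"
ANNOT_PARTIAL = "partially_known"
ANNOT_NOVEL = "novel"
ANNOT_NONE = "unannotated"


def is_symmetric(length: int) -> bool:
    """True iff an exon of ``length`` bp can be skipped frame-neutrally."""
    if length < 0:
        raise ValueError("negative exon length")
    return length % 3 == 0


def classify_exon_state(frequency: float, config: PipelineConfig) -> Optional[str]:
    """Map an exon's read frequency to stable/variable/rare.

    Returns None for exons below ``rare_min_frac``, which are excluded from
    the catalog.
    """
    if not 0.0 <= frequency <= 1.0:
        raise ValueError(f"frequency {frequency} outside [0, 1]")
    if frequency > config.stable_frac:
        return STATE_STABLE
    if frequency > config.variable_frac:
        return STATE_VARIABLE
    if frequency >= config.rare_min_frac:
        return STATE_RARE
    return None


@dataclass
class RepresentativeExon:
    """An elected exon region: one row of the exon catalog."""

    rex_id: str
    interval: GenomeInterval
    frequency: float = 0.0
    state: str = STATE_RARE
    annotation: str = ANNOT_NONE
    block_id: int = -1
    read_count: int = 0

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def symmetric(self) -> bool:
        return is_symmetric(self.length)


@dataclass
class ExonVariant:
    """An alternative boundary pair for a representative exon."""

    parent: str
    interval: GenomeInterval
    pattern: str
    support_frac: float = 0.0
    read_count: int = 0
    shares_boundary: bool = True  # QC flag: 5' or 3' boundary equals parent's

    variant_id: str = ""

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def length_change(self) -> int:
        d5, d3 = parse_pattern(self.pattern)
        return d5 + d3

    @property
    def change_symmetric(self) -> bool:
        """True iff swapping this variant for its parent preserves frame."""
        return abs(self.length_change) % 3 == 0


@dataclass
class ExonCatalog:
    """Ordered representatives plus admitted boundary variants."""

    representatives: List[RepresentativeExon] = field(default_factory=list)
    variants: List[ExonVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.representatives, self.representatives[1:]):
            if b.interval.start < a.interval.end and b.interval.chrom == a.interval.chrom:
                raise ValueError("representatives overlap or are unsorted")
        names = {r.rex_id for r in self.representatives}
        for v in self.variants:
            if v.parent not in names:
                raise ValueError(f"variant parent {v.parent} not in catalog")

    def representative(self, rex_id: str) -> RepresentativeExon:
        for r in self.representatives:
            if r.rex_id == rex_id:
                return r
        raise KeyError(rex_id)

    def variants_of(self, rex_id: str) -> List[ExonVariant]:
        return [v for v in self.variants if v.parent == rex_id]

    def elements(self) -> Dict[str, GenomeInterval]:
        """All catalog element ids (representatives and variants) -> interval."""
        out = {r.rex_id: r.interval for r in self.representatives}
        out.update({v.variant_id: v.interval for v in self.variants})
        return out


_PATTERN_RE = re.compile(r"^L(-?\d+):R(-?\d+)$")


def pattern_string(variant: GenomeInterval, representative: GenomeInterval) -> str:
    """Render the boundary-change pattern of ``variant`` vs its representative.

    d5 = representative.start - variant.start (a variant starting earlier
    extends the 5' end, positive); d3 = variant.end - representative.end
    (a variant ending later extends the 3' end, positive).
    """
    d5 = representative.start - variant.start
    d3 = variant.end - representative.end
    return f"L{d5}:R{d3}"


def parse_pattern(pattern: str) -> Tuple[int, int]:
    m = _PATTERN_RE.match(pattern)
    if not m:
        raise ValueError(f"malformed boundary pattern {pattern!r}")
    return int(m.group(1)), int(m.group(2))


def apply_pattern(representative: GenomeInterval, pattern: str) -> GenomeInterval:
    """Reconstruct a variant interval from its parent and pattern string."""
    d5, d3 = parse_pattern(pattern)
    return GenomeInterval(
        representative.chrom, representative.start - d5, representative.end + d3
    )


def primer_filter(
    alignments: Iterable[SplicedAlignment],
    primer_intervals: Tuple[GenomeInterval, GenomeInterval],
) -> List[SplicedAlignment]:
    """Keep alignments whose exon chain overlaps both primer-target exons.

    Off-target reads (non-specific priming elsewhere in the genome) and
    fragments missing either amplified end are dropped here.
    """
    left, right = primer_intervals
    kept = []
    for aln in alignments:
        hits_left = any(e.overlaps(left) for e in aln.exons)
        hits_right = any(e.overlaps(right) for e in aln.exons)
        if hits_left and hits_right:
            kept.append(aln)
    return kept


def _block_observations(
    alignments: Sequence[SplicedAlignment], blocks: Sequence[ExonBlock]
) -> Tuple[Dict[int, Counter], Dict[int, int]]:
    """Per block: boundary-pair counts, and count of reads touching the block."""
    pair_counts: Dict[int, Counter] = {b.block_id: Counter() for b in blocks}
    reads_touching: Dict[int, Counter] = {b.block_id: set() for b in blocks}
    sorted_blocks = sorted(blocks, key=lambda b: b.interval.start)
    for aln in alignments:
        for exon in aln.exons:
            for b in sorted_blocks:
                if exon.overlaps(b.interval):
                    pair_counts[b.block_id][(exon.start, exon.end)] += 1
                    reads_touching[b.block_id].add(aln.read_id)
                    break
    return pair_counts, {bid: len(s) for bid, s in reads_touching.items()}


def elect_representatives(
    alignments: Sequence[SplicedAlignment],
    blocks: Sequence[ExonBlock],
    config: Optional[PipelineConfig] = None,
) -> ExonCatalog:
    """Elect the most frequent boundary pair of each merged block.

    Ties break toward the smaller start, then smaller end. ``rex`` names are
    assigned in genomic order. When the config supplies primer-model outer
    boundaries, the first block's start and last block's end are clamped to
    them (their true ends lie inside the primers and cannot be voted on).
    """
    if not blocks:
        raise ValueError("no exon blocks")
    pair_counts, _ = _block_observations(alignments, blocks)
    sorted_blocks = sorted(blocks, key=lambda b: b.interval.start)
    reps: List[RepresentativeExon] = []
    for b in sorted_blocks:
        counts = pair_counts[b.block_id]
        if not counts:
            continue
        (start, end), n = min(
            counts.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1])
        )
        reps.append(
            RepresentativeExon(
                rex_id="",
                interval=GenomeInterval(b.interval.chrom, start, end),
                block_id=b.block_id,
                read_count=n,
            )
        )
    if config is not None and config.primer_model_boundaries is not None and reps:
        outer5, outer3 = config.primer_model_boundaries
        first, last = reps[0], reps[-1]
        reps[0] = RepresentativeExon(
            "", GenomeInterval(first.interval.chrom, outer5, first.interval.end),
            block_id=first.block_id, read_count=first.read_count,
        )
        last = reps[-1]
        reps[-1] = RepresentativeExon(
            "", GenomeInterval(last.interval.chrom, last.interval.start, outer3),
            block_id=last.block_id, read_count=last.read_count,
        )
    for i, r in enumerate(reps, start=1):
        r.rex_id = f"rex{i:02d}"
    return ExonCatalog(representatives=reps)


def detect_variants(
    alignments: Sequence[SplicedAlignment],
    catalog: ExonCatalog,
    blocks: Sequence[ExonBlock],
    config: PipelineConfig,
) -> List[ExonVariant]:
    """Admit non-representative boundary pairs above the support threshold.

    The denominator is the number of reads containing *any* exon overlapping
    the block ("exon-containing reads"); admission requires support strictly
    greater than ``variant_frac`` of it. Sharing a boundary with the
    representative is recorded as a QC flag, not required.
    """
    pair_counts, reads_per_block = _block_observations(alignments, blocks)
    by_block = {r.block_id: r for r in catalog.representatives}
    variants: List[ExonVariant] = []
    for block_id, rep in by_block.items():
        denom = reads_per_block.get(block_id, 0)
        if denom == 0:
            continue
        rep_pair = (rep.interval.start, rep.interval.end)
        candidates = [
            (pair, n)
            for pair, n in pair_counts[block_id].items()
            if pair != rep_pair and n / denom > config.variant_frac
        ]
        candidates.sort(key=lambda kv: (-kv[1], kv[0]))
        for i, ((start, end), n) in enumerate(candidates, start=1):
            iv = GenomeInterval(rep.interval.chrom, start, end)
            variants.append(
                ExonVariant(
                    parent=rep.rex_id,
                    interval=iv,
                    pattern=pattern_string(iv, rep.interval),
                    support_frac=n / denom,
                    read_count=n,
                    shares_boundary=(start == rep.interval.start)
                    or (end == rep.interval.end),
                    variant_id=f"{rep.rex_id}.v{i}",
                )
            )
    catalog.variants = variants
    return variants


def assign_exon_frequencies(
    catalog: ExonCatalog,
    matched_chains: Sequence[Tuple[str, ...]],
    config: PipelineConfig,
) -> None:
    """Set each representative's frequency/state from exact-match reads.

    ``matched_chains`` are catalog-element-id tuples, one per exact-match
    read; the denominator is their count. A read containing a variant of a
    representative counts as containing that exon region.
    """
    if not matched_chains:
        return
    parent_of = {v.variant_id: v.parent for v in catalog.variants}
    containing: Counter = Counter()
    for chain in matched_chains:
        regions = {parent_of.get(el, el) for el in chain}
        containing.update(regions)
    denom = len(matched_chains)
    for rep in catalog.representatives:
        rep.frequency = containing.get(rep.rex_id, 0) / denom
        state = classify_exon_state(rep.frequency, config)
        rep.state = state if state is not None else STATE_RARE


def annotate_exons(
    catalog: ExonCatalog, models: Optional[Sequence[GenomeInterval]]
) -> ExonCatalog:
    """Set annotation status against known gene-model exons.

    known = both boundaries match an annotated exon exactly;
    partially_known = >=1 bp overlap without a boundary-exact match;
    novel = no overlap at all. With no models, all exons are 'unannotated'.
    """
    if models is None:
        for rep in catalog.representatives:
            rep.annotation = ANNOT_NONE
        return catalog
    exact = {(m.chrom, m.start, m.end) for m in models}
    for rep in catalog.representatives:
        iv = rep.interval
        if (iv.chrom, iv.start, iv.end) in exact:
            rep.annotation = ANNOT_KNOWN
        elif any(iv.overlaps(m) for m in models):
            rep.annotation = ANNOT_PARTIAL
        else:
            rep.annotation = ANNOT_NOVEL
    return catalog
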