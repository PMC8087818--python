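"""Minimal spliced aligner for a single amplified locus.

Exact k-mer anchors between read and reference are chained colinearly; a
large genomic gap with a small read gap between adjacent anchors opens an
intron. The split point inside each intron gap is refined by scoring every
partition of the unplaced read bases between the flanking exons and then
snapped (within a small window) to the nearest canonical GT...AG splice
motif. Designed for desk-scale references (one locus, <= ~500 kb), not
whole genomes; external aligner output can be imported instead and bypasses
this module entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import edlib

from .model import GenomeInterval, LongRead, PipelineConfig, SplicedAlignment

INTRON_MIN_GAP = 30      # genomic gap opening an intron (bp)
READ_GAP_MAX = 30        # read gap must stay below this for an intron
MOTIF_WINDOW = 6         # max shift to snap a junction onto GT...AG
ANCHOR_TRIM = 8          # bp of flanking anchor softened during refinement
MIN_ANCHOR_COVERAGE = 0.25  # chained anchor coverage of read length
_LOOKBACK = 64           # chaining DP predecessor window

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AnchorChain:
    """Colinear exact-match anchors (read_pos, genome_pos, k)."""

    anchors: List[Tuple[int, int, int]]
    score: int


class ReferenceIndex:
    """Exact k-mer index of the locus sequence."""

    def __init__(self, reference: str, k: int, max_occ: int = 50):
        if len(reference) < k:
            raise ValueError(f"reference shorter than k={k}")
        self.reference = reference.upper()
        self.k = k
        index: Dict[str, List[int]] = {}
        for i in range(len(self.reference) - k + 1):
            index.setdefault(self.reference[i : i + k], []).append(i)
        # drop hyper-repetitive seeds; they only bloat the chaining DP
        self.index = {km: pos for km, pos in index.items() if len(pos) <= max_occ}

    def anchors(self, seq: str, stride: int = 1) -> List[Tuple[int, int, int]]:
        k = self.k
        out = []
        for i in range(0, len(seq) - k + 1, stride):
            for g in self.index.get(seq[i : i + k], ()):
                out.append((i, g, k))
        return out


def chain_anchors(anchors: List[Tuple[int, int, int]]) -> AnchorChain:
    """Highest-coverage colinear chain (weighted LIS, bounded lookback)."""
    if not anchors:
        return AnchorChain([], 0)
    anchors = sorted(anchors)
    n = len(anchors)
    score = [a[2] for a in anchors]
    prev = [-1] * n
    for j in range(n):
        rj, gj, kj = anchors[j]
        lo = max(0, j - _LOOKBACK)
        for i in range(lo, j):
            ri, gi, ki = anchors[i]
            if ri < rj and gi < gj and (gj - gi) >= (rj - ri) - READ_GAP_MAX:
                # overlap-adjusted gain of appending anchor j after i
                gain = min(kj, rj - ri, gj - gi)
                if score[i] + gain > score[j]:
                    score[j] = score[i] + gain
                    prev[j] = i
    best = max(range(n), key=lambda j: score[j])
    chain = []
    j = best
    while j != -1:
        chain.append(anchors[j])
        j = prev[j]
    chain.reverse()
    return AnchorChain(chain, score[best])


def _matches(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def _refine_intron(
    read: str, ref: str, r_lo: int, r_hi: int, g_lo: int, g_hi: int
) -> Tuple[int, int]:
    """Place the splice junction inside an anchor gap.

    Read bases read[r_lo:r_hi] must be split between the end of the left
    exon (genome from g_lo) and the start of the right exon (genome up to
    g_hi). Returns (donor, acceptor): left exon ends at donor, right exon
    starts at acceptor. Prefers, then snaps to, a GT...AG intron motif
    within MOTIF_WINDOW bp.
    """
    gap = read[r_lo:r_hi]
    g = len(gap)
    best = None
    for i in range(g + 1):
        donor = g_lo + i
        acceptor = g_hi - (g - i)
        if acceptor - donor < 2:
            continue
        score = _matches(gap[:i], ref[g_lo:donor]) + _matches(
            gap[i:], ref[acceptor:g_hi]
        )
        # canonical splice motif acts as a scoring bonus, so exact splits
        # with ambiguous flanking bases still land on GT...AG
        if ref[donor : donor + 2] == "GT":
            score += 2
        if ref[acceptor - 2 : acceptor] == "AG":
            score += 2
        if best is None or score > best[0]:
            best = (score, donor, acceptor)
    if best is None:
        return g_lo + g, g_hi  # degenerate: no room for an intron
    _, donor, acceptor = best
    # residual shift (indels near the junction): move both ends together
    # onto a motif, preserving the summed exon length
    if not (ref[donor : donor + 2] == "GT" and ref[acceptor - 2 : acceptor] == "AG"):
        for s in sorted(range(-MOTIF_WINDOW, MOTIF_WINDOW + 1), key=lambda x: (abs(x), x)):
            d, a = donor + s, acceptor + s
            if d < 0 or a > len(ref) or a - d < 2:
                continue
            if ref[d : d + 2] == "GT" and ref[a - 2 : a] == "AG":
                return d, a
    return donor, acceptor


def _build_exons(
    read: str, ref: str, chain: List[Tuple[int, int, int]], chrom: str
) -> List[GenomeInterval]:
    """Turn an anchor chain into an exon chain with refined junctions."""
    exons: List[Tuple[int, int]] = []
    exon_start = chain[0][1]
    prev_r_end = chain[0][0] + chain[0][2]
    prev_g_end = chain[0][1] + chain[0][2]
    for r, g, k in chain[1:]:
        read_gap = max(0, r - prev_r_end)
        genome_gap = g - prev_g_end
        is_intron = genome_gap >= INTRON_MIN_GAP and (
            read_gap < READ_GAP_MAX
            # anchors can thin out around a junction in noisy sequence,
            # inflating the read gap; a genomic gap exceeding the read gap
            # by an intron's worth still indicates an intron
            or genome_gap - read_gap >= INTRON_MIN_GAP
        )
        if is_intron:
            # soften the flanking anchor edges: a chance k-mer match can
            # overlap the true junction by a few bases, so let the split
            # search re-place them
            trim = min(ANCHOR_TRIM, prev_r_end - 1, max(0, genome_gap // 2 - 1))
            r_hi = max(r, prev_r_end)
            donor, acceptor = _refine_intron(
                read, ref,
                prev_r_end - trim, min(r_hi + trim, len(read)),
                prev_g_end - trim, min(g + trim, len(ref)),
            )
            exons.append((exon_start, donor))
            exon_start = acceptor
        prev_r_end = max(prev_r_end, r + k)
        prev_g_end = max(prev_g_end, g + k)
    # extend the terminal exon ends by the unanchored read tails (clipped
    # to the reference), so error-free reads recover full exon boundaries
    head = chain[0][0]
    tail = len(read) - prev_r_end
    first_start = max(0, chain[0][1] - head)
    last_end = min(len(ref), prev_g_end + tail)
    if exons:
        exons[0] = (first_start, exons[0][1])
    exons.append((exon_start if exons else first_start, last_end))
    out = []
    for s, e in exons:
        if e > s:
            out.append(GenomeInterval(chrom, s, e))
    return out


def _align_oriented(
    seq: str, index: ReferenceIndex, chrom: str
) -> Tuple[Optional[List[GenomeInterval]], int]:
    anchors = index.anchors(seq)
    chain = chain_anchors(anchors)
    if not chain.anchors or chain.score < MIN_ANCHOR_COVERAGE * len(seq):
        return None, chain.score
    return _build_exons(seq, index.reference, chain.anchors, chrom), chain.score


def alignment_identity(seq: str, reference: str, exons: List[GenomeInterval]) -> float:
    """Edit-distance identity of ``seq`` against the spliced exon sequence."""
    spliced = "".join(reference[e.start : e.end] for e in exons)
    if not spliced:
        return 0.0
    d = edlib.align(seq, spliced, task="distance")["editDistance"]
    return max(0.0, 1.0 - d / max(len(seq), len(spliced)))


def align_spliced(
    read: LongRead,
    reference: str,
    config: PipelineConfig,
    index: Optional[ReferenceIndex] = None,
    chrom: str = "locus",
) -> Optional[SplicedAlignment]:
    """Spliced-align one read against the locus; None if it doesn't anchor.

    Both orientations are tried; the one with the higher chain score wins.
    Returns None when chained anchor coverage is below 25% of read length
    (off-target or junk reads).
    """
    if index is None:
        index = ReferenceIndex(reference, config.anchor_k)
    ref = index.reference
    fwd = read.sequence.upper()
    exons_f, score_f = _align_oriented(fwd, index, chrom)
    exons_r, score_r = _align_oriented(revcomp(fwd), index, chrom)
    if exons_f is None and exons_r is None:
        return None
    if exons_r is None or (exons_f is not None and score_f >= score_r):
        exons, strand, seq = exons_f, "+", fwd
    else:
        exons, strand, seq = exons_r, "-", revcomp(fwd)
    return SplicedAlignment(
        read_id=read.read_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        identity=alignment_identity(seq, ref, exons),
    )
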