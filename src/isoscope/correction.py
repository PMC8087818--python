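"""Reference-guided self-correction of error-prone long reads.

Reads are grouped by a loose exon-structure signature (which merged genomic
blocks their alignment touches) and corrected *within* each group by a star
consensus: the medoid member serves as template, every member is aligned to
it by edit distance (edlib), and a per-column majority vote over
match/substitution/insertion/deletion events yields one consensus that is
assigned to every member. Two rounds are run: round-1 consensi are
re-aligned to obtain boundary-accurate groups, and the ORIGINAL raw reads
are then re-corrected inside those round-2 groups so that any mis-grouping
in round 1 does not bias the final sequences.

Correction is deliberately partial: reads that fail to align, or end up in
single-member groups, pass through uncorrected and are flagged, mirroring
the attrition seen with real amplicon data.
"""

from __future__ import annotations

import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import edlib

from .aligner import ReferenceIndex, align_spliced
from .model import (
    ExonBlock,
    GenomeInterval,
    LongRead,
    PipelineConfig,
    ReadGroup,
    SplicedAlignment,
)

MEDOID_SAMPLE = 30  # pairwise-identity sample size for medoid election


def merge_exon_blocks(alignments: Sequence[SplicedAlignment]) -> List[ExonBlock]:
    """Merge all aligned exons into maximal connected genomic blocks."""
    if not alignments:
        raise ValueError("no alignments to merge")
    intervals = sorted(
        (e.chrom, e.start, e.end) for a in alignments for e in a.exons
    )
    blocks: List[ExonBlock] = []
    cur_chrom, cur_start, cur_end = intervals[0]
    bid = 0
    for chrom, start, end in intervals[1:]:
        if chrom == cur_chrom and start <= cur_end:
            cur_end = max(cur_end, end)
        else:
            blocks.append(ExonBlock(bid, GenomeInterval(cur_chrom, cur_start, cur_end)))
            bid += 1
            cur_chrom, cur_start, cur_end = chrom, start, end
    blocks.append(ExonBlock(bid, GenomeInterval(cur_chrom, cur_start, cur_end)))
    return blocks


def read_signature(
    alignment: SplicedAlignment, blocks: Sequence[ExonBlock]
) -> Tuple[int, ...]:
    """Ordered ids of the blocks this alignment's exons overlap (>=1 bp)."""
    ids = []
    for b in sorted(blocks, key=lambda b: b.interval.start):
        if any(e.overlaps(b.interval) for e in alignment.exons):
            ids.append(b.block_id)
    if not ids:
        raise ValueError(f"alignment {alignment.read_id} overlaps no block")
    return tuple(ids)


def group_by_signature(
    alignments: Sequence[SplicedAlignment],
    blocks: Sequence[ExonBlock],
    round: int = 1,
) -> List[ReadGroup]:
    by_sig: Dict[Tuple[int, ...], List[str]] = defaultdict(list)
    for aln in alignments:
        by_sig[read_signature(aln, blocks)].append(aln.read_id)
    return [
        ReadGroup(signature=sig, members=sorted(members), round=round)
        for sig, members in sorted(by_sig.items())
    ]


def _identity(a: str, b: str) -> float:
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def choose_medoid(reads: Sequence[LongRead], seed: int = 0) -> LongRead:
    """Member with highest mean pairwise identity; ties -> longest, then
    lexicographically smallest read_id. Large groups are subsampled."""
    if len(reads) == 1:
        return reads[0]
    pool = list(reads)
    if len(pool) > MEDOID_SAMPLE:
        pool = random.Random(seed).sample(pool, MEDOID_SAMPLE)
    def mean_identity(cand: LongRead) -> float:
        return sum(
            _identity(cand.sequence, other.sequence)
            for other in pool
            if other is not cand
        ) / (len(pool) - 1)

    return min(pool, key=lambda c: (-mean_identity(c), -len(c.sequence), c.read_id))


def _consensus_from_template(template: str, members: Sequence[str]) -> str:
    """Per-template-column majority over match/sub/ins/del events."""
    L = len(template)
    col_votes: List[Counter] = [Counter() for _ in range(L)]
    ins_votes: List[Counter] = [Counter() for _ in range(L + 1)]
    n = len(members)
    for seq in members:
        res = edlib.align(seq, template, task="path")
        qpos = tpos = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            ln = int(num)
            num = ""
            if ch in "=X":
                for i in range(ln):
                    col_votes[tpos + i][seq[qpos + i]] += 1
                qpos += ln
                tpos += ln
            elif ch == "I":  # extra bases in the member
                ins_votes[tpos][seq[qpos : qpos + ln]] += 1
                qpos += ln
            elif ch == "D":  # member lacks these template bases
                for i in range(ln):
                    col_votes[tpos + i]["-"] += 1
                tpos += ln
    out: List[str] = []
    for t in range(L + 1):
        if ins_votes[t]:
            ins, cnt = max(sorted(ins_votes[t].items()), key=lambda kv: kv[1])
            if cnt > n / 2:
                out.append(ins)
        if t < L:
            votes = col_votes[t]
            if not votes:
                out.append(template[t])
                continue
            top = max(votes.values())
            # deterministic tie-break: prefer the template's own base
            winners = sorted(tok for tok, c in votes.items() if c == top)
            tok = template[t] if template[t] in winners else winners[0]
            if tok != "-":
                out.append(tok)
    return "".join(out)


def correct_group(reads: Sequence[LongRead], seed: int = 0) -> List[LongRead]:
    """Correct one read group; every member receives the group consensus.

    Single-member groups pass through uncorrected (there is nothing to vote
    with); callers flag them and exclude them from corrected counts.
    """
    if not reads:
        return []
    if len(reads) == 1:
        return list(reads)
    template = choose_medoid(reads, seed=seed)
    consensus = _consensus_from_template(
        template.sequence, [r.sequence for r in reads]
    )
    return [
        LongRead(r.read_id, r.sample_id, consensus, qualities=None) for r in reads
    ]


@dataclass
class CorrectionResult:
    """Round-2 corrected reads with the group structure of both rounds."""

    corrected: List[LongRead] = field(default_factory=list)
    uncorrected: List[LongRead] = field(default_factory=list)  # singletons etc.
    groups_round1: List[ReadGroup] = field(default_factory=list)
    groups_round2: List[ReadGroup] = field(default_factory=list)
    n_input: int = 0
    n_aligned: int = 0

    @property
    def n_corrected(self) -> int:
        return len(self.corrected)


AlignFn = Callable[[LongRead], Optional[SplicedAlignment]]


def run_grouped_correction(
    reads: Sequence[LongRead],
    reference: str,
    config: PipelineConfig,
    alignments: Optional[Dict[str, SplicedAlignment]] = None,
    chrom: str = "locus",
) -> CorrectionResult:
    """Two-round grouped self-correction of ``reads`` against one locus.

    Round-1 alignments come from ``alignments`` (imported external output,
    keyed by read_id) when given, otherwise from the built-in aligner.
    Round 2 always re-aligns the round-1 consensi with the built-in aligner;
    raw reads whose consensus fails that alignment are dropped.
    """
    result = CorrectionResult(n_input=len(reads))
    index = ReferenceIndex(reference, config.anchor_k)

    def builtin_align(read: LongRead) -> Optional[SplicedAlignment]:
        return align_spliced(read, reference, config, index=index, chrom=chrom)

    # --- round 1: loose groups on raw alignments
    by_id = {r.read_id: r for r in reads}
    round1_alns: List[SplicedAlignment] = []
    for r in reads:
        aln = alignments.get(r.read_id) if alignments is not None else builtin_align(r)
        if aln is not None and aln.is_primary:
            round1_alns.append(aln)
    if not round1_alns:
        result.uncorrected = list(reads)
        return result
    result.n_aligned = len(round1_alns)
    blocks1 = merge_exon_blocks(round1_alns)
    groups1 = group_by_signature(round1_alns, blocks1, round=1)
    result.groups_round1 = groups1

    # singleton groups cannot vote; their members pass through uncorrected
    # and are kept out of round 2, where a raw read's sloppy alignment could
    # coarsen the refined blocks and merge distinct isoform groups
    consensus1: Dict[int, str] = {}  # group index -> round-1 consensus
    for gi, g in enumerate(groups1):
        members = [by_id[rid] for rid in g.members]
        if len(members) == 1:
            result.uncorrected.extend(members)
            continue
        consensus1[gi] = correct_group(members, seed=config.seed + gi)[0].sequence

    # --- round 2: re-align the consensi, regroup, re-correct raw reads
    cons_alns: List[SplicedAlignment] = []
    cons_group: Dict[str, int] = {}
    for gi, seq in consensus1.items():
        pseudo = LongRead(f"group{gi}", "consensus", seq)
        aln = builtin_align(pseudo)
        if aln is None:
            continue  # raw members of this group drop out of correction
        cons_alns.append(aln)
        cons_group[pseudo.read_id] = gi
    if not cons_alns:
        result.uncorrected = list(reads)
        return result
    blocks2 = merge_exon_blocks(cons_alns)
    merged: Dict[Tuple[int, ...], List[int]] = defaultdict(list)
    for aln in cons_alns:
        merged[read_signature(aln, blocks2)].append(cons_group[aln.read_id])

    for gi2, (sig, round1_ids) in enumerate(sorted(merged.items())):
        member_ids = sorted(
            rid for gi in round1_ids for rid in groups1[gi].members
        )
        result.groups_round2.append(ReadGroup(signature=sig, members=member_ids, round=2))
        raw_members = [by_id[rid] for rid in member_ids]
        if len(raw_members) == 1:
            result.uncorrected.extend(raw_members)
            continue
        result.corrected.extend(correct_group(raw_members, seed=config.seed + 1000 + gi2))
    return result
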