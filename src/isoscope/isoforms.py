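"""Exact-match isoform enumeration, counting, and diversity summaries.

A corrected read is assigned an isoform only when its *entire* exon chain
equals, boundary-exactly, a combination of catalog representatives and
admitted variants — exactness is what gives the catalog its base-pair-level
meaning. Isoforms are ranked by pooled read total; supporting-read tiers
(>=20 high-confidence, >=3 minimum-evidence) grade how much evidence backs
each isoform.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from scipy.stats import spearmanr

from .exons import ExonCatalog
from .model import PipelineConfig, SplicedAlignment

TIER_HIGH = "high_confidence"
TIER_MINIMUM = "minimum_evidence"
TIER_SINGLETON = "singleton_zone"

IsoformKey = Tuple[str, ...]


@dataclass
class IsoformRecord:
    """One distinct isoform with per-sample read counts."""

    key: IsoformKey
    counts: Dict[str, int] = field(default_factory=dict)
    rank: int = 0
    tier: str = TIER_SINGLETON

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def name(self) -> str:
        return ",".join(self.key)


def match_isoform(
    alignment: SplicedAlignment,
    catalog: ExonCatalog,
    tolerance: int = 0,
) -> Optional[IsoformKey]:
    """Match an exon chain against the catalog; None unless every exon hits.

    Each exon must equal a representative or variant of successive blocks
    (within ``tolerance`` bp per boundary, default 0 = exact). Skipped
    blocks are fine — exon skipping is the phenomenon under study — but two
    exons may not hit the same block and block order must be ascending.
    """
    block_of: Dict[str, int] = {}
    elements: List[Tuple[str, int, int, int]] = []  # id, start, end, block
    for i, rep in enumerate(catalog.representatives):
        block = rep.block_id if rep.block_id >= 0 else i
        block_of[rep.rex_id] = block
        elements.append((rep.rex_id, rep.interval.start, rep.interval.end, block))
    for v in catalog.variants:
        block = block_of[v.parent]
        elements.append((v.variant_id, v.interval.start, v.interval.end, block))

    key: List[str] = []
    last_block = -1
    for exon in alignment.exons:
        hit = None
        for el_id, start, end, block in elements:
            if abs(exon.start - start) <= tolerance and abs(exon.end - end) <= tolerance:
                hit = (el_id, block)
                break
        if hit is None or hit[1] <= last_block:
            return None
        key.append(hit[0])
        last_block = hit[1]
    return tuple(key)


def count_isoforms(
    keys_per_sample: Dict[str, Sequence[IsoformKey]],
    config: Optional[PipelineConfig] = None,
) -> List[IsoformRecord]:
    """Aggregate matched keys into ranked, tiered isoform records.

    Technical replicates are pooled for ranking (rank = order by total read
    count, descending; ties lexicographic on the key) while per-sample
    counts are retained for replicate-level analyses.
    """
    config = config or PipelineConfig()
    counts: Dict[IsoformKey, Counter] = defaultdict(Counter)
    for sample, keys in keys_per_sample.items():
        for key in keys:
            counts[key][sample] += 1
    records = [IsoformRecord(key=k, counts=dict(c)) for k, c in counts.items()]
    records.sort(key=lambda r: (-r.total, r.key))
    for i, rec in enumerate(records, start=1):
        rec.rank = i
        if rec.total >= config.high_conf_reads:
            rec.tier = TIER_HIGH
        elif rec.total >= config.min_evidence_reads:
            rec.tier = TIER_MINIMUM
        else:
            rec.tier = TIER_SINGLETON
    return records


def junction_frequencies(
    keys: Sequence[IsoformKey],
) -> Dict[Tuple[str, str], int]:
    """Counts of adjacent catalog-element pairs across all matched reads."""
    out: Counter = Counter()
    for key in keys:
        for a, b in zip(key, key[1:]):
            out[(a, b)] += 1
    return dict(out)


def cumulative_coverage(
    records: Sequence[IsoformRecord],
) -> List[Tuple[int, float]]:
    """Running read fraction by isoform rank; ends at 1.0."""
    total = sum(r.total for r in records)
    out: List[Tuple[int, float]] = []
    running = 0
    for rec in sorted(records, key=lambda r: r.rank):
        running += rec.total
        out.append((rec.rank, running / total))
    return out


def variable_combination_count(n_variable: int) -> int:
    """Isoform count if each variable exon were included independently."""
    if n_variable < 0:
        raise ValueError("negative exon count")
    return 2 ** n_variable


def replicate_correlation(
    records: Sequence[IsoformRecord], sample_a: str, sample_b: str
) -> Optional[float]:
    """Spearman rank correlation of isoform counts between two replicates.

    Restricted to isoforms observed in either sample, zero-filling the
    other; None (not computable) with fewer than 3 such isoforms.
    """
    pairs = [
        (r.counts.get(sample_a, 0), r.counts.get(sample_b, 0))
        for r in records
        if sample_a in r.counts or sample_b in r.counts
    ]
    if len(pairs) < 3:
        return None
    a, b = zip(*pairs)
    rho = spearmanr(a, b).statistic
    return float(rho)
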