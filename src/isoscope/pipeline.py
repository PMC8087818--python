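"""End-to-end orchestration: correct -> call exons -> call isoforms -> report.

The RunManifest records the read funnel (input -> aligned -> corrected ->
primer-filtered -> exact-matched) the way amplicon studies report attrition;
the counts are monotone non-increasing by construction and checked.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .aligner import ReferenceIndex, align_spliced
from .correction import CorrectionResult, merge_exon_blocks, run_grouped_correction
from .exons import (
    ExonCatalog,
    annotate_exons,
    assign_exon_frequencies,
    detect_variants,
    elect_representatives,
    primer_filter,
)
from .isoforms import (
    IsoformRecord,
    count_isoforms,
    cumulative_coverage,
    junction_frequencies,
    match_isoform,
)
from .model import GenomeInterval, LongRead, PipelineConfig, SplicedAlignment


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    input_digests: Dict[str, str] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    STAGES = ("input", "aligned", "corrected", "primer_filtered", "exact_matched")

    def record(self, stage: str, n: int) -> None:
        if stage not in self.STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        prev = [s for s in self.STAGES if s in self.counts]
        if prev and n > self.counts[prev[-1]]:
            raise ValueError(
                f"funnel violation: {stage}={n} exceeds {prev[-1]}={self.counts[prev[-1]]}"
            )
        self.counts[stage] = n

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


@dataclass
class PipelineResult:
    manifest: RunManifest
    catalog: Optional[ExonCatalog]
    records: List[IsoformRecord]
    junctions: Dict[Tuple[str, str], int]
    coverage: List[Tuple[int, float]]
    correction: Optional[CorrectionResult] = None


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    d = asdict(config)
    if d.get("primer_intervals"):
        d["primer_intervals"] = [str(GenomeInterval(**iv)) if isinstance(iv, dict) else str(iv)
                                 for iv in config.primer_intervals]
    return d


def align_corrected(
    reads: Sequence[LongRead],
    reference: str,
    config: PipelineConfig,
    chrom: str = "locus",
) -> List[SplicedAlignment]:
    """Align corrected reads, deduplicating identical sequences.

    Group consensus means many corrected reads share one sequence; each
    distinct sequence is aligned once and the alignment cloned per read.
    """
    index = ReferenceIndex(reference, config.anchor_k)
    cache: Dict[str, Optional[SplicedAlignment]] = {}
    out: List[SplicedAlignment] = []
    for r in reads:
        if r.sequence not in cache:
            cache[r.sequence] = align_spliced(r, reference, config, index=index, chrom=chrom)
        aln = cache[r.sequence]
        if aln is not None:
            out.append(
                SplicedAlignment(
                    read_id=r.read_id,
                    chrom=aln.chrom,
                    strand=aln.strand,
                    exons=aln.exons,
                    identity=aln.identity,
                )
            )
    return out


def call_exons(
    alignments: Sequence[SplicedAlignment],
    config: PipelineConfig,
    annotation: Optional[Sequence[GenomeInterval]] = None,
) -> ExonCatalog:
    """Merged blocks -> representatives -> admitted variants -> annotation."""
    blocks = merge_exon_blocks(alignments)
    catalog = elect_representatives(alignments, blocks, config)
    detect_variants(alignments, catalog, blocks, config)
    annotate_exons(catalog, annotation)
    return catalog


def run_pipeline(
    reads: Sequence[LongRead],
    reference: str,
    config: PipelineConfig,
    alignments: Optional[Dict[str, SplicedAlignment]] = None,
    annotation: Optional[Sequence[GenomeInterval]] = None,
    outdir=None,
    input_paths: Optional[Dict[str, str]] = None,
    chrom: str = "locus",
) -> PipelineResult:
    """Run the full pipeline on one locus and optionally write all reports."""
    manifest = RunManifest(
        config=_config_snapshot(config),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for name, p in (input_paths or {}).items():
        manifest.input_digests[name] = _digest(p)
    manifest.record("input", len(reads))
    sample_of = {r.read_id: r.sample_id for r in reads}

    try:
        correction = run_grouped_correction(
            reads, reference, config, alignments=alignments, chrom=chrom
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("correct", exc)
    manifest.record("aligned", correction.n_aligned)
    manifest.record("corrected", correction.n_corrected)

    try:
        corrected_alns = align_corrected(correction.corrected, reference, config, chrom)
        primer = config.primer_intervals
        if primer is None and corrected_alns:
            blocks = merge_exon_blocks(corrected_alns)
            primer = (blocks[0].interval, blocks[-1].interval)
        filtered = primer_filter(corrected_alns, primer) if primer else []
    except Exception as exc:
        raise StageError("primer_filter", exc)
    manifest.record("primer_filtered", len(filtered))

    if not filtered:
        manifest.record("exact_matched", 0)
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        return PipelineResult(manifest, None, [], {}, [], correction)

    try:
        catalog = call_exons(filtered, config, annotation)
    except Exception as exc:
        raise StageError("call_exons", exc)

    try:
        keys_per_sample: Dict[str, List] = {}
        matched_chains = []
        for aln in filtered:
            key = match_isoform(aln, catalog, tolerance=config.match_tolerance)
            if key is None:
                continue
            matched_chains.append(key)
            keys_per_sample.setdefault(sample_of.get(aln.read_id, "sample"), []).append(key)
        assign_exon_frequencies(catalog, matched_chains, config)
        records = count_isoforms(keys_per_sample, config)
        junctions = junction_frequencies(matched_chains)
        coverage = cumulative_coverage(records) if records else []
    except Exception as exc:
        raise StageError("call_isoforms", exc)
    manifest.record("exact_matched", len(matched_chains))
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")

    result = PipelineResult(manifest, catalog, records, junctions, coverage, correction)
    if outdir is not None:
        write_reports(result, outdir)
    return result


# --- report writing ---------------------------------------------------------


def exon_table(catalog: ExonCatalog) -> pd.DataFrame:
    rows = [
        {
            "name": r.rex_id,
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "length": r.length,
            "symmetric": r.symmetric,
            "frequency": round(r.frequency, 6),
            "state": r.state,
            "annotation": r.annotation,
        }
        for r in catalog.representatives
    ]
    return pd.DataFrame(rows)


def variant_table(catalog: ExonCatalog) -> pd.DataFrame:
    rows = [
        {
            "variant_id": v.variant_id,
            "parent": v.parent,
            "start": v.interval.start,
            "end": v.interval.end,
            "pattern": v.pattern,
            "length_change": v.length_change,
            "change_symmetric": v.change_symmetric,
            "support_frac": round(v.support_frac, 6),
            "shares_boundary": v.shares_boundary,
        }
        for v in catalog.variants
    ]
    return pd.DataFrame(rows)


def isoform_table(records: Sequence[IsoformRecord]) -> pd.DataFrame:
    samples = sorted({s for r in records for s in r.counts})
    rows = []
    for r in records:
        row = {"isoform": r.name, "rank": r.rank, "total": r.total, "tier": r.tier}
        for s in samples:
            row[s] = r.counts.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def junction_table(junctions: Dict[Tuple[str, str], int]) -> pd.DataFrame:
    rows = [
        {"from": a, "to": b, "count": n}
        for (a, b), n in sorted(junctions.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)


def write_reports(result: PipelineResult, outdir) -> Dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    if result.catalog is not None:
        paths["exons"] = outdir / "exons.tsv"
        exon_table(result.catalog).to_csv(paths["exons"], sep="\t", index=False)
        paths["variants"] = outdir / "variants.tsv"
        variant_table(result.catalog).to_csv(paths["variants"], sep="\t", index=False)
    paths["isoforms"] = outdir / "isoforms.tsv"
    isoform_table(result.records).to_csv(paths["isoforms"], sep="\t", index=False)
    paths["junctions"] = outdir / "junctions.tsv"
    junction_table(result.junctions).to_csv(paths["junctions"], sep="\t", index=False)
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        fh.write(result.manifest.to_json())
    return paths
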