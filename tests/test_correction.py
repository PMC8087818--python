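"""Exon-block merging, grouping, and two-round consensus correction."""

import edlib
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from isoscope.correction import (
    correct_group,
    group_by_signature,
    merge_exon_blocks,
    read_signature,
    run_grouped_correction,
)
from isoscope.model import (
    GenomeInterval,
    LongRead,
    PipelineConfig,
    SplicedAlignment,
)
from isoscope.simulate import _apply_errors, make_locus


def _aln(read_id, pairs, chrom="c"):
    return SplicedAlignment(
        read_id, chrom, "+", [GenomeInterval(chrom, s, e) for s, e in pairs]
    )


def union_blocks_oracle(pairs):
    """Per-base union oracle: maximal runs of covered positions."""
    covered = set()
    for s, e in pairs:
        covered.update(range(s, e))
    runs, start, prev = [], None, None
    for p in sorted(covered):
        if start is None:
            start = prev = p
        elif p == prev + 1:
            prev = p
        else:
            runs.append((start, prev + 1))
            start = prev = p
    if start is not None:
        runs.append((start, prev + 1))
    return runs


class TestMergeExonBlocks:
    def test_overlapping_exons_merge(self):
        alns = [_aln("a", [(100, 200), (300, 400)]), _aln("b", [(150, 250)])]
        blocks = merge_exon_blocks(alns)
        assert [(b.interval.start, b.interval.end) for b in blocks] == [
            (100, 250),
            (300, 400),
        ]

    def test_single_exon_is_its_own_block(self):
        (b,) = merge_exon_blocks([_aln("a", [(10, 20)])])
        assert (b.interval.start, b.interval.end) == (10, 20)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_exon_blocks([])

    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 60)),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_per_base_union_oracle(self, raw):
        pairs = [(s, s + ln) for s, ln in raw]
        alns = [_aln(f"r{i}", [p]) for i, p in enumerate(pairs)]
        got = [(b.interval.start, b.interval.end) for b in merge_exon_blocks(alns)]
        assert got == union_blocks_oracle(pairs)


class TestSignatures:
    BLOCKS = [_aln("x", [(0, 100), (200, 300), (400, 500)])]

    def test_signature_lists_touched_blocks_in_order(self):
        blocks = merge_exon_blocks(self.BLOCKS)
        aln = _aln("r", [(10, 90), (410, 490)])
        assert read_signature(aln, blocks) == (0, 2)

    def test_boundary_jitter_preserves_signature(self):
        blocks = merge_exon_blocks(self.BLOCKS)
        a = _aln("a", [(10, 90), (210, 290)])
        b = _aln("b", [(0, 100), (200, 300)])  # +-10 bp jitter
        assert read_signature(a, blocks) == read_signature(b, blocks)

    def test_skipping_a_block_changes_signature(self):
        blocks = merge_exon_blocks(self.BLOCKS)
        with_mid = _aln("a", [(10, 90), (210, 290), (410, 490)])
        without = _aln("b", [(10, 90), (410, 490)])
        assert read_signature(with_mid, blocks) != read_signature(without, blocks)

    def test_grouping_is_a_partition(self):
        blocks = merge_exon_blocks(self.BLOCKS)
        alns = [
            _aln("a", [(10, 90)]),
            _aln("b", [(20, 80)]),
            _aln("c", [(210, 290)]),
        ]
        groups = group_by_signature(alns, blocks)
        members = [rid for g in groups for rid in g.members]
        assert sorted(members) == ["a", "b", "c"]
        assert len(members) == len(set(members))


class TestCorrectGroup:
    def test_majority_vote_fixes_single_substitution(self):
        seq = "ACGTACGTACGTACGT"
        mutated = seq[:5] + "A" + seq[6:]
        reads = [
            LongRead("a", "s", seq),
            LongRead("b", "s", seq),
            LongRead("c", "s", mutated),
        ]
        out = correct_group(reads)
        assert all(r.sequence == seq for r in out)
        assert [r.read_id for r in out] == ["a", "b", "c"]

    def test_singleton_passes_through_unchanged(self):
        r = LongRead("a", "s", "ACGTACGT")
        assert correct_group([r])[0].sequence == "ACGTACGT"

    def test_idempotent_on_identical_groups(self):
        reads = [LongRead(f"r{i}", "s", "ACGTACGTAA") for i in range(4)]
        out = correct_group(reads)
        assert {r.sequence for r in out} == {"ACGTACGTAA"}

    def test_consensus_of_noisy_reads_recovers_truth(self):
        locus = make_locus(3, seed=8)
        truth = "".join(
            locus.reference[e.start : e.end] for e in locus.exons
        )
        rng = np.random.default_rng(8)
        reads = [
            LongRead(f"r{i}", "s", _apply_errors(truth, (0.04, 0.03, 0.03), rng))
            for i in range(20)
        ]
        consensus = correct_group(reads)[0].sequence
        d = edlib.align(consensus, truth, task="distance")["editDistance"]
        assert 1 - d / len(truth) > 0.99


class TestTwoRoundCorrection:
    def _mixture(self, seed=3, n=300):
        locus = make_locus(6, seed=seed)
        classes = ["stable", "variable", "stable", "rare", "variable", "stable"]
        from isoscope.simulate import make_isoforms, simulate_reads

        isoforms = make_isoforms(locus, classes, 6, seed=seed + 1)
        truth = simulate_reads(
            locus, isoforms, n, seed=seed + 2,
            error_rates=(0.03, 0.02, 0.02), offtarget_frac=0.05, classes=classes,
        )
        return locus, truth

    def test_noise_free_input_is_a_fixed_point(self):
        locus, truth = self._mixture()
        from isoscope.simulate import simulate_reads

        clean = simulate_reads(
            locus, truth.isoforms, 60, seed=1, error_rates=(0, 0, 0),
            offtarget_frac=0.0,
        )
        cfg = PipelineConfig(seed=1)
        res = run_grouped_correction(
            clean.reads, locus.reference, cfg, alignments=clean.truth_alignments()
        )
        raw = {r.read_id: r.sequence for r in clean.reads}
        for r in res.corrected:
            assert r.sequence == raw[r.read_id]

    def test_correction_improves_identity_to_truth(self):
        locus, truth = self._mixture(seed=5)
        cfg = PipelineConfig(seed=5)
        res = run_grouped_correction(
            truth.reads, locus.reference, cfg, alignments=truth.truth_alignments()
        )
        spliced = {
            j: "".join(
                locus.reference[locus.exons[i].start : locus.exons[i].end]
                for i in incl
            )
            for j, (incl, _) in enumerate(truth.isoforms)
        }

        def mean_identity(reads):
            vals = []
            for r in reads:
                iso = truth.per_read[r.read_id].isoform
                if iso is None:
                    continue
                t = spliced[iso]
                d = edlib.align(r.sequence, t, task="distance")["editDistance"]
                vals.append(1 - d / max(len(t), len(r.sequence)))
            return np.mean(vals)

        corrected_ids = {r.read_id for r in res.corrected}
        raw_subset = [r for r in truth.reads if r.read_id in corrected_ids]
        assert mean_identity(res.corrected) > mean_identity(raw_subset)

    def test_round_two_regroups_oversegmented_isoform(self):
        """A small exon observed at two disjoint jittered positions splits
        one isoform over two round-1 groups; re-aligning the round-1
        consensi merges them, so round-2 groups agree better with the true
        isoform labels (adjusted Rand index) than round-1 groups."""
        locus = make_locus(4, seed=21)
        ref = locus.reference
        ex = locus.exons
        iso_a = (0, 1, 2, 3)
        iso_b = (0, 2, 3)
        rng = np.random.default_rng(21)
        reads, alignments, labels = [], {}, {}
        spliced = {
            iso: "".join(ref[ex[i].start : ex[i].end] for i in iso)
            for iso in (iso_a, iso_b)
        }
        for i in range(60):
            iso = iso_a if i % 2 == 0 else iso_b
            rid = f"r{i:03d}"
            seq = _apply_errors(spliced[iso], (0.03, 0.02, 0.02), rng)
            reads.append(LongRead(rid, "s", seq))
            labels[rid] = iso
            exons = [ex[j] for j in iso]
            if iso is iso_b and i % 4 == 1:
                # half of isoform-B alignments report a spurious exon deep
                # inside the first intron: a disjoint extra block
                mid = (ex[0].end + ex[1].start) // 2
                exons = [exons[0], GenomeInterval(locus.chrom, mid, mid + 20)] + exons[1:]
            alignments[rid] = SplicedAlignment(rid, locus.chrom, "+", exons)
        cfg = PipelineConfig(seed=21)
        res = run_grouped_correction(reads, ref, cfg, alignments=alignments)

        def ari(groups):
            ids = [rid for g in groups for rid in g.members]
            pred = [i for i, g in enumerate(groups) for _ in g.members]
            true = [str(labels[rid]) for rid in ids]
            return adjusted_rand_score(true, pred)

        assert len(res.groups_round1) == 3
        assert len(res.groups_round2) == 2
        assert ari(res.groups_round2) > ari(res.groups_round1)
        assert ari(res.groups_round2) == 1.0
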