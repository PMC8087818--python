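"""Representative election, boundary variants, symmetry and annotation."""

import pytest

from isoscope.correction import merge_exon_blocks
from isoscope.exons import (
    annotate_exons,
    apply_pattern,
    classify_exon_state,
    detect_variants,
    elect_representatives,
    is_symmetric,
    pattern_string,
    primer_filter,
)
from isoscope.model import GenomeInterval, PipelineConfig, SplicedAlignment

CFG = PipelineConfig()


def _aln(read_id, pairs, chrom="c"):
    return SplicedAlignment(
        read_id, chrom, "+", [GenomeInterval(chrom, s, e) for s, e in pairs]
    )


class TestSymmetry:
    @pytest.mark.parametrize("length,flag", [(78, True), (61, False), (0, True),
                                             (5313, True), (1312, False)])
    def test_multiple_of_three(self, length, flag):
        assert is_symmetric(length) is flag

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            is_symmetric(-3)


class TestStateClassification:
    @pytest.mark.parametrize(
        "freq,state",
        [(0.98, "stable"), (0.45, "variable"), (0.105, "variable"),
         (0.005, "rare"), (0.0001, "rare"), (0.00001, None)],
    )
    def test_thresholds(self, freq, state):
        assert classify_exon_state(freq, CFG) == state

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            classify_exon_state(1.2, CFG)


class TestPatternString:
    REP = GenomeInterval("chr10", 123842161, 123847474)  # 5313-bp exon

    def test_five_prime_truncation(self):
        var = GenomeInterval("chr10", 123846573, 123847474)
        assert pattern_string(var, self.REP) == "L-4412:R0"

    def test_identity_pattern(self):
        assert pattern_string(self.REP, self.REP) == "L0:R0"

    def test_three_prime_extension(self):
        rep16 = GenomeInterval("chr10", 123969911, 123971223)
        var = GenomeInterval("chr10", 123969911, 123971235)
        assert pattern_string(var, rep16) == "L0:R12"
        assert abs(var.length - rep16.length) % 3 == 0  # frame-preserving

    def test_apply_pattern_round_trips(self):
        for pattern in ("L-4412:R0", "L0:R-2445", "L9:R0", "L0:R12"):
            var = apply_pattern(self.REP, pattern)
            assert pattern_string(var, self.REP) == pattern


class TestPrimerFilter:
    PRIMERS = (GenomeInterval("c", 100, 200), GenomeInterval("c", 900, 1000))

    def test_full_length_chain_kept(self):
        aln = _aln("a", [(120, 180), (500, 600), (920, 980)])
        assert primer_filter([aln], self.PRIMERS) == [aln]

    def test_chain_missing_three_prime_primer_dropped(self):
        aln = _aln("a", [(120, 180), (500, 600)])
        assert primer_filter([aln], self.PRIMERS) == []

    def test_off_target_alignment_dropped(self):
        aln = _aln("a", [(5000, 5100)], chrom="other")
        assert primer_filter([aln], self.PRIMERS) == []


class TestElectRepresentatives:
    def test_most_frequent_pair_wins(self):
        alns = [_aln(f"a{i}", [(10, 20)]) for i in range(5)]
        alns += [_aln(f"b{i}", [(10, 25)]) for i in range(3)]
        blocks = merge_exon_blocks(alns)
        catalog = elect_representatives(alns, blocks)
        (rep,) = catalog.representatives
        assert (rep.interval.start, rep.interval.end) == (10, 20)
        assert rep.rex_id == "rex01"

    def test_tie_breaks_toward_smaller_start_then_end(self):
        alns = [_aln("a", [(12, 20)]), _aln("b", [(10, 20)])]
        blocks = merge_exon_blocks(alns)
        (rep,) = elect_representatives(alns, blocks).representatives
        assert rep.interval.start == 10

    def test_single_observed_pair(self):
        alns = [_aln("a", [(7, 19)])]
        blocks = merge_exon_blocks(alns)
        (rep,) = elect_representatives(alns, blocks).representatives
        assert (rep.interval.start, rep.interval.end) == (7, 19)

    def test_primer_model_boundaries_clamp_outer_ends(self):
        alns = [_aln(f"r{i}", [(110, 200), (900, 990)]) for i in range(3)]
        blocks = merge_exon_blocks(alns)
        cfg = PipelineConfig(primer_model_boundaries=(100, 1000))
        catalog = elect_representatives(alns, blocks, cfg)
        first, last = catalog.representatives
        assert first.interval.start == 100
        assert last.interval.end == 1000


class TestDetectVariants:
    def test_threshold_is_strictly_more_than_five_percent(self):
        alns = [_aln(f"a{i}", [(10, 20)]) for i in range(90)]
        alns += [_aln(f"b{i}", [(10, 17)]) for i in range(8)]
        alns += [_aln(f"c{i}", [(12, 20)]) for i in range(2)]
        blocks = merge_exon_blocks(alns)
        catalog = elect_representatives(alns, blocks)
        variants = detect_variants(alns, catalog, blocks, CFG)
        assert [(v.interval.start, v.interval.end) for v in variants] == [(10, 17)]
        assert variants[0].pattern == "L0:R-3"
        assert variants[0].change_symmetric
        assert variants[0].support_frac > CFG.variant_frac

    def test_no_pair_above_threshold_yields_empty(self):
        alns = [_aln(f"a{i}", [(10, 20)]) for i in range(100)]
        alns += [_aln("b", [(10, 25)])]
        blocks = merge_exon_blocks(alns)
        catalog = elect_representatives(alns, blocks)
        assert detect_variants(alns, catalog, blocks, CFG) == []

    def test_higher_threshold_admits_fewer_variants(self):
        alns = [_aln(f"a{i}", [(10, 20)]) for i in range(60)]
        alns += [_aln(f"b{i}", [(10, 17)]) for i in range(25)]
        alns += [_aln(f"c{i}", [(12, 20)]) for i in range(15)]
        blocks = merge_exon_blocks(alns)
        lo = detect_variants(
            alns, elect_representatives(alns, blocks), blocks, PipelineConfig()
        )
        hi = detect_variants(
            alns, elect_representatives(alns, blocks), blocks,
            PipelineConfig(variant_frac=0.5),
        )
        assert len(hi) < len(lo)


class TestAnnotation:
    MODELS = [GenomeInterval("c", 100, 200), GenomeInterval("c", 400, 500)]

    def _catalog(self, pairs):
        alns = [_aln("a", pairs)]
        blocks = merge_exon_blocks(alns)
        return elect_representatives(alns, blocks)

    def test_exact_match_is_known(self):
        cat = annotate_exons(self._catalog([(100, 200)]), self.MODELS)
        assert cat.representatives[0].annotation == "known"

    def test_half_overlap_is_partially_known(self):
        cat = annotate_exons(self._catalog([(150, 250)]), self.MODELS)
        assert cat.representatives[0].annotation == "partially_known"

    def test_annotation_gap_is_novel(self):
        cat = annotate_exons(self._catalog([(250, 300)]), self.MODELS)
        assert cat.representatives[0].annotation == "novel"

    def test_missing_models_reported_unannotated(self):
        cat = annotate_exons(self._catalog([(100, 200)]), None)
        assert cat.representatives[0].annotation == "unannotated"
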