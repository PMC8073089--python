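"""Pileup construction and threshold-based calling."""

import pytest

from mitotile.align import AlignedRead
from mitotile.call import (
    CallError,
    Pileup,
    Thresholds,
    anchor_insertion,
    build_pileup,
    call_position,
    call_sample,
    insertion_calls,
    length_heteroplasmy_calls,
    strand_depth,
)
from mitotile.reference import Region

THR = Thresholds(10.0, 10.0, 45, 30)


def _pile(genome, pos, counts):
    """counts: dict base -> (fwd, rev)"""
    p = Pileup(genome_length=genome.length)
    for base, (f, r) in counts.items():
        for _ in range(f):
            (p.add_deletion if base == "del" else lambda x, s: p.add_base(x, base, s))(
                pos, "+"
            )
        for _ in range(r):
            (p.add_deletion if base == "del" else lambda x, s: p.add_base(x, base, s))(
                pos, "-"
            )
    return p


def _mread(genome, start, seq, qual=None, strand="+", cigar=None):
    return AlignedRead(
        read_id=f"r{start}",
        seq=seq,
        qual=qual or chr(36 + 33) * len(seq),
        strand=strand,
        ref_start=start,
        linear_start=start - 1,
        cigar=cigar or [("M", len(seq))],
        score=len(seq),
    )


class TestThresholds:
    def test_at_above_it_rejected(self):
        with pytest.raises(CallError):
            Thresholds(20.0, 10.0, 45, 30)

    def test_defaults_match_presets(self):
        from mitotile.call import CONTROL_REGION_THRESHOLDS, WHOLE_GENOME_THRESHOLDS

        assert (
            CONTROL_REGION_THRESHOLDS.analytical_threshold,
            CONTROL_REGION_THRESHOLDS.min_read_count,
        ) == (10.0, 64)
        assert (
            WHOLE_GENOME_THRESHOLDS.analytical_threshold,
            WHOLE_GENOME_THRESHOLDS.min_read_count,
        ) == (6.0, 45)


class TestBuildPileup:
    def test_counts_error_free_reads(self, genome):
        reads = [_mread(genome, 1000, genome.sequence[999:1060]) for _ in range(5)]
        pile = build_pileup(reads, genome)
        assert pile.total_depth(1030) == 5
        assert pile.base_count(1030, genome.base(1030)) == 5

    def test_empty_alignment_set(self, genome):
        pile = build_pileup([], genome)
        assert pile.total_depth(100) == 0

    def test_masked_base_reduces_depth_by_one(self, genome):
        reads = [_mread(genome, 1000, genome.sequence[999:1060]) for _ in range(3)]
        reads[0].masked_offsets.add(30)  # ref position 1030
        pile = build_pileup(reads, genome)
        assert pile.total_depth(1030) == 2
        assert pile.total_depth(1029) == 3

    def test_byproduct_and_numt_flags_exclude_whole_read(self, genome):
        r1 = _mread(genome, 1000, genome.sequence[999:1060])
        r1.flags["byproduct_filtered"] = True
        r2 = _mread(genome, 1000, genome.sequence[999:1060])
        r2.flags["numt_filtered"] = True
        pile = build_pileup([r1, r2], genome)
        assert pile.total_depth(1030) == 0

    def test_deletion_and_insertion_recording(self, genome):
        seq = genome.sequence[999:1029] + genome.sequence[1030:1060]  # 1030 deleted
        r = _mread(genome, 1000, seq, cigar=[("M", 30), ("D", 1), ("M", 30)])
        pile = build_pileup([r], genome)
        assert pile.counts[1030]["del"] == [1, 0]
        ins_seq = genome.sequence[999:1030] + "T" + genome.sequence[1030:1059]
        ri = _mread(genome, 1000, ins_seq, cigar=[("M", 31), ("I", 1), ("M", 29)])
        pile2 = build_pileup([ri], genome)
        assert any(k[2] == "T" for k in pile2.insertions)


class TestAnchorInsertion:
    def test_hvii_cstretch_anchors_to_309(self, genome):
        # a C inserted anywhere in the 303..309 run names as 309.N
        for pos in (303, 306, 309):
            assert anchor_insertion(genome, pos, "C") == 309

    def test_second_run_anchors_to_315(self, genome):
        assert anchor_insertion(genome, 311, "C") == 315

    def test_non_homopolymer_insertion_keeps_anchor(self, genome):
        pos = 310  # T between the C runs
        assert anchor_insertion(genome, pos, "T") == 310


class TestCallPosition:
    def test_clean_majority(self, genome):
        pile = _pile(genome, 1000, {"G": (50, 45), "A": (3, 2)})
        vc = call_position(pile, 1000, THR, genome)
        assert vc.called == "G"
        assert vc.depth == 100

    def test_two_base_heteroplasmy_iupac(self, genome):
        pile = _pile(genome, 1000, {"C": (35, 35), "T": (15, 15)})
        vc = call_position(pile, 1000, THR, genome)
        assert vc.called == "Y"

    def test_below_min_read_count_is_no_call(self, genome):
        pile = _pile(genome, 1000, {"G": (20, 20)})  # depth 40 < 45
        vc = call_position(pile, 1000, THR, genome)
        assert vc.status == "no_call"

    def test_retained_deletion(self, genome):
        pile = _pile(genome, 1000, {"del": (48, 48), "A": (2, 2)})
        vc = call_position(pile, 1000, THR, genome)
        assert vc.called == "del"

    def test_below_it_flag(self, genome):
        thr = Thresholds(5.0, 20.0, 45, 30)
        ref = genome.base(1000)
        alt = "A" if ref != "A" else "C"
        pile = _pile(genome, 1000, {ref: (45, 45), alt: (5, 5)})
        vc = call_position(pile, 1000, thr, genome)
        assert vc.status == "below_IT"


class TestStrandDepth:
    @pytest.mark.parametrize("fwd,rev,expected", [(120, 80, 120), (0, 0, 0), (50, 50, 50)])
    def test_majority_strand(self, genome, fwd, rev, expected):
        pile = _pile(genome, 500, {"G": (fwd, rev)})
        assert strand_depth(pile, 500) == expected


class TestInsertionCalls:
    def _ins_pile(self, genome, frac_with_insert, depth=200):
        pile = Pileup(genome_length=genome.length)
        n_ins = int(depth * frac_with_insert)
        for i in range(depth):
            pile.add_base(309, "C", "+" if i % 2 else "-")
            if i < n_ins:
                pile.add_insertion(309, 1, "C", "+" if i % 2 else "-")
        return pile

    def test_partial_insertion_renders_lowercase(self, genome):
        pile = self._ins_pile(genome, 0.6)
        calls = insertion_calls(pile, THR)
        assert len(calls) == 1
        assert calls[0].lowercase  # 60% < 90% of reads
        assert str(calls[0].token()) == "309.1c"

    def test_full_insertion_renders_uppercase(self, genome):
        pile = self._ins_pile(genome, 1.0)
        calls = insertion_calls(pile, THR)
        assert str(calls[0].token()) == "309.1C"

    def test_insertion_below_at_dropped(self, genome):
        pile = self._ins_pile(genome, 0.05)
        assert insertion_calls(pile, THR) == []


class TestLengthHeteroplasmy:
    def test_undeclared_region_rejected(self, genome):
        pile = Pileup(genome_length=genome.length)
        with pytest.raises(CallError):
            length_heteroplasmy_calls(
                pile, Region(100, 120), THR, genome, declared_homopolymers=[Region(303, 315)]
            )

    def test_uas_compat_reports_t_deletion_as_substitution(self, genome):
        # all reads delete the interrupting T at 16189; 60% insert a C
        pile = Pileup(genome_length=genome.length)
        region = Region(16184, 16193)
        for i in range(200):
            pile.add_deletion(16189, "+" if i % 2 else "-")
            if i < 120:
                pile.add_insertion(16193, 1, "C", "+" if i % 2 else "-")
            for pos in list(region.positions(genome.length)):
                if pos != 16189:
                    pile.add_base(pos, genome.base(pos), "+" if i % 2 else "-")
        off = length_heteroplasmy_calls(
            pile, region, THR, genome, declared_homopolymers=[region]
        )
        on = length_heteroplasmy_calls(
            pile, region, THR, genome, declared_homopolymers=[region], uas_compat=True
        )
        off_tokens = sorted(str(c.token()) for c in off)
        on_tokens = sorted(str(c.token()) for c in on)
        assert off_tokens == ["16193.1c"]
        assert "16189C" in on_tokens and "16193.1c" in on_tokens

    def test_uas_compat_reanchors_mixed_310_to_309_insertion(self, genome):
        # 30% of reads show C at the interrupting T (310): an alignment-shifted
        # C insertion that should re-anchor as the next 309.N ordinal
        pile = Pileup(genome_length=genome.length)
        region = Region(303, 315)
        for i in range(200):
            strand = "+" if i % 2 else "-"
            pile.add_base(310, "C" if i < 60 else "T", strand)
            for pos in region.positions(genome.length):
                if pos != 310:
                    pile.add_base(pos, genome.base(pos), strand)
        on = length_heteroplasmy_calls(
            pile, region, THR, genome, declared_homopolymers=[region], uas_compat=True
        )
        tokens = [str(c.token()) for c in on]
        assert "309.1c" in tokens


class TestCallSample:
    def _uniform_pileup(self, genome, target, depth=100, variants=None):
        variants = variants or {}
        pile = Pileup(genome_length=genome.length)
        for pos in target.positions(genome.length):
            base = variants.get(pos, genome.base(pos))
            for i in range(depth):
                pile.add_base(pos, base, "+" if i % 2 else "-")
        return pile

    def test_clean_sample_full_coverage_no_calls(self, genome):
        target = Region(16500, 100)  # wraps the origin
        pile = self._uniform_pileup(genome, target)
        res = call_sample(pile, THR, target, genome)
        assert res.coverage_percent == 100.0
        assert res.no_call_regions == []
        assert len(res.haplotype) == 0

    def test_planted_substitutions_called(self, genome):
        target = Region(900, 1100)
        alt1 = "A" if genome.base(950) != "A" else "G"
        alt2 = "T" if genome.base(1050) != "T" else "G"
        pile = self._uniform_pileup(genome, target, variants={950: alt1, 1050: alt2})
        res = call_sample(pile, THR, target, genome)
        from mitotile.nomenclature import format_haplotype

        assert format_haplotype(res.haplotype) == f"950{alt1} 1050{alt2}"

    def test_empty_pileup_is_all_no_call(self, genome):
        target = Region(1000, 1099)
        res = call_sample(Pileup(genome_length=genome.length), THR, target, genome)
        assert res.coverage_percent == 0.0
        assert res.no_call_regions == [target := Region(1000, 1099)]
        assert len(res.haplotype) == 0

    def test_dropout_produces_single_no_call_region(self, genome):
        target = Region(1000, 1199)
        pile = self._uniform_pileup(genome, Region(1000, 1099))
        pile2 = self._uniform_pileup(genome, Region(1150, 1199))
        for pos, slot in pile2.counts.items():
            pile.counts[pos] = slot
        res = call_sample(pile, THR, target, genome)
        assert res.no_call_regions == [Region(1100, 1149)]
        assert res.coverage_percent == 75.0

    def test_coverage_100_iff_no_call_empty(self, genome):
        target = Region(2000, 2099)
        for depth in (100, 30):  # above and below min read count
            pile = self._uniform_pileup(genome, target, depth=depth)
            res = call_sample(pile, THR, target, genome)
            assert (res.coverage_percent == 100.0) == (res.no_call_regions == [])

    def test_at_monotonicity_and_min_read_count_monotonicity(self, genome):
        target = Region(3000, 3199)
        variants = {}
        rngpos = [3010, 3050, 3090, 3130]
        for p in rngpos:
            variants[p] = "A" if genome.base(p) != "A" else "C"
        pile = self._uniform_pileup(genome, target, depth=80, variants=variants)
        # add minority evidence at one position
        for i in range(12):
            pile.add_base(3150, "G" if genome.base(3150) != "G" else "T", "+")
        keys = {}
        for at in (5.0, 10.0, 20.0):
            res = call_sample(pile, Thresholds(at, at, 45, 30), target, genome)
            keys[at] = {(t.position, t.ordinal) for t in res.haplotype}
        assert keys[20.0] <= keys[10.0] <= keys[5.0]
        lengths = []
        for mrc in (45, 81, 200):
            res = call_sample(pile, Thresholds(10, 10, mrc, 30), target, genome)
            lengths.append(sum(1 for r in res.no_call_regions for _ in r.positions(genome.length)))
        assert lengths[0] <= lengths[1] <= lengths[2]
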