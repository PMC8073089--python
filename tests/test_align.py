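"""Circular alignment and read-level filters."""

import random

import pytest

from mitotile.align import (
    AlignedRead,
    NumtDB,
    Scoring,
    align_read,
    filter_byproduct,
    fit_align,
    hvii_softclip,
    mask_low_quality,
    numt_filter,
    trim_primers,
)
from mitotile.simulate import revcomp

Q36 = lambda n: chr(36 + 33) * n  # noqa: E731


def _aligned(genome, start, seq=None, strand="+", cigar=None, qual=None):
    seq = seq or genome.sequence[start - 1 : start - 1 + 60]
    return AlignedRead(
        read_id="r",
        seq=seq,
        qual=qual or Q36(len(seq)),
        strand=strand,
        ref_start=start,
        linear_start=start - 1,
        cigar=cigar or [("M", len(seq))],
        score=len(seq),
    )


class TestFitAlign:
    def test_exact_match(self):
        ref = "AAACGTACGTACGTTT"
        score, start, cigar = fit_align("CGTACGTACG", ref)
        assert score == 10
        assert start == 3
        assert cigar == [("M", 10)]

    def test_mismatch_scoring(self):
        score, _, _ = fit_align("CGTACGTACG", "AAACGTACTTACGTTT".replace("T", "T"))
        # one mismatch: 9*1 - 4
        ref = "AAACGTACTTACGTTT"
        score, _, cigar = fit_align("CGTACGTACG", ref)
        assert score == 9 - 4
        assert cigar == [("M", 10)]

    def test_gap_scoring(self):
        ref = "AACCGGTTAACCGGTT"
        query = "CCGGTTACCGGT"  # one A deleted from the middle
        score, _, cigar = fit_align(query, ref)
        assert score == 12 * 1 - 6
        assert ("D", 1) in cigar

    def test_banded_equals_full_matrix_on_random_instances(self):
        rng = random.Random(77)
        sc = Scoring()
        for _ in range(40):
            n = rng.randint(40, 200)
            ref = "".join(rng.choice("ACGT") for _ in range(n + 40))
            q = list(ref[20 : 20 + n])
            for _ in range(rng.randint(0, 5)):
                q[rng.randrange(len(q))] = rng.choice("ACGT")
            for _ in range(rng.randint(0, 3)):
                p = rng.randrange(1, len(q) - 1)
                if rng.random() < 0.5:
                    q.insert(p, rng.choice("ACGT"))
                else:
                    del q[p]
            q = "".join(q)
            banded, _, _ = fit_align(q, ref, band=16, scoring=sc)
            full, _, _ = fit_align(q, ref, band=None, scoring=sc)
            assert banded == full


class TestAlignRead:
    def test_error_free_read_maps_to_amplicon_start(self, genome, panel, index):
        amp = panel.amplicons[0]
        start = amp.outer.start
        length = 100
        seq = (genome.sequence * 2)[start - 1 : start - 1 + length]
        ar = align_read("r1", seq, Q36(length), index, panel)
        assert ar.aligned
        assert ar.ref_start == start
        assert ar.cigar == [("M", length)]
        assert ar.amplicon_id == amp.id

    def test_read_spanning_origin(self, genome, index):
        # a read across the origin must align contiguously in circular coords
        seq = genome.sequence[-50:] + genome.sequence[:50]
        ar = align_read("wrap", seq, Q36(100), index)
        assert ar.aligned
        assert ar.ref_start == genome.length - 49
        assert ar.cigar == [("M", 100)]
        # score equals the exhaustive DP on the doubled sequence
        window = (genome.sequence * 2)[genome.length - 60 : genome.length + 60]
        oracle, _, _ = fit_align(seq, window, band=None)
        assert ar.score == oracle

    def test_reverse_strand_read(self, genome, panel, index):
        amp = panel.amplicons[1]
        start = amp.outer.start
        fwd = (genome.sequence * 2)[start - 1 : start - 1 + 90]
        ar = align_read("r2", revcomp(fwd), Q36(90), index, panel)
        assert ar.aligned and ar.strand == "-"
        assert ar.ref_start == start

    def test_read_with_insertion(self, genome, index):
        seq = genome.sequence[999:1050] + "A" * 0  # baseline
        mutated = genome.sequence[999:1025] + "T" + genome.sequence[1025:1050]
        ar = align_read("ins", mutated, Q36(len(mutated)), index)
        assert ar.aligned
        assert any(op == "I" for op, _ in ar.cigar)

    def test_random_read_flagged_unaligned(self, index):
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGT") for _ in range(120))
        ar = align_read("junk", seq, Q36(120), index)
        assert not ar.aligned
        assert ar.flags.get("unaligned")


class TestMaskLowQuality:
    def test_all_high_quality_empty_mask(self, genome):
        ar = _aligned(genome, 100)
        assert mask_low_quality(ar) == set()

    def test_q29_masked_q30_not(self, genome):
        qual = Q36(60)
        qual = chr(29 + 33) + qual[1:30] + chr(30 + 33) + qual[31:]
        ar = _aligned(genome, 100, qual=qual)
        masked = mask_low_quality(ar, 30)
        assert 0 in masked  # Q29 < 30: masked
        assert 30 not in masked  # Q30 is kept ("less than 30" is strict)

    def test_length_mismatch_errors(self, genome):
        ar = _aligned(genome, 100)
        ar.qual = ar.qual[:-1]
        with pytest.raises(ValueError):
            mask_low_quality(ar)


class TestByproductFilter:
    @pytest.mark.parametrize("insert,kept", [(39, False), (40, True), (60, True)])
    def test_boundary(self, genome, insert, kept):
        a = _aligned(genome, 100, seq=genome.sequence[99 : 99 + insert])
        b = _aligned(genome, 100, seq=genome.sequence[99 : 99 + insert])
        assert filter_byproduct(a, b, genome.length) is kept
        assert a.flags.get("byproduct_filtered", False) is (not kept)

    def test_insert_spans_mates(self, genome):
        a = _aligned(genome, 100, seq=genome.sequence[99:129])  # 100..129
        b = _aligned(genome, 150, seq=genome.sequence[149:179])  # 150..179
        assert filter_byproduct(a, b, genome.length)  # insert = 80


class TestTrimPrimers:
    def test_full_amplicon_read_clips_both_primers(self, genome, panel):
        amp = panel.amplicons[0]
        start = amp.outer.start
        length = amp.fwd_primer_len + 40 + amp.rev_primer_len
        from mitotile.reference import region_length

        outer_len = region_length(amp.outer, genome.length)
        seq = (genome.sequence * 2)[start - 1 : start - 1 + outer_len]
        ar = _aligned(genome, start, seq=seq)
        ar.amplicon_id = amp.id
        trim_primers(ar, panel, genome.length)
        assert len(ar.clipped_offsets) == amp.fwd_primer_len + amp.rev_primer_len
        assert set(range(amp.fwd_primer_len)) <= ar.clipped_offsets

    def test_read_inside_insert_untouched(self, genome, panel):
        amp = panel.amplicons[0]
        s = amp.insert.start
        seq = (genome.sequence * 2)[s - 1 : s - 1 + 30]
        ar = _aligned(genome, s, seq=seq)
        ar.amplicon_id = amp.id
        trim_primers(ar, panel, genome.length)
        assert ar.clipped_offsets == set()

    def test_unassigned_read_flagged(self, genome, panel):
        ar = _aligned(genome, 5000)
        trim_primers(ar, panel, genome.length)
        assert ar.flags.get("untrimmed")


class TestNumtFilter:
    def test_decoy_read_flagged(self, genome):
        seg = list(genome.sequence[2000:2120])
        for off in (10, 50, 90):  # three diagnostic edits
            seg[off] = "A" if seg[off] != "A" else "C"
        decoy = "".join(seg)
        db = NumtDB(decoys=[("numt1", decoy)])
        assert numt_filter(decoy[:100], db, genome, max_distance=2)

    def test_reference_read_not_flagged(self, genome):
        db = NumtDB(decoys=[("numt1", "ACGTTGCAAC" * 12)])
        assert not numt_filter(genome.sequence[3000:3100], db, genome)

    def test_empty_db_disabled(self, genome):
        assert not numt_filter(genome.sequence[3000:3100], NumtDB(), genome)
        assert not numt_filter(genome.sequence[3000:3100], None, genome)

    def test_fasta_loading(self, genome, tmp_path):
        p = tmp_path / "numts.fasta"
        p.write_text(">n1\nACGTACGTAC\n>n2\nTTTTACGTTT\n")
        assert len(NumtDB.from_fasta(p)) == 2


class TestHviiSoftclip:
    def _rev_read(self, genome, start=262, end=353, stutter=False):
        seq = list(genome.sequence[start - 1 : end])
        if stutter:
            seq[303 - start] = "A"  # two mismatches inside 303..315
            seq[308 - start] = "G"
        return AlignedRead(
            read_id="rev",
            seq="".join(seq),
            qual=Q36(len(seq)),
            strand="-",
            ref_start=start,
            linear_start=start - 1,
            cigar=[("M", len(seq))],
            score=len(seq),
        )

    def test_clean_reverse_read_not_clipped(self, genome):
        ar = hvii_softclip(self._rev_read(genome), genome)
        assert not ar.flags.get("hvii_softclipped")

    def test_stutter_reverse_read_clipped_after_303(self, genome):
        ar = hvii_softclip(self._rev_read(genome, stutter=True), genome)
        assert ar.flags.get("hvii_softclipped")
        # offsets for reference positions > 303 are excluded
        kept_ref = {
            col[1]
            for col in ar.walk(genome.length)
            if col[0] == "M" and col[2] not in ar.clipped_offsets
        }
        assert max(kept_ref) == 303
        assert 262 in kept_ref

    def test_forward_read_never_clipped(self, genome):
        ar = self._rev_read(genome, stutter=True)
        ar.strand = "+"
        assert not hvii_softclip(ar, genome).flags.get("hvii_softclipped")

    def test_reverse_read_away_from_anchor_not_clipped(self, genome):
        ar = self._rev_read(genome, stutter=True)
        ar.ref_start = 280
        ar.linear_start = 279
        assert not hvii_softclip(ar, genome).flags.get("hvii_softclipped")

    def test_coverage_halves_past_cstretch(self, genome):
        from mitotile.call import build_pileup

        reads = []
        for i in range(10):
            fwd = self._rev_read(genome)
            fwd.strand = "+"
            fwd.read_id = f"f{i}"
            reads.append(fwd)
            rev = self._rev_read(genome, stutter=True)
            rev.read_id = f"r{i}"
            reads.append(hvii_softclip(rev, genome))
        pile = build_pileup(reads, genome)
        assert pile.total_depth(280) == 20
        assert pile.total_depth(340) == 10  # half: reverse reads clipped
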