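"""Read simulator: haplotype application, heteroplasmy, runs and spiking."""

import math

import pytest

from mitotile.simulate import (
    HaplotypeSpec,
    LibrarySpec,
    RunSpec,
    SimulationError,
    VariantSpec,
    apply_haplotype,
    simulate_library,
    simulate_run,
    spike_numts,
    write_fastq_pair,
)
from mitotile.scenarios import (
    generate_index_pairs,
    mixture_library,
    random_haplotype,
    single_source_library,
)


class TestApplyHaplotype:
    def test_substitution_and_insertion(self, genome):
        hap = HaplotypeSpec.from_string("h", "263G 315.1C", lowercase_fraction=1.0)
        seq, coord = apply_haplotype(genome, hap)
        assert len(seq) == genome.length + 1
        assert seq[coord[263]] == "G"
        # bases after the insertion shift by one
        assert coord[316] == 316 - 1 + 1

    def test_empty_haplotype_is_identity(self, genome):
        seq, coord = apply_haplotype(genome, HaplotypeSpec("e", []))
        assert seq == genome.sequence
        assert all(coord[p] == p - 1 for p in (1, 100, genome.length))

    def test_deletion_shortens(self, genome):
        seq, coord = apply_haplotype(
            genome, HaplotypeSpec("d", [VariantSpec(249, "deletion")])
        )
        assert len(seq) == genome.length - 1
        assert coord[249] is None

    def test_conflicting_variants_rejected(self):
        with pytest.raises(SimulationError):
            HaplotypeSpec(
                "c",
                [
                    VariantSpec(100, "substitution", "G"),
                    VariantSpec(100, "deletion"),
                ],
            )

    def test_insertion_ordinals_contiguous(self):
        with pytest.raises(SimulationError):
            HaplotypeSpec(
                "c", [VariantSpec(100, "insertion", "C", insertion_index=2)]
            )


class TestSimulateLibrary:
    def test_ntc_produces_no_reads(self, genome, panel):
        lib = LibrarySpec("ntc", [], 0)
        assert simulate_library(genome, panel, lib) == []

    def test_deterministic_per_seed(self, genome, panel):
        hap = random_haplotype(genome, panel, 3, seed=8)
        a = simulate_library(genome, panel, single_source_library(hap, 80, seed=4))
        b = simulate_library(genome, panel, single_source_library(hap, 80, seed=4))
        assert [(r.r1_seq, r.r1_qual, r.r2_seq, r.r2_qual) for r in a] == [
            (r.r1_seq, r.r1_qual, r.r2_seq, r.r2_qual) for r in b
        ]

    def test_unknown_amplicon_id_rejected(self, genome, panel):
        hap = random_haplotype(genome, panel, 2, seed=8)
        lib = single_source_library(hap, 10, seed=1)
        lib.per_amplicon_efficiency = {"NOPE": 2.0}
        with pytest.raises(KeyError):
            simulate_library(genome, panel, lib)

    def test_mixture_minor_fraction_binomial(self, genome, panel):
        minor = random_haplotype(genome, panel, 3, seed=21, include_indels=False)
        major = random_haplotype(genome, panel, 3, seed=22, include_indels=False)
        n = 6000
        lib = mixture_library(minor, major, 1, 3, n, seed=5)
        reads = simulate_library(genome, panel, lib)
        m = sum(1 for r in reads if r.truth["contributor"] == minor.name)
        se = math.sqrt(0.25 * 0.75 / n)
        assert abs(m / n - 0.25) <= 3 * se

    def test_truth_tags_present(self, genome, panel):
        hap = random_haplotype(genome, panel, 2, seed=3)
        reads = simulate_library(genome, panel, single_source_library(hap, 5, seed=2))
        for r in reads:
            assert r.truth["contributor"] == hap.name
            assert panel.by_id(r.truth["amplicon"])


class TestSimulateRun:
    def test_bait_indexes_emit_no_reads(self, genome, panel):
        hap = random_haplotype(genome, panel, 2, seed=1)
        idx = generate_index_pairs(3, seed=1)
        run = simulate_run(
            RunSpec(
                libraries=[(single_source_library(hap, 30, seed=1), *idx[0])],
                bait_indexes=idx[1:],
                seed=1,
            ),
            genome,
            panel,
        )
        bait_pairs = {tuple(p) for p in idx[1:]}
        assert all((r.i7, r.i5) not in bait_pairs for r in run.reads)
        assert len(run.sample_sheet) == 3

    def test_duplicate_index_pairs_rejected(self, genome, panel):
        hap = random_haplotype(genome, panel, 2, seed=1)
        (pair,) = generate_index_pairs(1, seed=1)
        with pytest.raises(SimulationError):
            RunSpec(
                libraries=[
                    (single_source_library(hap, 5, seed=1), *pair),
                    (single_source_library(hap, 5, seed=2, sample_name="b"), *pair),
                ]
            )

    def test_crosstalk_rate_binomial(self, genome, panel):
        hap = random_haplotype(genome, panel, 2, seed=1)
        idx = generate_index_pairs(2, seed=2)
        # share the i7 read so crosstalk has a destination
        shared = [(idx[0][0], idx[0][1]), (idx[0][0], idx[1][1])]
        libs = [
            (single_source_library(hap, 2000, seed=1, sample_name="a"), *shared[0]),
            (single_source_library(hap, 2000, seed=2, sample_name="b"), *shared[1]),
        ]
        run = simulate_run(
            RunSpec(libraries=libs, crosstalk_rate=0.01, seed=3), genome, panel
        )
        n = len(run.reads)
        mis = len(run.truth["crosstalk_reads"])
        se = math.sqrt(0.01 * 0.99 / n)
        assert abs(mis / n - 0.01) <= 3 * se

    def test_zero_carryover_lists_no_reads(self, genome, panel):
        hap = random_haplotype(genome, panel, 2, seed=1)
        idx = generate_index_pairs(2, seed=4)
        prev = RunSpec(
            libraries=[(single_source_library(hap, 50, seed=1), *idx[0])], seed=1
        )
        run = simulate_run(
            RunSpec(
                libraries=[(single_source_library(hap, 50, seed=2), *idx[1])],
                carryover=(prev, 0.0),
                seed=2,
            ),
            genome,
            panel,
        )
        assert run.truth["carryover_reads"] == []

    def test_fastq_output_byte_identical_across_seed_repeats(
        self, genome, panel, tmp_path
    ):
        hap = random_haplotype(genome, panel, 2, seed=1)
        idx = generate_index_pairs(1, seed=5)
        spec = RunSpec(
            libraries=[(single_source_library(hap, 40, seed=6), *idx[0])], seed=6
        )
        texts = []
        for rep in range(2):
            run = simulate_run(spec, genome, panel)
            r1 = tmp_path / f"r1_{rep}.fastq"
            r2 = tmp_path / f"r2_{rep}.fastq"
            write_fastq_pair(run.reads, r1, r2)
            texts.append((r1.read_text(), r2.read_text()))
        assert texts[0] == texts[1]


class TestSpikeNumts:
    def _reads(self, genome, panel, n=400):
        hap = random_haplotype(genome, panel, 2, seed=9)
        return simulate_library(genome, panel, single_source_library(hap, n, seed=9))

    def test_fraction_zero_unchanged(self, genome, panel):
        reads = self._reads(genome, panel, 20)
        assert spike_numts(reads, [("n1", "ACGT" * 40)], 0.0, seed=1) is reads

    def test_fraction_binomial(self, genome, panel):
        reads = self._reads(genome, panel, 2000)
        decoys = [("n1", "ACGTTGCA" * 30)]
        out = spike_numts(reads, decoys, 0.05, seed=2)
        tagged = sum(1 for r in out if "numt" in r.truth)
        se = math.sqrt(0.05 * 0.95 / len(reads))
        assert abs(tagged / len(reads) - 0.05) <= 3 * se

    def test_decoy_identical_to_reference_warns(self, genome, panel):
        reads = self._reads(genome, panel, 10)
        decoy = genome.sequence[1000:1150]
        with pytest.warns(UserWarning, match="identical to a reference segment"):
            spike_numts(reads, [("twin", decoy)], 0.5, seed=3, genome=genome)

    def test_fraction_out_of_range(self, genome, panel):
        with pytest.raises(SimulationError):
            spike_numts(self._reads(genome, panel, 5), [("n", "ACGT")], 1.5, seed=1)
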