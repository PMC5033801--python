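"""Sliding-window genotyping, masking and bin-marker construction."""

import numpy as np
import pytest

from chalkmap import bin_genotyping as bg
from chalkmap import synthetic_data as sd
from chalkmap import variant_filtering as vf
from chalkmap.core import GENO_A, GENO_B, GENO_H, MISSING


class TestWindowGenotype:
    def test_unanimous_window_is_homozygous(self):
        assert bg.window_genotype(np.full(15, GENO_A)) == GENO_A

    def test_split_window_is_heterozygous(self):
        calls = np.array([GENO_A] * 8 + [GENO_B] * 7)
        assert bg.window_genotype(calls) == GENO_H

    def test_sparse_window_is_missing(self):
        calls = np.array([GENO_A] * 3 + [MISSING] * 12)
        assert bg.window_genotype(calls) == MISSING

    def test_hom_min_boundary(self):
        calls = np.array([GENO_A] * 11 + [GENO_B] * 4)
        assert bg.window_genotype(calls) == GENO_A
        calls = np.array([GENO_A] * 10 + [GENO_B] * 5)
        assert bg.window_genotype(calls) == GENO_H


class TestSegmentLine:
    def test_breakpoint_at_midpoint_between_runs(self):
        pos = np.concatenate([
            np.arange(20) * 50_000 + 50_000,          # A block
            np.arange(20) * 50_000 + 1_200_000,       # B block
        ])
        pos[19] = 1_000_000
        calls = np.array([GENO_A] * 20 + [GENO_B] * 20, dtype=np.int8)
        segs = bg.segment_line(pos, calls, 3_000_000)
        assert len(segs) == 2
        assert segs[0].end == (1_000_000 + 1_200_000) // 2
        assert segs[1].start == segs[0].end + 1

    def test_uniform_line_single_segment(self):
        pos = np.arange(100) * 10_000 + 1
        calls = np.full(100, GENO_A, dtype=np.int8)
        segs = bg.segment_line(pos, calls, 2_000_000)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (1, 2_000_000)
        assert segs[0].genotype == GENO_A

    def test_short_chromosome_majority_with_warning(self, caplog):
        pos = np.arange(8) * 1000 + 1
        calls = np.array([GENO_A] * 6 + [GENO_B] * 2, dtype=np.int8)
        with caplog.at_level("WARNING"):
            segs = bg.segment_line(pos, calls, 10_000)
        assert len(segs) == 1
        assert segs[0].genotype == GENO_A

    def test_double_recombinant_core_recovered(self):
        # B core of 10 SNPs inside A background: the window consensus
        # dilutes it to H, the flank-informed re-call restores it
        calls = np.array([GENO_A] * 30 + [GENO_B] * 10 + [GENO_A] * 30,
                         dtype=np.int8)
        pos = np.arange(1, 71) * 100_000
        segs = bg.segment_line(pos, calls, 7_100_000)
        assert [s.genotype for s in segs] == [GENO_A, GENO_B, GENO_A]
        assert segs[1].n_snps == 10

    def test_segments_tile_chromosome(self, two_chrom_config,
                                      two_chrom_observations):
        vm = vf.classify_sites(two_chrom_observations)
        vm, _ = vf.filter_calls(vm)
        lengths = {c.name: c.length_bp for c in two_chrom_config.chromosomes}
        _, segments = bg.bin_population(vm, chrom_lengths=lengths)
        for line, segs in list(segments.items())[:20]:
            for chrom, length in lengths.items():
                ss = sorted((s for s in segs if s.chrom == chrom),
                            key=lambda s: s.start)
                assert ss[0].start == 1
                assert ss[-1].end == length
                for a, b in zip(ss, ss[1:]):
                    assert b.start == a.end + 1

    def test_error_free_full_capture_breakpoints_bracket_truth(self):
        cfg = sd.SimConfig(
            n_lines=40, capture_fraction=1.0, genotyping_error=0.0,
            chromosomes=[sd.ChromosomeSpec("c1", 30_000_000, 120.0)],
            seed=21)
        g = sd.simulate_ril_genomes(cfg)
        vm = sd.simulate_gbs_observations(g, cfg)
        _, segments = bg.bin_population(
            vm, chrom_lengths={"c1": 30_000_000})
        spacing = 30_000_000 / vm.n_sites
        for j, line in enumerate(g.lines):
            truth = g.junctions("c1", j)
            rec = np.array(sorted(
                s.end for s in segments[line] if s.end < 30_000_000))
            for b in truth:
                if len(rec) == 0:
                    continue
                d = np.min(np.abs(rec - b))
                # every recovered breakpoint within the flanking observed
                # SNP gap of some true junction (window-width slack for
                # junctions near the chromosome ends)
                assert d <= 40 * spacing


class TestMaskSegments:
    @pytest.mark.parametrize("length,n_snps,masked", [
        (250_000, 3, True),     # both conditions met
        (250_000, 10, False),   # enough SNPs
        (400_000, 3, False),    # long enough
    ])
    def test_conjunctive_masking_rule(self, length, n_snps, masked):
        seg = bg.GenotypeSegment("L1", "c1", 1, length, GENO_A, n_snps)
        out = bg.mask_segments([seg])
        assert (out[0].genotype == MISSING) == masked

    def test_neighbours_not_merged_across_mask(self):
        segs = [
            bg.GenotypeSegment("L1", "c1", 1, 1_000_000, GENO_A, 30),
            bg.GenotypeSegment("L1", "c1", 1_000_001, 1_100_000, GENO_B, 2),
            bg.GenotypeSegment("L1", "c1", 1_100_001, 2_000_000, GENO_A, 30),
        ]
        out = bg.mask_segments(segs)
        assert [s.genotype for s in out] == [GENO_A, MISSING, GENO_A]
        assert len(out) == 3


class TestBuildBinMarkers:
    def _segs(self, line, chrom, parts):
        out = []
        pos = 1
        for end, g in parts:
            out.append(bg.GenotypeSegment(line, chrom, pos, end, g, 10))
            pos = end + 1
        return out

    def test_population_without_breakpoints_gives_one_bin_per_chrom(self):
        by_line = {
            "L1": self._segs("L1", "c1", [(1_000_000, GENO_A)]),
            "L2": self._segs("L2", "c1", [(1_000_000, GENO_B)]),
        }
        bins = bg.build_bin_markers(by_line, {"c1": 1_000_000},
                                    ["L1", "L2"])
        assert bins.n_markers == 1
        assert list(bins.genotypes[0]) == [GENO_A, GENO_B]

    def test_identical_adjacent_intervals_merge(self):
        by_line = {
            "L1": self._segs("L1", "c1", [(400_000, GENO_A),
                                          (1_000_000, GENO_B)]),
            "L2": self._segs("L2", "c1", [(600_000, GENO_A),
                                          (1_000_000, GENO_B)]),
        }
        bins = bg.build_bin_markers(by_line, {"c1": 1_000_000},
                                    ["L1", "L2"])
        # boundaries at 400k and 600k -> 3 intervals, all distinct vectors
        assert bins.n_markers == 3
        assert bins.ids == ["mk1", "mk2", "mk3"]
        assert list(bins.start) == [1, 400_001, 600_001]

    def test_ids_follow_genome_order(self, two_chrom_config,
                                     two_chrom_observations):
        vm = vf.classify_sites(two_chrom_observations)
        vm, _ = vf.filter_calls(vm)
        lengths = {c.name: c.length_bp for c in two_chrom_config.chromosomes}
        bins, _ = bg.bin_population(vm, chrom_lengths=lengths)
        order = np.lexsort((bins.start, bins.chroms))
        assert list(order) == list(range(bins.n_markers))
        # adjacent same-chromosome markers differ somewhere
        for i in range(bins.n_markers - 1):
            if bins.chroms[i] == bins.chroms[i + 1]:
                assert not np.array_equal(bins.genotypes[i],
                                          bins.genotypes[i + 1])

    def test_bin_count_close_to_truth_junction_union(
            self, two_chrom_config, two_chrom_genomes,
            two_chrom_observations):
        from chalkmap.evaluation import oracle_bin_count
        vm = vf.classify_sites(two_chrom_observations)
        vm, _ = vf.filter_calls(vm)
        lengths = {c.name: c.length_bp for c in two_chrom_config.chromosomes}
        bins, _ = bg.bin_population(vm, chrom_lengths=lengths)
        oracle = oracle_bin_count(two_chrom_genomes)
        assert abs(bins.n_markers - oracle) / oracle <= 0.15

    def test_determinism(self, two_chrom_config, two_chrom_observations):
        vm = vf.classify_sites(two_chrom_observations)
        vm, _ = vf.filter_calls(vm)
        lengths = {c.name: c.length_bp for c in two_chrom_config.chromosomes}
        b1, _ = bg.bin_population(vm, chrom_lengths=lengths)
        b2, _ = bg.bin_population(vm, chrom_lengths=lengths)
        assert b1.ids == b2.ids
        assert np.array_equal(b1.start, b2.start)
        assert np.array_equal(b1.genotypes, b2.genotypes)
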