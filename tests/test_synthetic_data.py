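"""Generator checks: selfing theory, GBS channel, phenotypes, counts."""

import numpy as np
import pytest
from scipy import stats

from _util import gamete_drop_line
from chalkmap import synthetic_data as sd
from chalkmap.core import GENO_A, GENO_B, GENO_H, MISSING
from chalkmap.ril_theory import junction_densities


def _one_chrom_config(n_lines, length_cm=180.0, seed=0, **kw):
    return sd.SimConfig(
        n_lines=n_lines,
        chromosomes=[sd.ChromosomeSpec("c1", 30_000_000, length_cm)],
        seed=seed, **kw)


class TestRILGenomes:
    def test_residual_heterozygosity_matches_selfing_expectation(self):
        # (1/2)^6 per-locus heterozygosity at F7; 10,000 lines
        cfg = _one_chrom_config(10_000, seed=1)
        g = sd.simulate_ril_genomes(cfg)
        expected = 0.5 ** 6
        got = g.het_fraction()
        # binomial SE at the per-line level (tract lengths inflate the
        # variance; 3 SDs of the per-line het fraction mean is generous)
        per_line = []
        for m in g.mosaics["c1"]:
            segs = m.segments(30_000_000)
            tot = sum(e - s + 1 for s, e, _ in segs)
            het = sum(e - s + 1 for s, e, gg in segs if gg == GENO_H)
            per_line.append(het / tot)
        se = np.std(per_line) / np.sqrt(len(per_line))
        assert abs(got - expected) < 3 * se + 1e-4

    def test_zero_genetic_length_gives_single_segment(self):
        cfg = sd.SimConfig(
            n_lines=50,
            chromosomes=[sd.ChromosomeSpec("flat", 5_000_000, 0.0)],
            seed=2)
        g = sd.simulate_ril_genomes(cfg)
        for m in g.mosaics["flat"]:
            assert len(m.breaks) == 0
            assert len(m.genos) == 1

    def test_junction_count_matches_gamete_dropping_oracle(self):
        # mean junction count and full distribution (KS) vs per-meiosis
        # oracle at 180 cM, 6 selfing generations
        n = 1000
        cfg = _one_chrom_config(n, length_cm=180.0, seed=3)
        g = sd.simulate_ril_genomes(cfg)
        direct = np.array([len(g.junctions("c1", j)) for j in range(n)])
        rng = np.random.default_rng(99)
        oracle = np.array([gamete_drop_line(1.8, 6, rng)[0]
                           for _ in range(n)])
        se = np.sqrt(direct.var() / n + oracle.var() / n)
        assert abs(direct.mean() - oracle.mean()) < 3 * se
        assert stats.ks_2samp(direct, oracle).pvalue > 0.01

    def test_fixed_seed_reproduces_everything(self):
        cfg = _one_chrom_config(20, seed=5)
        g1 = sd.simulate_ril_genomes(cfg)
        g2 = sd.simulate_ril_genomes(cfg)
        for a, b in zip(g1.mosaics["c1"], g2.mosaics["c1"]):
            assert np.array_equal(a.breaks, b.breaks)
            assert np.array_equal(a.genos, b.genos)
        v1 = sd.simulate_gbs_observations(g1, cfg)
        v2 = sd.simulate_gbs_observations(g2, cfg)
        assert np.array_equal(v1.calls, v2.calls)
        assert np.array_equal(v1.depth, v2.depth)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sd.SimConfig(chromosomes=[
                sd.ChromosomeSpec("bad", -5, 100.0)]).validate()
        with pytest.raises(ValueError):
            sd.SimConfig(capture_fraction=0.0).validate()

    def test_junction_density_theory_limits(self):
        # fixation limit: homozygous junction density -> 2 per Morgan
        lam_inf, _, _ = junction_densities(40)
        assert abs(lam_inf - 2.0) < 1e-3


class TestGBSObservations:
    def test_full_capture_no_error_equals_truth(self):
        cfg = _one_chrom_config(30, seed=6, capture_fraction=1.0,
                                genotyping_error=0.0)
        g = sd.simulate_ril_genomes(cfg)
        vm = sd.simulate_gbs_observations(g, cfg)
        assert (vm.calls != MISSING).all()
        for j in range(30):
            truth = g.mosaics["c1"][j].genotype_at(vm.pos)
            assert np.array_equal(vm.calls[:, j], truth)

    def test_observed_site_count_binomial(self):
        cfg = sd.SimConfig(
            n_lines=50, snp_density=1000.0, capture_fraction=0.07,
            chromosomes=[sd.ChromosomeSpec("c1", 30_000_000, 120.0)],
            seed=7)
        g = sd.simulate_ril_genomes(cfg)
        vm = sd.simulate_gbs_observations(g, cfg)
        n_sites = vm.n_sites
        assert n_sites == 30_000
        per_line = (vm.calls != MISSING).sum(axis=0)
        exp = n_sites * 0.07
        sdv = np.sqrt(n_sites * 0.07 * 0.93)
        assert abs(per_line.mean() - exp) < 3 * sdv / np.sqrt(50)
        assert (np.abs(per_line - exp) < 5 * sdv).all()

    def test_error_rate_recovered_against_truth(self):
        cfg = _one_chrom_config(100, seed=8, genotyping_error=0.01)
        g = sd.simulate_ril_genomes(cfg)
        vm = sd.simulate_gbs_observations(g, cfg)
        mism = 0
        called = 0
        for j in range(100):
            truth = g.mosaics["c1"][j].genotype_at(vm.pos)
            obs = vm.calls[:, j]
            hom = (obs != MISSING) & np.isin(truth, (GENO_A, GENO_B))
            called += int(hom.sum())
            mism += int((obs[hom] != truth[hom]).sum())
        rate = mism / called
        se = np.sqrt(0.01 * 0.99 / called)
        assert abs(rate - 0.01) < 3 * se

    def test_depth_truncated_poisson(self):
        cfg = _one_chrom_config(50, seed=9)
        g = sd.simulate_ril_genomes(cfg)
        vm = sd.simulate_gbs_observations(g, cfg)
        obs = vm.depth[vm.calls != MISSING]
        assert obs.min() >= 1
        assert abs(obs.mean() - 11.76) < 0.1


class TestPhenotypes:
    def test_null_traits_have_unit_variance(self, rng):
        cfg = _one_chrom_config(400, seed=10)
        g = sd.simulate_ril_genomes(cfg)
        ph = sd.simulate_phenotypes(g, [], ["E1"], rng,
                                    default_resid_sd=1.0)
        for t in sd.TRAITS:
            v = ph[t].var()
            assert abs(v - 1.0) < 3 * np.sqrt(2.0 / 400)

    def test_single_qtl_realized_pve(self, rng):
        # a=1, sigma^2=3 -> PVE = 1/(1+3) = 25%
        cfg = _one_chrom_config(2000, seed=11)
        g = sd.simulate_ril_genomes(cfg)
        q = sd.QTLSpec("GW", "c1", 90.0, 1.0, {"E1": 1.0},
                       {"E1": np.sqrt(3.0)})
        ph = sd.simulate_phenotypes(g, [q], ["E1"], rng)
        y = ph["GW"].to_numpy()
        x = sd.genotype_scores_at(g, "c1", 90.0)
        x = np.nan_to_num(x)
        pve = np.var(x * 1.0) / y.var()
        assert abs(pve - 0.25) < 0.03

    def test_zero_effect_uncorrelated_with_genotype(self, rng):
        cfg = _one_chrom_config(500, seed=12)
        g = sd.simulate_ril_genomes(cfg)
        q = sd.QTLSpec("GW", "c1", 90.0, 1.0,
                       {"E1": 0.0}, {"E1": 1.0})
        ph = sd.simulate_phenotypes(g, [q], ["E1"], rng)
        x = np.nan_to_num(sd.genotype_scores_at(g, "c1", 90.0))
        r = np.corrcoef(x, ph["GW"])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(500)

    def test_unknown_qtl_chromosome_rejected(self, rng):
        cfg = _one_chrom_config(10, seed=13)
        g = sd.simulate_ril_genomes(cfg)
        q = sd.QTLSpec("GW", "nope", 10.0, 1.0, {}, {})
        with pytest.raises(ValueError):
            sd.simulate_phenotypes(g, [q], ["E1"], rng)


class TestCounts:
    def test_zero_dispersion_counts_are_poisson(self, rng):
        specs = [sd.DEGSpec(f"g{i}", "c1", 1, 100, baseline_mean=100.0,
                            dispersion=0.0) for i in range(5000)]
        counts = sd.simulate_counts(specs, ["s1", "s2"], rng=rng)
        x = counts.to_numpy().ravel()
        assert abs(x.var() / x.mean() - 1.0) < 0.05

    def test_log2fc_three_gives_eightfold_mean_ratio(self, rng):
        specs = [sd.DEGSpec(f"g{i}", "c1", 1, 100, baseline_mean=100.0,
                            log2fc=3.0, dispersion=0.0,
                            affected_samples=["s2"])
                 for i in range(2000)]
        counts = sd.simulate_counts(specs, ["s1", "s2"], rng=rng)
        ratio = counts["s2"].mean() / counts["s1"].mean()
        assert abs(ratio - 8.0) < 0.2

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            sd.DEGSpec("g", "c1", 1, 100, baseline_mean=10.0,
                       dispersion=-0.1)

    def test_library_size_scaling(self, rng):
        specs = [sd.DEGSpec(f"g{i}", "c1", 1, 100, baseline_mean=200.0,
                            dispersion=0.0) for i in range(2000)]
        counts = sd.simulate_counts(specs, ["s1", "s2"],
                                    {"s1": 1e6, "s2": 2e6}, rng=rng)
        ratio = counts["s2"].mean() / counts["s1"].mean()
        assert abs(ratio - 2.0) < 0.1
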