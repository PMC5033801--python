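"""ICIM-ADD components: stepwise selection, EM scan, peaks, clustering."""

import numpy as np
import pytest

from _util import truth_marker_matrix
from chalkmap import linkage_map as lm
from chalkmap import qtl_mapping as qm
from chalkmap import synthetic_data as sd
from chalkmap.core import GENO_A, GENO_B, MISSING, geno_to_score


def _coded_markers(rng, n=192, m=50):
    return np.where(rng.random((n, m)) < 0.5, 1.0, -1.0)


class TestStepwiseSelect:
    def test_constant_phenotype_selects_nothing(self, rng):
        X = _coded_markers(rng)
        sel, coefs, _ = qm.stepwise_select(np.ones(192), X)
        assert sel == [] and coefs == {}

    def test_strong_marker_selected_in_most_replicates(self):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            X = _coded_markers(rng)
            y = 2.0 * X[:, 17] + rng.normal(0, 0.5, 192)
            sel, _, _ = qm.stepwise_select(y, X)
            # the marker itself or a near-perfect proxy
            ok = any(abs(np.corrcoef(X[:, k], X[:, 17])[0, 1]) > 0.95
                     for k in sel)
            hits += ok
        assert hits >= 95

    def test_null_selection_rate_matches_p_in(self):
        total = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(2000 + rep)
            X = _coded_markers(rng, m=100)
            y = rng.normal(0, 1, 192)
            sel, _, _ = qm.stepwise_select(y, X)
            total += len(sel)
        expected = n_rep * 100 * 0.001   # = 20
        assert total < expected + 3 * np.sqrt(expected) + 5
        assert total > 0

    def test_collinear_duplicates_keep_first(self, rng):
        X = _coded_markers(rng, m=10)
        X[:, 4] = X[:, 3]
        y = 3.0 * X[:, 3] + rng.normal(0, 0.5, 192)
        sel, _, _ = qm.stepwise_select(y, X)
        assert 3 in sel and 4 not in sel


class TestAdjustPhenotype:
    def test_empty_selection_identity(self, rng):
        y = rng.normal(size=50)
        X = _coded_markers(rng, n=50, m=5)
        assert np.array_equal(qm.adjust_phenotype(y, X, {}), y)

    def test_flanking_markers_excluded(self, rng):
        y = rng.normal(size=50)
        X = _coded_markers(rng, n=50, m=5)
        coefs = {1: 2.0, 2: -1.0}
        dy = qm.adjust_phenotype(y, X, coefs, exclude={1, 2})
        assert np.array_equal(dy, y)

    def test_off_interval_marker_subtracted_elementwise(self, rng):
        y = rng.normal(size=50)
        X = _coded_markers(rng, n=50, m=5)
        dy = qm.adjust_phenotype(y, X, {0: 1.5}, exclude=set())
        assert np.allclose(dy, y - 1.5 * X[:, 0])


class TestGenotypeProbabilities:
    def test_scan_point_at_marker_is_deterministic(self):
        pA, pH, pB = qm.qtl_genotype_prob(
            np.array([GENO_A]), np.array([GENO_A]), 0.0, 0.3)
        assert pA[0] == pytest.approx(1.0)

    def test_discordant_flanks_symmetric(self):
        pA, _, pB = qm.qtl_genotype_prob(
            np.array([GENO_A]), np.array([GENO_B]), 0.1, 0.1)
        assert pA[0] == pytest.approx(0.5)
        assert pB[0] == pytest.approx(0.5)

    def test_concordant_flanks_formula(self):
        pA, _, _ = qm.qtl_genotype_prob(
            np.array([GENO_A]), np.array([GENO_A]), 0.1, 0.1)
        assert pA[0] == pytest.approx(0.81 / 0.82)

    def test_missing_flank_conditions_on_observed(self):
        pA, _, _ = qm.qtl_genotype_prob(
            np.array([GENO_A]), np.array([MISSING]), 0.1, 0.4)
        assert pA[0] == pytest.approx(0.9)
        pA, _, _ = qm.qtl_genotype_prob(
            np.array([MISSING]), np.array([MISSING]), 0.1, 0.1)
        assert pA[0] == pytest.approx(0.5)


class TestEMScan:
    def test_closed_form_lod_and_additive(self):
        y = np.array([2.0, 4.0, 2.0, 4.0, -2.0, -4.0, -2.0, -4.0])
        pA = np.array([1.0] * 4 + [0.0] * 4)
        lod, a, _, _, _ = qm.em_scan_position(y, pA, np.zeros(8), 1 - pA)
        assert lod == pytest.approx(4.0, abs=1e-6)
        assert a == pytest.approx(3.0, abs=1e-6)

    def test_equal_class_means_no_signal(self, rng):
        y = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 1, 50)])
        pA = np.array([1.0] * 50 + [0.0] * 50)
        lod, a, _, _, _ = qm.em_scan_position(y, pA, np.zeros(100), 1 - pA)
        assert lod < 1.0
        assert abs(a) < 0.5

    def test_uninformative_probabilities_zero_lod(self, rng):
        y = rng.normal(0, 1, 100)
        pA = np.full(100, 0.5)
        lod, _, _, _, _ = qm.em_scan_position(y, pA, np.zeros(100), 1 - pA)
        assert lod <= 1e-6

    def test_em_matches_regression_lod_when_fully_informative(self, rng):
        # LOD == (n/2) log10(RSS0/RSS1) with hard genotype classes
        for rep in range(5):
            r = np.random.default_rng(300 + rep)
            n = 120
            cls = r.random(n) < 0.5
            y = np.where(cls, 1.2, -1.2) + r.normal(0, 2.0, n)
            pA = cls.astype(float)
            lod, _, _, _, _ = qm.em_scan_position(
                y, pA, np.zeros(n), 1 - pA,
                qm.ScanConfig(em_tol=1e-12, em_max_iter=500))
            x = np.where(cls, 1.0, -1.0)
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            rss1 = ((y - X @ beta) ** 2).sum()
            rss0 = ((y - y.mean()) ** 2).sum()
            expect = (n / 2) * np.log10(rss0 / rss1)
            assert lod == pytest.approx(expect, abs=1e-6)

    def test_affine_phenotype_invariance(self, rng):
        y = rng.normal(0, 1, 100) + np.repeat([1.0, -1.0], 50)
        pA = np.array([1.0] * 50 + [0.0] * 50)
        lod1, _, _, _, _ = qm.em_scan_position(y, pA, np.zeros(100), 1 - pA)
        lod2, _, _, _, _ = qm.em_scan_position(
            5.0 * y + 30.0, pA, np.zeros(100), 1 - pA)
        assert lod1 == pytest.approx(lod2, abs=1e-4)


@pytest.fixture(scope="module")
def scan_setup():
    chroms = [sd.ChromosomeSpec("c1", 30_000_000, 100.0)]
    cfg = sd.SimConfig(n_lines=192, chromosomes=chroms, seed=55)
    g = sd.simulate_ril_genomes(cfg)
    bins = truth_marker_matrix(g, spacing_cm=1.25)
    gmap = lm.build_map(bins)
    return g, bins, gmap


class TestScanGenome:
    def test_planted_qtl_recovered(self, scan_setup):
        g, bins, gmap = scan_setup
        q = sd.QTLSpec("T", "c1", 40.0, 1.0, {"E": 1.0}, {"E": 2.0})
        ph = sd.simulate_phenotypes(g, [q], ["E"],
                                    np.random.default_rng(8))
        y = ph.set_index("line")["T"].reindex(bins.lines).to_numpy()
        recs, prof = qm.scan_genome(y, bins, gmap, trait="T",
                                    environment="E")
        assert recs, "no QTL detected"
        best = max(recs, key=lambda r: r.lod)
        true_pos = 0.40 * gmap.chrom_length_cm("c1")
        assert abs(best.pos_cm - true_pos) <= 5.0
        assert best.lod >= 2.5
        assert best.additive > 0

    def test_b_parent_allele_gives_negative_additive(self, scan_setup):
        g, bins, gmap = scan_setup
        # negative additive: the B allele increases the trait
        q = sd.QTLSpec("T", "c1", 40.0, -1.0, {"E": 1.0}, {"E": 2.0})
        ph = sd.simulate_phenotypes(g, [q], ["E"],
                                    np.random.default_rng(9))
        y = ph.set_index("line")["T"].reindex(bins.lines).to_numpy()
        recs, _ = qm.scan_genome(y, bins, gmap, trait="T", environment="E")
        best = max(recs, key=lambda r: r.lod)
        assert best.additive < 0

    def test_mostly_missing_phenotype_skipped(self, scan_setup, caplog):
        g, bins, gmap = scan_setup
        y = np.full(len(bins.lines), np.nan)
        y[:20] = 1.0
        with caplog.at_level("WARNING"):
            recs, prof = qm.scan_genome(y, bins, gmap, trait="T",
                                        environment="E")
        assert recs == []


class TestStabilityAndClusters:
    def _rec(self, trait, env, chrom="c5", lo=100, hi=200):
        return qm.QTLRecord(
            trait=trait, environment=env, chrom=chrom, pos_cm=1.0,
            left_marker="l", right_marker="r", lod=3.0, pve=5.0,
            additive=-1.0, left_start_bp=lo, right_end_bp=hi)

    def test_three_environments_stable(self):
        recs = [self._rec("PGWC", e) for e in ("G-DS", "Z-DS", "G-WS")]
        qm.classify_stable(recs)
        assert all(r.stable for r in recs)

    def test_two_environments_not_stable(self):
        recs = [self._rec("PGWC", e) for e in ("G-DS", "Z-DS")]
        qm.classify_stable(recs)
        assert not any(r.stable for r in recs)

    def test_disjoint_intervals_not_grouped(self):
        recs = [self._rec("PGWC", "G-DS", lo=100, hi=200),
                self._rec("PGWC", "Z-DS", lo=300, hi=400),
                self._rec("PGWC", "G-WS", lo=500, hi=600)]
        qm.classify_stable(recs)
        assert not any(r.stable for r in recs)
        assert len({r.group_id for r in recs}) == 3

    def test_multi_trait_cluster(self):
        traits = ["CS", "GW", "AS", "PGWC", "DEC"]
        recs = [self._rec(t, "G-DS") for t in traits]
        clusters = qm.cluster_qtls(recs)
        assert len(clusters) == 1
        assert clusters[0].traits == sorted(traits)

    def test_different_chromosomes_separate_clusters(self):
        recs = [self._rec("GW", "G-DS", chrom="c1"),
                self._rec("GW", "G-DS", chrom="c2")]
        assert len(qm.cluster_qtls(recs)) == 2

    def test_chained_overlap_single_linkage(self):
        recs = [self._rec("GW", "G-DS", lo=100, hi=200),
                self._rec("GL", "G-DS", lo=150, hi=300),
                self._rec("CS", "G-DS", lo=250, hi=400)]
        clusters = qm.cluster_qtls(recs)
        assert len(clusters) == 1
        assert clusters[0].start_bp == 100
        assert clusters[0].end_bp == 400
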