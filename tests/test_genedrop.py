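"""Gene dropping: recombination model, Mendelian consistency, replicates."""

import numpy as np
import pytest

from pedimpute.genedrop import (
    GeneticMap,
    drop_haplotypes,
    make_replicates,
    mask_gwas_panel,
    meiosis,
)
from pedimpute.pedigree import Member, Pedigree
from pedimpute.synthetic import HaplotypePool


class TestGeneticMap:
    def test_one_cm_per_mb(self):
        gmap = GeneticMap(np.array([0, 1_000_000, 1_500_000]))
        assert np.allclose(gmap.interval_cm(), [1.0, 0.5])
        assert np.allclose(gmap.recombination_fractions(), [0.01, 0.005])

    def test_theta_clipped_at_half(self):
        gmap = GeneticMap(np.array([0, 100_000_000]))  # 100 cM
        assert gmap.recombination_fractions()[0] == 0.5

    def test_zero_distance_never_recombines(self, rng):
        parent = rng.integers(0, 2, size=(2, 2)).astype(np.uint8)
        thetas = np.array([0.0])
        for _ in range(50):
            gam = meiosis(parent, thetas, rng)
            assert np.array_equal(gam, parent[0]) or np.array_equal(gam, parent[1])


class TestRecombinationRate:
    def test_one_percent_per_cm(self, rng):
        # two distinguishable haplotypes so the template is observable
        parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        thetas = np.array([0.01])  # 1 cM
        n = 100_000
        rec = 0
        for _ in range(n):
            g = meiosis(parent, thetas, rng)
            rec += g[0] != g[1]
        p_hat = rec / n
        ci = 2.576 * np.sqrt(0.01 * 0.99 / n)
        assert abs(p_hat - 0.01) < ci

    def test_linear_in_distance(self, rng):
        # recombinant fraction tracks 0.01/cM over 1-10 cM
        for d_cm in (1.0, 5.0, 10.0):
            theta = np.array([0.01 * d_cm])
            parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)
            n = 20_000
            rec = sum(
                int(g[0] != g[1]) for g in (meiosis(parent, theta, rng)
                                            for _ in range(n))
            )
            assert rec / n == pytest.approx(0.01 * d_cm, rel=0.12)


class TestDropHaplotypes:
    def test_mendelian_consistency(self, small_peds, small_pool):
        truth = drop_haplotypes(small_peds, small_pool, seed=1)
        lut = {s: i for i, s in enumerate(truth.subject_order)}
        for ped in small_peds:
            for m in ped.nonfounders:
                child = truth.haplotypes[lut[m.subject_id]]
                for k, parent in enumerate((m.father_id, m.mother_id)):
                    ph = truth.haplotypes[lut[parent]]
                    # each child haplotype is a site-wise mosaic of the
                    # corresponding parent's two haplotypes
                    ok = (child[k] == ph[0]) | (child[k] == ph[1])
                    assert ok.all()

    def test_founders_sample_pool_without_replacement(self, small_peds, small_pool):
        truth = drop_haplotypes(small_peds, small_pool, seed=2)
        rows = [r for pair in truth.founder_haplotype_labels.values() for r in pair]
        assert len(rows) == len(set(rows))
        n_founders = sum(len(p.founders) for p in small_peds)
        assert len(rows) == 2 * n_founders
        for sid, (r1, r2) in truth.founder_haplotype_labels.items():
            hap = truth.haplotypes[truth.subject_order.index(sid)]
            assert np.array_equal(hap[0], small_pool.haplotypes[r1])
            assert np.array_equal(hap[1], small_pool.haplotypes[r2])

    def test_insufficient_pool_rejected(self, small_peds):
        tiny = HaplotypePool(
            np.array([[0, 1], [1, 0]], dtype=np.uint8), np.array([10, 20])
        )
        with pytest.raises(ValueError, match="pool"):
            drop_haplotypes(small_peds, tiny, seed=0)

    def test_deterministic(self, small_peds, small_pool):
        a = drop_haplotypes(small_peds, small_pool, seed=3)
        b = drop_haplotypes(small_peds, small_pool, seed=3)
        assert np.array_equal(a.haplotypes, b.haplotypes)


class TestPanelAndReplicates:
    def test_panel_size_and_determinism(self, small_peds, small_pool):
        truth = drop_haplotypes(small_peds, small_pool, seed=1)
        ds1 = mask_gwas_panel(truth, small_peds, small_pool.maf(), 40, seed=7)
        ds2 = mask_gwas_panel(truth, small_peds, small_pool.maf(), 40, seed=7)
        assert len(ds1.gwas_snp_ids) == 40
        assert ds1.gwas_snp_ids == ds2.gwas_snp_ids

    def test_panel_boundary(self, small_peds, small_pool):
        truth = drop_haplotypes(small_peds, small_pool, seed=1)
        ds = mask_gwas_panel(truth, small_peds, small_pool.maf(),
                             small_pool.n_snps - 1, seed=0)
        assert len(ds.gwas_snp_ids) == small_pool.n_snps - 1
        with pytest.raises(ValueError):
            mask_gwas_panel(truth, small_peds, small_pool.maf(),
                            small_pool.n_snps, seed=0)

    def test_replicates_independent_and_reproducible(self, small_peds, small_cfg):
        reps = make_replicates(small_peds, small_cfg, 3, base_seed=4)
        assert len(reps) == 3
        sums = {int(r.truth.haplotypes.sum()) for r in reps}
        assert len(sums) == 3  # different pools/drops per replicate
        again = make_replicates(small_peds, small_cfg, 1, base_seed=4)[0]
        assert np.array_equal(again.truth.haplotypes, reps[0].truth.haplotypes)
        assert again.gwas_snp_ids == reps[0].gwas_snp_ids

    def test_allele_frequency_conservation(self, small_peds, small_pool):
        # dropping conserves frequency in expectation: the pedigree-member
        # MAF tracks the frequency among the sampled founder haplotypes
        common = small_pool.maf() > 0.2
        devs = []
        for s in range(20):
            truth = drop_haplotypes(small_peds, small_pool, seed=100 + s)
            rows = [r for pair in truth.founder_haplotype_labels.values()
                    for r in pair]
            f0 = small_pool.haplotypes[rows].mean(axis=0)
            fm = truth.dosages().mean(axis=0) / 2.0
            devs.append(fm - f0)
        mean_dev = np.abs(np.mean(devs, axis=0))[common]
        assert mean_dev.mean() < 0.02
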