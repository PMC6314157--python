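"""Baseline imputers, the hybrid combiner, and external VCF import."""

import numpy as np
import pytest

from pedimpute.genedrop import StudyDataset, drop_haplotypes, mask_gwas_panel
from pedimpute.imputation import (
    ImputationResult,
    combine_ped_pop,
    dosage_to_posteriors,
    estimate_reference_maf,
    import_external_result,
    impute_allele_frequency,
    impute_family_kinship,
    impute_population_ld,
)
from pedimpute.io import write_imputed_vcf
from pedimpute.metrics import dosage_r2
from pedimpute.pedigree import Member, Pedigree
from pedimpute.synthetic import HaplotypePool


def tiny_dataset(pool_matrix, positions, peds, panel_ids, ref_ids, seed=0):
    pool = HaplotypePool(np.asarray(pool_matrix, dtype=np.uint8),
                         np.asarray(positions))
    truth = drop_haplotypes(peds, pool, seed=seed)
    ds = StudyDataset(truth=truth, pedigrees=list(peds), pool_maf=pool.maf(),
                      gwas_snp_ids=set(panel_ids),
                      reference_subject_ids=set(ref_ids))
    return ds


class TestInvariants:
    def test_posterior_simplex_and_dosage_consistency(self, small_dataset):
        for result in (
            impute_allele_frequency(small_dataset),
            impute_family_kinship(small_dataset),
            impute_population_ld(small_dataset, k_flank=5),
        ):
            p = result.posteriors
            assert np.all(p >= -1e-9)
            assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-6)
            assert np.allclose(result.dosages, p[..., 1] + 2 * p[..., 2],
                               atol=1e-6)

    def test_invalid_posteriors_rejected(self):
        bad = np.full((1, 1, 3), 0.5)
        with pytest.raises(ValueError):
            ImputationResult(bad, ["s"], ["snp1"])


class TestAlleleFrequencyBaseline:
    def test_hwe_posteriors(self, small_dataset):
        maf = np.zeros(small_dataset.truth.n_snps)
        res = impute_allele_frequency(small_dataset, ref_mafs=maf)
        off_panel = ~small_dataset.panel_mask
        assert np.allclose(res.posteriors[:, off_panel, 0], 1.0)
        assert np.allclose(res.dosages[:, off_panel], 0.0)

    def test_half_frequency_dosage_one(self, small_dataset):
        maf = np.full(small_dataset.truth.n_snps, 0.5)
        res = impute_allele_frequency(small_dataset, ref_mafs=maf)
        j = int(np.flatnonzero(~small_dataset.panel_mask)[0])
        assert res.dosages[0, j] == pytest.approx(1.0)
        assert res.posteriors[0, j] == pytest.approx([0.25, 0.5, 0.25])

    def test_out_of_range_maf_rejected(self, small_dataset):
        maf = np.full(small_dataset.truth.n_snps, 0.7)
        with pytest.raises(ValueError):
            impute_allele_frequency(small_dataset, ref_mafs=maf)

    def test_constant_predictor_r2_undefined(self, small_dataset):
        res = impute_allele_frequency(small_dataset)
        tgt = small_dataset.truth.subject_index(res.subject_order)
        true_d = small_dataset.truth.dosages()[tgt]
        j = int(np.flatnonzero(~small_dataset.panel_mask)[0])
        assert np.isnan(dosage_r2(true_d[:, j], res.dosages[:, j]))


class TestFamilyKinship:
    def test_identity_relationship_equals_af_baseline(self):
        # all-founder pedigree: A = I, so conditioning adds nothing
        ped = Pedigree("p", [Member(f"s{i}") for i in range(6)])
        rng = np.random.default_rng(0)
        pool = (rng.random((12, 30)) < 0.3).astype(np.uint8)
        flip = pool.mean(axis=0) > 0.5
        pool[:, flip] = 1 - pool[:, flip]
        ds = tiny_dataset(pool, np.arange(30) * 1000 + 1, [ped],
                          panel_ids=["snp1"], ref_ids={"s0", "s1"})
        fam = impute_family_kinship(ds)
        af = impute_allele_frequency(ds)
        assert np.allclose(fam.posteriors, af.posteriors)

    def test_observed_homozygous_parents_give_dosage_two(self, trio):
        # both parents homozygous minor at a site -> child dosage exactly 2
        pool = np.ones((4, 10), dtype=np.uint8)
        pool[:, ::2] = 0
        pool[0, 1] = pool[1, 1] = 1  # keep site polymorphic definitions simple
        ds = tiny_dataset(pool, np.arange(10) * 500 + 1, [trio],
                          panel_ids=["snp1"], ref_ids={"dad", "mum"})
        maf = np.full(10, 0.25)
        res = impute_family_kinship(ds, ref_mafs=maf)
        j = 3  # odd sites are monomorphic-1 in the pool: parents carry 1|1
        kid = res.subject_order.index("kid")
        assert res.dosages[kid, j] == pytest.approx(2.0)

    def test_unrelated_subject_falls_back_to_prior_mean(self):
        peds = [Pedigree("a", [Member("r1"), Member("r2")]),
                Pedigree("b", [Member("u")])]
        rng = np.random.default_rng(1)
        pool = (rng.random((6, 20)) < 0.4).astype(np.uint8)
        flip = pool.mean(axis=0) > 0.5
        pool[:, flip] = 1 - pool[:, flip]
        ds = tiny_dataset(pool, np.arange(20) * 100 + 1, peds,
                          panel_ids=[], ref_ids={"r1", "r2"})
        maf = np.full(20, 0.3)
        res = impute_family_kinship(ds, ref_mafs=maf)
        u = res.subject_order.index("u")
        assert np.allclose(res.dosages[u], 0.6)


class TestPopulationLD:
    def test_duplicated_site_imputed_perfectly(self):
        # target site is an exact copy of a panel site -> R^2 ~ 1
        rng = np.random.default_rng(3)
        n_hap, S = 60, 12
        pool = (rng.random((n_hap, S)) < 0.4).astype(np.uint8)
        pool[:, 5] = pool[:, 4]  # snp6 duplicates snp5
        flip = pool.mean(axis=0) > 0.5
        pool[:, flip] = 1 - pool[:, flip]
        peds = [Pedigree(f"p{k}", [Member(f"f{k}a"), Member(f"f{k}b"),
                                   Member(f"c{k}", f"f{k}a", f"f{k}b")])
                for k in range(8)]
        panel = [f"snp{j}" for j in (1, 3, 5, 8, 10)]
        ref = {f"f{k}a" for k in range(8)} | {f"f{k}b" for k in range(4)}
        ds = tiny_dataset(pool, np.arange(S) * 400 + 1, peds, panel, ref)
        res = impute_population_ld(ds, k_flank=3)
        tgt = ds.truth.subject_index(res.subject_order)
        true_d = ds.truth.dosages()[tgt]
        j = 5  # snp6, duplicate of panel snp5
        if np.ptp(true_d[:, j]) > 0:
            assert dosage_r2(true_d[:, j], res.dosages[:, j]) > 0.99

    def test_requires_reference_subjects(self, small_peds, small_pool):
        truth = drop_haplotypes(small_peds, small_pool, seed=0)
        ds = mask_gwas_panel(truth, small_peds, small_pool.maf(), 40, seed=0)
        with pytest.raises(ValueError, match="reference"):
            impute_population_ld(ds)


class TestPedPopCombiner:
    @pytest.fixture
    def pair(self, small_dataset):
        fam = impute_family_kinship(small_dataset)
        pop = impute_population_ld(small_dataset, k_flank=5)
        return fam, pop

    def test_tau_zero_is_family(self, pair):
        fam, pop = pair
        combo = combine_ped_pop(fam, pop, tau=0.0)
        assert np.allclose(combo.posteriors, fam.posteriors)

    def test_tau_above_one_is_population(self, pair):
        fam, pop = pair
        combo = combine_ped_pop(fam, pop, tau=1.01)
        assert np.allclose(combo.posteriors, pop.posteriors)

    def test_idempotent(self, pair):
        fam, _ = pair
        combo = combine_ped_pop(fam, fam, tau=0.8)
        assert np.allclose(combo.posteriors, fam.posteriors)

    def test_cellwise_threshold_hand_example(self):
        fam_p = np.array([[[0.9, 0.1, 0.0], [0.5, 0.3, 0.2]],
                          [[0.1, 0.8, 0.1], [0.2, 0.3, 0.5]]])
        pop_p = np.array([[[0.2, 0.6, 0.2], [0.1, 0.1, 0.8]],
                          [[0.3, 0.4, 0.3], [0.6, 0.2, 0.2]]])
        fam = ImputationResult(fam_p, ["s1", "s2"], ["m1", "m2"])
        pop = ImputationResult(pop_p, ["s1", "s2"], ["m1", "m2"])
        combo = combine_ped_pop(fam, pop, tau=0.8)
        # cells with max family posterior >= 0.8: (s1,m1) and (s2,m1)
        assert np.allclose(combo.posteriors[0, 0], fam_p[0, 0])
        assert np.allclose(combo.posteriors[1, 0], fam_p[1, 0])
        assert np.allclose(combo.posteriors[0, 1], pop_p[0, 1])
        assert np.allclose(combo.posteriors[1, 1], pop_p[1, 1])
        assert combo.provenance == {"family": 2, "population": 2}

    def test_grid_mismatch_rejected(self, pair):
        fam, pop = pair
        sub = pop.subset_subjects(pop.subject_order[:3])
        with pytest.raises(ValueError, match="grid"):
            combine_ped_pop(fam, sub)


class TestExternalImport:
    def test_round_trip(self, tmp_path, small_dataset):
        res = impute_family_kinship(small_dataset)
        path = tmp_path / "imp.vcf"
        write_imputed_vcf(res, small_dataset.truth.positions_bp, path)
        back = import_external_result(path)
        assert back.subject_order == res.subject_order
        assert back.snp_ids == res.snp_ids
        assert np.allclose(back.dosages, res.dosages, atol=1e-4)

    def test_ds_only_vcf(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="dosage">\n'
            "##contig=<ID=22>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "22\t100\tsnp1\tA\tC\t.\tPASS\t.\tDS\t1.6\t0.2\n"
        )
        path = tmp_path / "ds.vcf"
        path.write_text(vcf)
        res = import_external_result(path)
        assert res.dosages[0, 0] == pytest.approx(1.6, abs=1e-6)
        expected = dosage_to_posteriors(np.array([1.6]))[0]
        assert np.allclose(res.posteriors[0, 0], expected)

    def test_gp_dosage_identity(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GP,Number=G,Type=Float,Description="probs">\n'
            "##contig=<ID=22>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "22\t100\tsnp1\tA\tC\t.\tPASS\t.\tGP\t0.1,0.2,0.7\n"
        )
        path = tmp_path / "gp.vcf"
        path.write_text(vcf)
        res = import_external_result(path)
        assert res.dosages[0, 0] == pytest.approx(1.6, abs=1e-6)

    def test_swapped_alleles_flip_dosage(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GP,Number=G,Type=Float,Description="probs">\n'
            "##contig=<ID=22>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "22\t100\tsnp1\tC\tA\t.\tPASS\t.\tGP\t0.7,0.2,0.1\n"
        )
        path = tmp_path / "swap.vcf"
        path.write_text(vcf)
        res = import_external_result(path, expected_alleles={"snp1": ("A", "C")})
        assert res.dosages[0, 0] == pytest.approx(2.0 - 0.4, abs=1e-6)

    def test_allele_mismatch_and_missing_fields_rejected(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "##contig=<ID=22>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "22\t100\tsnp1\tG\tT\t.\tPASS\t.\tGT\t0|1\n"
        )
        path = tmp_path / "bad.vcf"
        path.write_text(vcf)
        with pytest.raises(ValueError, match="snp1"):
            import_external_result(path, expected_alleles={"snp1": ("A", "C")})
        with pytest.raises(ValueError, match="neither DS nor GP"):
            import_external_result(path)
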