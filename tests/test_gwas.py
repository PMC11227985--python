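"""QC, kinship, structure covariates, mixed-model scan and locus calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spectrait.gwas import (
    GenotypeMatrix,
    GwasResult,
    call_loci,
    compare_leads,
    kinship_matrix,
    mlm_scan,
    read_dosage_csv,
    read_vcf,
    snp_qc,
    structure_covariates,
)
from spectrait.simulate import TraitGenetics, simulate_genotypes_with_trait


def geno_from(dosages, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    n_snp = dosages.shape[1]
    pos = positions if positions is not None else (np.arange(n_snp) + 1) * 10_000
    snp_map = pd.DataFrame({
        "chrom": [chrom] * n_snp, "pos": pos,
        "id": [f"SNP{chrom}.{p}" for p in pos],
    })
    return GenotypeMatrix(dosages, snp_map)


class TestQc:
    def test_monomorphic_and_low_call_removed(self):
        d = np.array([
            [0, 2, 1, np.nan],
            [0, 1, 1, np.nan],
            [0, 0, 2, 1],
            [0, 2, 1, 1],
            [0, 1, 0, 1],
            [0, 2, 2, 1],
            [0, 0, 1, 1],
            [0, 1, 0, 1],
            [0, 2, 1, 1],
            [0, 1, 2, 1],
        ])
        # SNP0 monomorphic; SNP3 call rate 0.8 < 0.9
        kept, report = snp_qc(geno_from(d))
        assert list(kept.snp_map["id"]) == ["SNP1.20000", "SNP1.30000"]
        assert report["n_retained"] == 2

    def test_matches_bruteforce_rule(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(40, 5)).astype(float)
        d[rng.random(d.shape) < 0.1] = np.nan
        kept, _ = snp_qc(geno_from(d), maf_min=0.1, call_min=0.85)
        expect = []
        for j in range(5):
            col = d[:, j]
            ok = ~np.isnan(col)
            call = ok.mean()
            p = col[ok].mean() / 2
            maf = min(p, 1 - p)
            expect.append(maf > 0.1 and call > 0.85)
        assert kept.n_snps == sum(expect)

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(30, 8)).astype(float)
        once, _ = snp_qc(geno_from(d))
        twice, _ = snp_qc(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_all_removed_raises(self):
        with pytest.raises(ValueError):
            snp_qc(geno_from(np.zeros((5, 3))))


class TestKinship:
    def test_duplicated_individuals_share_entries(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(6, 20)).astype(float)
        d[3] = d[0]
        K = kinship_matrix(geno_from(d))
        assert K[0, 0] == pytest.approx(K[0, 3])
        assert K[0, 3] == pytest.approx(K[3, 3])

    def test_symmetry_and_hand_computation(self):
        d = np.array([[0.0, 2.0, 1.0, 0.0],
                      [1.0, 1.0, 2.0, 0.0],
                      [2.0, 0.0, 0.0, 2.0]])
        K = kinship_matrix(geno_from(d))
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        p = d.mean(axis=0) / 2
        Z = d - 2 * p
        expected = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_monomorphic_only_raises(self):
        with pytest.raises(ValueError):
            kinship_matrix(geno_from(np.full((4, 3), 2.0)))


class TestStructureCovariates:
    def test_two_populations_separate_on_pc1(self):
        # direct construction: strongly diverged allele frequencies
        rng = np.random.default_rng(5)
        pop = np.repeat([0, 1], 60)
        freq = np.stack([rng.uniform(0.05, 0.25, 200),
                         rng.uniform(0.75, 0.95, 200)])
        d = rng.binomial(2, freq[pop]).astype(float)
        Q = structure_covariates(geno_from(d), 2)
        lo = Q[pop == 0, 0]
        hi = Q[pop == 1, 0]
        if lo.mean() > hi.mean():
            lo, hi = hi, lo
        assert lo.max() < hi.min()      # no overlap

    def test_orthogonal_columns_and_deterministic_sign(self):
        geno, _, _ = simulate_genotypes_with_trait(80, 200, seed=6)
        Q1 = structure_covariates(geno, 3)
        Q2 = structure_covariates(geno, 3)
        np.testing.assert_array_equal(Q1, Q2)
        gram = Q1.T @ Q1
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_q_too_large(self):
        geno, _, _ = simulate_genotypes_with_trait(10, 50, seed=7)
        with pytest.raises(ValueError):
            structure_covariates(geno, 10)


class TestMlmScan:
    def test_identity_kinship_reduces_to_ols(self):
        geno, gpc, _ = simulate_genotypes_with_trait(100, 60, seed=8)
        res = mlm_scan(gpc, geno, Q=None, K=np.eye(100))
        for j in [0, 17, 44]:
            d = geno.dosages[:, j]
            if d.std() == 0:
                continue
            ols = stats.linregress(d, gpc)
            assert res.table.loc[j, "p"] == pytest.approx(ols.pvalue, abs=1e-6)

    def test_permuted_phenotype_gives_uniform_pvalues(self):
        geno, gpc, _ = simulate_genotypes_with_trait(150, 200, seed=9)
        rng = np.random.default_rng(10)
        res = mlm_scan(rng.permutation(gpc), geno,
                       Q=structure_covariates(geno, 1))
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_smallest_p_at_causal_snp(self):
        hits = 0
        for seed in range(10):
            geno, gpc, truth = simulate_genotypes_with_trait(
                200, 100, TraitGenetics(h2=0.25), seed=seed)
            res = mlm_scan(gpc, geno, Q=structure_covariates(geno, 1), loco=True)
            top = res.table.loc[res.table["p"].idxmin(), "id"]
            block_ids = set(truth["causal_ids"])
            hits += top in block_ids
        assert hits >= 9

    def test_invariance_to_column_order_and_phenotype_shift(self):
        geno, gpc, _ = simulate_genotypes_with_trait(80, 40, seed=11)
        K = kinship_matrix(geno)
        base = mlm_scan(gpc, geno, K=K).table["p"].to_numpy()
        shifted = mlm_scan(gpc + 100.0, geno, K=K).table["p"].to_numpy()
        np.testing.assert_allclose(base, shifted, rtol=1e-6)
        # reversing SNP order within a chromosome-agnostic map changes only
        # the row order of the result, not any per-SNP p-value
        perm = np.arange(geno.n_snps)[::-1]
        snp_map_p = geno.snp_map.iloc[perm].reset_index(drop=True).copy()
        snp_map_p["pos"] = geno.snp_map["pos"].to_numpy()  # keep map sorted
        geno_p = GenotypeMatrix(geno.dosages[:, perm], snp_map_p)
        res_p = mlm_scan(gpc, geno_p, K=K).table.set_index("id")["p"]
        res_b = mlm_scan(gpc, geno, K=K).table.set_index("id")["p"]
        np.testing.assert_allclose(res_p[res_b.index].to_numpy(),
                                   res_b.to_numpy(), rtol=1e-6)


class TestLociAndLeads:
    def _result(self, neglog, positions, chrom="1"):
        tab = pd.DataFrame({
            "chrom": [chrom] * len(neglog),
            "pos": positions,
            "id": [f"SNP{chrom}.{p}" for p in positions],
            "beta": 0.1, "se": 0.1,
            "p": 10.0 ** (-np.asarray(neglog, dtype=float)),
            "neglog10p": neglog,
        })
        return GwasResult(table=tab, threshold_neglog10=4.0)

    def test_no_significant_snps_no_loci(self):
        res = call_loci(self._result([1, 2, 3], [1000, 2000, 3000]))
        assert res.loci == []
        assert res.lead_snps.empty

    def test_four_consecutive_selects_minimum_p(self):
        res = call_loci(self._result(
            [5, 7, 6, 5], [10_000, 20_000, 30_000, 40_000]))
        assert len(res.loci) == 1
        assert res.loci[0]["lead"] == "SNP1.20000"
        assert list(res.lead_snps["id"]) == ["SNP1.20000"]

    def test_three_significant_yield_locus_without_lead(self):
        res = call_loci(self._result([5, 6, 5], [10_000, 20_000, 30_000]))
        assert len(res.loci) == 1
        assert res.loci[0]["lead"] is None
        assert res.lead_snps.empty

    def test_runs_300kb_apart_split_into_two_loci(self):
        neglog = [5, 5, 5, 5, 6, 6, 6, 6]
        pos = [10_000, 20_000, 30_000, 40_000,
               340_000, 350_000, 360_000, 370_000]
        res = call_loci(self._result(neglog, pos))
        assert len(res.loci) == 2
        assert len(res.lead_snps) == 2

    def test_strict_adjacency_option(self):
        # significant run interrupted by a non-significant SNP in map order
        neglog = [5, 5, 1, 5, 5]
        pos = [10_000, 20_000, 30_000, 40_000, 50_000]
        loose = call_loci(self._result(neglog, pos), min_run=4)
        assert len(loose.lead_snps) == 1
        strict = call_loci(self._result(neglog, pos), min_run=4,
                           strict_map_adjacency=True)
        assert strict.lead_snps.empty


class TestCompareLeads:
    def _leads(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "id", "p", "neglog10p"])

    def test_identical_lists_all_shared(self):
        a = self._leads([("1", 100_000, "A", 1e-6, 6.0), ("2", 5_000_000, "B", 1e-7, 7.0)])
        shared = compare_leads(a, a.copy())
        assert len(shared) == 2
        assert (shared["distance_bp"] == 0).all()

    def test_window_boundary(self):
        a = self._leads([("1", 1_000_000, "A", 1e-6, 6.0)])
        near = self._leads([("1", 1_099_000, "B", 1e-5, 5.0)])
        far = self._leads([("1", 1_101_000, "C", 1e-5, 5.0)])
        assert len(compare_leads(a, near, 100.0)) == 1
        assert len(compare_leads(a, far, 100.0)) == 0

    def test_empty_list_shares_nothing(self):
        a = self._leads([("1", 100, "A", 1e-6, 6.0)])
        assert compare_leads(a, a.iloc[:0]).empty

    def test_one_to_one_greedy_matching(self):
        a = self._leads([("1", 1_000_000, "A", 1e-6, 6.0)])
        b = self._leads([("1", 1_010_000, "B1", 1e-5, 5.0),
                         ("1", 1_020_000, "B2", 1e-5, 5.0)])
        shared = compare_leads(a, b, 100.0)
        assert len(shared) == 1
        assert shared.loc[0, "id_b"] == "B1"     # nearest wins


class TestIo:
    def test_vcf_reader(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\tsnp2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1\n"
        )
        geno = read_vcf(vcf)
        assert geno.sample_ids == ["S1", "S2", "S3"]
        np.testing.assert_array_equal(geno.dosages[:, 0], [0, 1, 2])
        assert np.isnan(geno.dosages[0, 1])
        np.testing.assert_array_equal(geno.dosages[1:, 1], [0, 1])

    def test_dosage_csv_round_trip(self, tmp_path):
        geno, _, _ = simulate_genotypes_with_trait(10, 8, seed=13)
        pd.DataFrame(geno.dosages, index=geno.sample_ids).to_csv(tmp_path / "d.csv")
        geno.snp_map.to_csv(tmp_path / "m.csv", index=False)
        back = read_dosage_csv(tmp_path / "d.csv", tmp_path / "m.csv")
        np.testing.assert_array_equal(back.dosages, geno.dosages)
        assert list(back.snp_map["id"]) == list(geno.snp_map["id"])
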