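"""QC, allelic chi-square scan, inflation factor and file dialects."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, chi2_contingency

from dlakit.gwas_lite import (
    CHI2_1_MEDIAN,
    SnpDataset,
    allelic_scan,
    allelic_test,
    genomic_inflation,
    gwas_run,
    qc_filter,
    read_genotype_tables,
    read_ped_map,
    write_genotype_tables,
)


def make_dataset(genotypes, affected, chrom=None):
    genotypes = np.asarray(genotypes, dtype=float)
    n_snps = genotypes.shape[1]
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n_snps)],
            "chromosome": chrom or ["1"] * n_snps,
            "position_bp": list(range(100, 100 + n_snps)),
        }
    )
    ids = [f"x{i}" for i in range(genotypes.shape[0])]
    return SnpDataset(ids, np.asarray(affected, dtype=bool), snps, genotypes)


class TestQcFilter:
    def test_low_call_rate_removed(self):
        g = np.ones((10, 2))
        g[:, 1] = 1.0
        g[0:2, 0] = np.nan  # 80% call rate
        d = make_dataset(g, [True] * 5 + [False] * 5)
        kept = qc_filter(d, min_call_rate=0.90, min_maf=0.0)
        assert list(kept.snps["snp_id"]) == ["s1"]

    def test_monomorphic_removed_and_boundary_maf_kept(self):
        # SNP 0: monomorphic. SNP 1: MAF exactly 0.05 (1 copy / 20 alleles
        # would be 0.05 with 10 samples).  SNP 2: common.
        g = np.zeros((10, 3))
        g[0, 1] = 1.0  # 1/20 = 0.05
        g[:5, 2] = 1.0
        d = make_dataset(g, [True] * 5 + [False] * 5)
        kept = qc_filter(d, min_maf=0.05)
        assert list(kept.snps["snp_id"]) == ["s1", "s2"]

    def test_maf_folded_to_minor_side(self):
        g = np.full((10, 1), 2.0)
        g[0, 0] = 1.0  # allele frequency 0.95 -> MAF 0.05
        d = make_dataset(g, [True] * 5 + [False] * 5)
        assert len(qc_filter(d, min_maf=0.05).snps) == 1

    def test_removing_everything_is_not_an_error(self):
        d = make_dataset(np.zeros((4, 2)), [True, True, False, False])
        assert qc_filter(d).n_snps == 0


class TestAllelicTest:
    def test_fully_separated_cohorts(self):
        # 5 cases all dosage 2, 5 controls all 0 -> table (10,0,0,10).
        dosages = np.array([2.0] * 5 + [0.0] * 5)
        affected = np.array([True] * 5 + [False] * 5)
        stat, p = allelic_test(dosages, affected)
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(chi2.sf(20, 1), rel=1e-9)
        assert p == pytest.approx(7.7e-6, rel=0.01)

    def test_identical_cohorts_give_null(self):
        dosages = np.array([1.0, 0.0, 1.0, 0.0])
        stat, p = allelic_test(dosages, np.array([True, True, False, False]))
        assert stat == 0.0 and p == 1.0

    def test_degenerate_margin(self):
        stat, p = allelic_test(
            np.zeros(6), np.array([True] * 3 + [False] * 3)
        )
        assert (stat, p) == (0.0, 1.0)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(42)
        affected = rng.random(40) < 0.5
        for _ in range(20):
            dosages = rng.binomial(2, rng.uniform(0.1, 0.5), size=40).astype(float)
            dosages[rng.random(40) < 0.1] = np.nan
            stat, p = allelic_test(dosages, affected)
            ok = ~np.isnan(dosages)
            a = dosages[ok & affected].sum()
            b = 2 * (ok & affected).sum() - a
            c = dosages[ok & ~affected].sum()
            d = 2 * (ok & ~affected).sum() - c
            table = np.array([[a, b], [c, d]])
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                assert (stat, p) == (0.0, 1.0)
                continue
            expect, pexp, _, _ = chi2_contingency(table, correction=False)
            assert stat == pytest.approx(expect, rel=1e-9)
            assert p == pytest.approx(pexp, rel=1e-9)

    def test_vectorised_scan_matches_scalar_test(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.3, size=(30, 25)).astype(float)
        g[rng.random(g.shape) < 0.05] = np.nan
        affected = rng.random(30) < 0.5
        d = make_dataset(g, affected)
        scan = allelic_scan(d)
        for j in range(25):
            stat, p = allelic_test(g[:, j], affected)
            assert scan["chisq"][j] == pytest.approx(stat, abs=1e-10)
            assert scan["p_raw"][j] == pytest.approx(p, abs=1e-12)


class TestGenomicInflation:
    def test_definitional_value(self):
        assert genomic_inflation([CHI2_1_MEDIAN] * 5) == pytest.approx(1.0)

    def test_median_homogeneity(self):
        stats = [0.1, 0.4, 0.9, 2.0, 5.0]
        assert genomic_inflation([2 * s for s in stats]) == pytest.approx(
            2 * genomic_inflation(stats)
        )

    def test_null_chi_square_sample_is_calibrated(self):
        rng = np.random.default_rng(0)
        sample = rng.chisquare(1, size=100_000)
        assert 0.98 <= genomic_inflation(sample) <= 1.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([])


class TestGwasRun:
    def test_single_snp_bonferroni_is_identity(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, size=(20, 1)).astype(float)
        d = make_dataset(g, [True] * 10 + [False] * 10)
        results, summary, _, _ = gwas_run(d)
        assert summary.n_snps_after_qc == 1
        assert results["p_bonferroni"][0] == pytest.approx(results["p_raw"][0])

    def test_bonferroni_preserves_ranking_and_caps_at_one(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, size=(30, 40)).astype(float)
        d = make_dataset(g, [True] * 15 + [False] * 15)
        results, summary, manhattan, qq = gwas_run(d)
        assert (results["p_bonferroni"] <= 1).all()
        assert results["p_raw"].is_monotonic_increasing
        assert results["p_bonferroni"].is_monotonic_increasing
        assert list(manhattan.columns) == [
            "snp_id", "chromosome", "position_bp", "neg_log10_p"
        ]
        assert len(qq) == summary.n_snps_after_qc


class TestReaders:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, size=(8, 5)).astype(float)
        g[0, 0] = np.nan
        d = make_dataset(g, [True] * 4 + [False] * 4)
        write_genotype_tables(d, tmp_path / "g.tsv", tmp_path / "m.tsv")
        back = read_genotype_tables(tmp_path / "g.tsv", tmp_path / "m.tsv")
        np.testing.assert_array_equal(back.affected, d.affected)
        np.testing.assert_array_equal(back.genotypes, d.genotypes)
        pd.testing.assert_frame_equal(
            back.snps, d.snps, check_dtype=False
        )

    def test_ped_map_dosages_count_minor_allele(self, tmp_path):
        (tmp_path / "t.map").write_text(
            "1 s1 0 100\n1 s2 0 200\n"
        )
        # s1: A is minor (3 of 8); s2 has a missing genotype for d3.
        (tmp_path / "t.ped").write_text(
            "f d1 0 0 1 2 A A G G\n"
            "f d2 0 0 1 2 A G G G\n"
            "f d3 0 0 1 1 G G 0 0\n"
            "f d4 0 0 1 1 G G G T\n"
        )
        d = read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")
        assert d.sample_ids == ["d1", "d2", "d3", "d4"]
        np.testing.assert_array_equal(d.affected, [True, True, False, False])
        np.testing.assert_array_equal(d.genotypes[:, 0], [2, 1, 0, 0])
        expected = np.array([0.0, 0.0, np.nan, 1.0])
        np.testing.assert_array_equal(d.genotypes[:, 1], expected)

    def test_ped_with_wrong_field_count_rejected(self, tmp_path):
        (tmp_path / "t.map").write_text("1 s1 0 100\n")
        (tmp_path / "t.ped").write_text("f d1 0 0 1 2 A\n")
        with pytest.raises(ValueError, match="allele fields"):
            read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")
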