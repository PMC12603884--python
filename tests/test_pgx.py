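"""SNP screening: MAF/HWE filter and additive regression step."""

import numpy as np
import pandas as pd
import pytest

from sedpkpd import pgx, trial


def _frame(*cols):
    d = {"ID": np.arange(1, len(cols[0][1]) + 1)}
    d.update({name: vals for name, vals in cols})
    return pd.DataFrame(d)


class TestMafHwe:
    def test_monomorphic_excluded_with_zero_maf(self):
        g = _frame(("snp1", np.zeros(40)))
        kept, tab = pgx.maf_hwe_filter(g)
        assert tab.loc["snp1", "maf"] == 0.0
        assert not tab.loc["snp1", "pass_maf"]
        assert list(kept.columns) == ["ID"]

    def test_exact_hwe_proportions_give_zero_chi2(self):
        g = np.repeat([0, 1, 2], [25, 50, 25]).astype(float)
        chi2, p = pgx.hwe_chisq(g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_worked_chi_square_example(self):
        # counts (30,40,30) vs HWE expectation (25,50,25): 1 + 2 + 1 = 4
        g = np.repeat([0, 1, 2], [30, 40, 30]).astype(float)
        chi2, p = pgx.hwe_chisq(g)
        assert chi2 == pytest.approx(4.0, rel=1e-12)
        assert p < 0.05

    def test_maf_folds_major_allele(self):
        g = np.repeat([0, 1, 2], [2, 6, 42]).astype(float)
        assert pgx.minor_allele_frequency(g) == pytest.approx(0.1)


class TestScreen:
    def test_bonferroni_threshold(self):
        # ten SNPs in exact Hardy-Weinberg proportions all survive step 1,
        # so the selection threshold is 0.2/10
        rng = np.random.default_rng(0)
        base = np.repeat([0, 1, 2], [15, 30, 15]).astype(float)
        g = _frame(*[(f"snp{i+1}", rng.permutation(base)) for i in range(10)])
        res = pgx.screen_snps(rng.normal(size=60), g)
        assert res.bonferroni_threshold == pytest.approx(0.2 / 10)

    def test_strong_effect_detected_in_most_replicates(self):
        hits = 0
        for seed in range(10):
            g, mult = trial.generate_genotypes(
                50, 8, maf=0.3, seed=seed, effect_snp=2,
                effect_per_allele=np.log(2.0))  # 2-fold CL per allele
            rng = np.random.default_rng(seed + 100)
            log_cl = np.log(5.0) + np.log(mult) + rng.normal(0, 0.3, 50)
            res = pgx.screen_snps(log_cl, g)
            hits += "snp3" in res.selected
        assert hits >= 8

    def test_null_familywise_rate_bounded(self):
        any_hit = 0
        for seed in range(20):
            g, _ = trial.generate_genotypes(50, 10, maf=0.3, seed=seed + 40)
            rng = np.random.default_rng(seed + 999)
            res = pgx.screen_snps(rng.normal(size=50), g)
            any_hit += bool(res.selected)
        # family-wise selection controlled near 0.2
        assert any_hit <= 9

    def test_allele_relabel_flips_sign_only(self):
        g, _ = trial.generate_genotypes(60, 1, maf=0.4, seed=5)
        rng = np.random.default_rng(6)
        y = rng.normal(size=60)
        r1 = pgx.screen_snps(y, g)
        g2 = g.copy()
        g2["snp1"] = 2.0 - g2["snp1"]
        r2 = pgx.screen_snps(y, g2)
        assert r1.table.loc["snp1", "p_value"] == pytest.approx(
            r2.table.loc["snp1", "p_value"], rel=1e-9)
        assert r1.table.loc["snp1", "beta"] == pytest.approx(
            -r2.table.loc["snp1", "beta"], rel=1e-9)
        assert r1.table.loc["snp1", "maf"] == pytest.approx(
            r2.table.loc["snp1", "maf"], rel=1e-12)

    def test_grouped_covariate_two_categories(self):
        g, _ = trial.generate_genotypes(80, 1, maf=0.4, seed=2)
        cov = pgx.grouped_covariate(g, "snp1")
        assert set(cov.unique()) <= {0.0, 1.0}

    def test_missing_genotypes_complete_case(self):
        g, _ = trial.generate_genotypes(60, 2, maf=0.4, seed=3,
                                        missing_rate=0.1)
        rng = np.random.default_rng(4)
        res = pgx.screen_snps(rng.normal(size=60), g)
        assert np.isfinite(res.table["p_value"].astype(float)).all()

    def test_empty_screen_warns(self):
        g = _frame(("snp1", np.zeros(30)))
        with pytest.warns(UserWarning, match="no SNPs"):
            res = pgx.screen_snps(np.random.default_rng(0).normal(size=30), g)
        assert res.selected == []
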