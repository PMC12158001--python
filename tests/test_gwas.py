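"""Phenotype preparation, REML, LOCO scan, inflation and FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from gsorpipe import gwas as gw
from gsorpipe.core import compute_grm
from gsorpipe.lmm import ConvergenceError, eigen_grm, gls_fixed_effects, reml_fit
from gsorpipe.simulate import SimConfig, simulate_genotypes

from conftest import make_panel


class TestRemoveOutliers:
    def test_single_extreme_point_removed(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(100)
        y[7] = 6 * y.std() + y.mean()
        out, n = gw.remove_outliers(pd.Series(y), k=4)
        assert n == 1 and np.isnan(out.iloc[7])

    def test_constant_vector_removes_nothing(self):
        out, n = gw.remove_outliers(pd.Series([3.0] * 10), k=4)
        assert n == 0 and out.notna().all()

    def test_single_pass_hand_constructed_pair(self):
        # 18 tight values plus two planted at +-4.5 SD of those 18; against
        # the full 20-value moments the pair sits at ~2.58 SD (hand result:
        # sd20 = sd18*sqrt((17 + 2*4.5^2)/19)), so both go at k=2.5 in one pass
        base = np.array([-0.85, -0.75, -0.55, -0.35, -0.15, 0.15, 0.35, 0.55, 0.75, 0.85] * 2)[:18]
        sd18 = base.std(ddof=1)
        y = np.concatenate([base, [4.5 * sd18, -4.5 * sd18]])
        ratio = 4.5 * sd18 / y.std(ddof=1)
        assert 2.5 < ratio < 2.7
        out, n = gw.remove_outliers(pd.Series(y), k=2.5)
        assert n == 2
        assert np.isnan(out.iloc[-1]) and np.isnan(out.iloc[-2])
        # single pass: the survivors are NOT re-screened against their own SD
        assert out.iloc[:18].notna().all()

    def test_missing_values_ignored_in_moments(self):
        y = pd.Series([1.0, 2.0, 3.0, np.nan, 100.0])
        out, n = gw.remove_outliers(y, k=1.4)
        assert n == 1 and np.isnan(out.iloc[4])
        assert np.isnan(out.iloc[3])  # missing stays missing, not counted


class TestAdjustCovariates:
    def test_intercept_only_centers(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        res = gw.adjust_covariates(y, np.ones((4, 1)))
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-12)

    def test_batch_shift_recovered(self):
        rng = np.random.default_rng(1)
        y0 = rng.standard_normal(40)
        shift = np.repeat([0.0, 10.0], 20)
        X = np.column_stack([np.ones(40), shift / 10.0])
        res = gw.adjust_covariates(y0 + shift, X)
        expected = gw.adjust_covariates(y0, X)
        np.testing.assert_allclose(res, expected, atol=1e-8)

    def test_nine_level_factor_residual_means_zero(self):
        rng = np.random.default_rng(2)
        levels = rng.integers(0, 9, size=180)
        effects = rng.normal(0, 3, size=9)
        y = effects[levels] + rng.standard_normal(180)
        X = gw.build_design(
            pd.DataFrame({"batch": [f"b{l}" for l in levels]}), ["batch"]
        )
        res = gw.adjust_covariates(y, X)
        for l in range(9):
            assert abs(res[levels == l].mean()) < 1e-10

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0) * 2])
        with pytest.raises(ValueError, match="aliased"):
            gw.adjust_covariates(np.random.default_rng(3).standard_normal(20), X)


def polygenic_trait(grm_matrix, h2, rng):
    """Draw y with exact variance-ratio h2 under the GRM covariance."""
    n = grm_matrix.shape[0]
    eig = eigen_grm(grm_matrix)
    g = eig.vectors @ (np.sqrt(eig.values) * rng.standard_normal(n))
    e = rng.standard_normal(n)
    g = g / g.std(ddof=1)
    e = e / e.std(ddof=1)
    return np.sqrt(h2) * g + np.sqrt(1 - h2) * e


@pytest.fixture(scope="module")
def grm_500():
    cfg = SimConfig(n_variants_per_chrom=700)
    rng = np.random.default_rng(42)
    g = simulate_genotypes(cfg, 500, rng)
    return compute_grm(g)


class TestREML:
    def test_recovers_h2_half_within_2se(self, grm_500):
        misses = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = polygenic_trait(grm_500.matrix, 0.5, rng)
            vc = reml_fit(y, grm_500.matrix)
            if abs(vc.h2 - 0.5) > 2 * vc.se_h2:
                misses += 1
        assert misses <= 1  # ~95% coverage leaves room for one excursion

    def test_null_trait_estimates_near_zero(self, grm_500):
        low = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            y = rng.standard_normal(500)
            vc = reml_fit(y, grm_500.matrix)
            low += vc.h2 <= 0.15
        assert low >= 9

    def test_invariant_under_joint_permutation(self, grm_500):
        rng = np.random.default_rng(7)
        y = polygenic_trait(grm_500.matrix, 0.4, rng)
        vc = reml_fit(y, grm_500.matrix)
        perm = rng.permutation(500)
        vc_p = reml_fit(y[perm], grm_500.matrix[np.ix_(perm, perm)])
        assert vc_p.h2 == pytest.approx(vc.h2, abs=1e-5)

    def test_identity_grm_not_identifiable(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ConvergenceError, match="identifiable"):
            reml_fit(rng.standard_normal(60), np.eye(60))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >="):
            reml_fit(np.zeros(10), np.eye(10))


@pytest.fixture(scope="module")
def tiny():
    cfg = SimConfig(
        n_variants_per_chrom=20,
        chrom_spec=(("1", 200_000), ("2", 200_000), ("3", 200_000)),
    )
    rng = np.random.default_rng(9)
    g = simulate_genotypes(cfg, 50, rng)
    keep = g.dosages.std(axis=0) > 0
    g = g.subset_variants(keep)
    y = polygenic_trait(compute_grm(g).matrix, 0.5, rng)
    return g, y


class TestLocoScan:
    def test_matches_dense_gls_oracle(self, tiny):
        g, y = tiny
        scan = gw.mlm_loco_scan(g, y)
        chroms = g.variants["chrom"].to_numpy()
        for c in pd.unique(chroms):
            grm_c = compute_grm(g.subset_variants(chroms != c))
            vc = reml_fit(y, grm_c.matrix)
            V = vc.sigma_g2 * grm_c.matrix + vc.sigma_e2 * np.eye(len(y))
            Vinv = np.linalg.inv(V)
            for j in np.flatnonzero(chroms == c):
                X = np.column_stack([np.ones(len(y)), g.dosages[:, j]])
                cov = np.linalg.inv(X.T @ Vinv @ X)
                beta = cov @ (X.T @ Vinv @ y)
                row = scan[scan["id"] == g.variants.iloc[j]["id"]].iloc[0]
                assert row["beta"] == pytest.approx(beta[1], rel=1e-8)
                assert row["se"] == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-8)

    def test_zero_genetic_variance_limit_is_ols(self, tiny):
        g, y = tiny
        eig = eigen_grm(compute_grm(g).matrix)
        j = 5
        X = np.column_stack([np.ones(len(y)), g.dosages[:, j]])
        beta, se = gls_fixed_effects(y, X, eig, 0.0, 1.0)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, ols, rtol=1e-10)

    def test_planted_qtl_is_chromosome_minimum(self):
        cfg = SimConfig(n_variants_per_chrom=600)
        rng = np.random.default_rng(10)
        g = simulate_genotypes(cfg, 400, rng)
        g = g.subset_variants(g.maf() >= 0.05)
        maf = g.maf()
        j = int(np.argmin(np.abs(maf - 0.4)))
        x = g.dosages[:, j]
        beta = np.sqrt(0.10 / (x.var() * 0.90))  # QTL explains 10% of variance
        y = beta * x + rng.standard_normal(400)
        scan = gw.mlm_loco_scan(g, y)
        row = scan[scan["id"] == g.variants.iloc[j]["id"]].iloc[0]
        assert row["p"] < 1e-6
        same_chrom = scan[scan["chrom"] == g.variants.iloc[j]["chrom"]]
        assert row["p"] == same_chrom["p"].min()

    def test_single_chromosome_rejected(self):
        rng = np.random.default_rng(11)
        g = make_panel(rng.integers(0, 3, size=(40, 10)).astype(float))
        with pytest.raises(ValueError, match="2 chrom"):
            gw.mlm_loco_scan(g, rng.standard_normal(40))


class TestFDRControl:
    def test_null_traits_rarely_yield_discoveries(self):
        # BH at q <= 0.10: the fraction of null traits with any discovery
        # should be at most ~10% (binomial slack over 20 traits)
        from gsorpipe.core import qc_filter_variants
        from gsorpipe.simulate import SimConfig, simulate_genotypes

        cfg = SimConfig(n_variants_per_chrom=300)
        rng = np.random.default_rng(0)
        g = qc_filter_variants(simulate_genotypes(cfg, 300, rng))
        n_disc = 0
        for _ in range(20):
            y = rng.standard_normal(300)
            scan = gw.mlm_loco_scan(g, y)
            n_disc += int((scan["q"].dropna() <= 0.10).any())
        assert n_disc <= 4


class TestGenomicInflation:
    def test_all_half_gives_unity(self):
        assert gw.genomic_inflation(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_uniform_pvalues_near_unity(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, size=100_000)
        p = np.clip(p, 1e-12, 1.0)
        assert gw.genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_linear_in_median_chi2(self):
        rng = np.random.default_rng(13)
        stats = rng.chisquare(1, size=5001)
        p = chi2.sf(stats, 1)
        p_half = chi2.sf(stats / 2.0, 1)
        lam = gw.genomic_inflation(p)
        assert gw.genomic_inflation(p_half) == pytest.approx(lam / 2, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gw.genomic_inflation(np.array([]))


class TestBH:
    def test_single_p_unchanged(self):
        assert gw.bh_adjust(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            gw.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_matches_manual_stepup_and_is_monotone(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(0, 1, size=57)
        q = gw.bh_adjust(p)
        order = np.argsort(p)
        m = len(p)
        manual = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(q[order], np.minimum(manual, 1.0), rtol=1e-12)
        assert (np.diff(q[order]) >= -1e-15).all()
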