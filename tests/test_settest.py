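import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longgxe.regions import GenotypeMatrix
from longgxe.settest import (
    POOLED_SHRINKAGE,
    bspline_basis,
    fit_null_model,
    interaction_set_test,
    marginal_set_test,
    standardize_genotypes,
    weighted_pca_adjustment,
)
from longgxe.simulate import RegionSpec, hrs_ea_like, simulate_cohort, simulate_genotypes


def simulate_once(seed, n=400, p=20, rho=0.5, **overrides):
    cfg = hrs_ea_like(
        n_subjects=n, region=RegionSpec(p=p, rho=rho), **overrides
    )
    gen = np.random.default_rng(seed)
    gm = simulate_genotypes(n, cfg.region, gen)
    table = simulate_cohort(cfg, gm, gen)
    return cfg, gm, table


def interaction_pvalue(gm, table, **kwargs):
    block, _, _ = standardize_genotypes(gm)
    adjustment = weighted_pca_adjustment(block)
    null = fit_null_model(
        table,
        "Y",
        ["age", "age2", "sex"],
        exposure="E",
        genotype_adjustment=adjustment,
        adjustment_subjects=gm.subjects,
    )
    return interaction_set_test(
        null, block, table["E"].to_numpy(), block_subjects=gm.subjects, **kwargs
    )


class TestStandardize:
    def test_centering(self):
        block, ids, _ = standardize_genotypes(
            np.array([[0.0], [1.0], [2.0]]), scale=False
        )
        np.testing.assert_allclose(block[:, 0], [-1.0, 0.0, 1.0])

    def test_unit_scale_default(self):
        block, _, _ = standardize_genotypes(np.array([[0.0], [1.0], [2.0]]))
        assert block[:, 0].std(ddof=0) == pytest.approx(1.0)

    def test_imputed_constant_dropped(self):
        with pytest.warns(UserWarning, match="zero variance"):
            block, ids, imputed = standardize_genotypes(
                np.array([[1.0], [np.nan], [1.0]])
            )
        assert ids == []
        assert imputed == {"v0": 1}

    def test_mean_imputation_counted(self):
        block, ids, imputed = standardize_genotypes(
            np.array([[0.0, 0.0], [np.nan, 1.0], [2.0, 2.0]])
        )
        assert imputed == {"v0": 1}
        assert block.shape == (3, 2)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="all dosages missing"):
            standardize_genotypes(np.array([[np.nan], [np.nan]]))

    def test_flip_negates_centered_column(self):
        raw = np.array([[0.0], [1.0], [2.0], [1.0]])
        a, _, _ = standardize_genotypes(raw)
        b, _, _ = standardize_genotypes(2.0 - raw)
        np.testing.assert_allclose(a, -b)


class TestWeightedPca:
    def test_revert_for_small_p(self, rng):
        block = rng.normal(size=(100, 5))
        out = weighted_pca_adjustment(block, p_max=50)
        np.testing.assert_array_equal(out, block)

    def test_rank_one_gives_single_component(self, rng):
        col = rng.normal(size=200)
        block = np.column_stack([col] * 30)
        out = weighted_pca_adjustment(block, tau=0.99, p_max=5)
        assert out.shape[1] == 1

    def test_component_count_matches_eigendecomposition(self, rng):
        block = rng.normal(size=(200, 120))
        block = block - block.mean(axis=0)
        out = weighted_pca_adjustment(block, tau=0.95, p_max=50)
        eigvals = np.linalg.eigvalsh(block.T @ block / 200)[::-1]
        k = int(np.searchsorted(np.cumsum(eigvals) / eigvals.sum(), 0.95 - 1e-12) + 1)
        assert out.shape[1] == k

    def test_default_p_max_scales_with_n(self, rng):
        block = rng.normal(size=(200, 30))
        out = weighted_pca_adjustment(block)  # p_max = min(100, 200//10) = 20
        assert out.shape[1] < 30

    def test_invalid_tau(self, rng):
        with pytest.raises(ValueError, match="tau"):
            weighted_pca_adjustment(rng.normal(size=(10, 3)), tau=1.5)


class TestNullModel:
    def test_binary_exposure_single_column(self):
        _, gm, table = simulate_once(1)
        null = fit_null_model(table, "Y", ["age", "sex"], exposure="E")
        assert null.column_names.count("E") == 1
        assert not any("bs" in c for c in null.column_names)

    def test_continuous_exposure_spline_columns(self):
        _, gm, table = simulate_once(2, exposure_continuous=True)
        null = fit_null_model(table, "Y", ["age", "sex"], exposure="E", n_knots=3)
        assert sum("E_bs" in c for c in null.column_names) == 6  # K + degree

    def test_linear_exposure_option(self):
        _, gm, table = simulate_once(3, exposure_continuous=True)
        null = fit_null_model(table, "Y", ["age", "sex"], exposure="E", n_knots=0)
        assert "E" in null.column_names

    def test_revert_includes_all_snp_columns(self):
        _, gm, table = simulate_once(4, p=10)
        block, _, _ = standardize_genotypes(gm)
        adjustment = weighted_pca_adjustment(block, p_max=50)
        null = fit_null_model(
            table, "Y", ["age", "sex"], exposure="E",
            genotype_adjustment=adjustment, adjustment_subjects=gm.subjects,
        )
        assert sum(c.startswith("G_adj") for c in null.column_names) == 10

    def test_residuals_orthogonal_to_design(self):
        _, gm, table = simulate_once(5)
        null = fit_null_model(table, "Y", ["age", "age2", "sex"], exposure="E")
        cross = null.design.T @ null.residuals
        scale = np.linalg.norm(null.design, axis=0) * np.linalg.norm(null.residuals)
        np.testing.assert_allclose(cross / scale, 0.0, atol=1e-9)

    def test_collinear_adjustment_dropped_with_warning(self):
        _, gm, table = simulate_once(6, p=2)
        block, _, _ = standardize_genotypes(gm)
        doubled = np.column_stack([block, block[:, 0]])
        with pytest.warns(UserWarning, match="collinear"):
            null = fit_null_model(
                table, "Y", ["age", "sex"], exposure="E",
                genotype_adjustment=doubled, adjustment_subjects=gm.subjects,
            )
        assert sum(c.startswith("G_adj") for c in null.column_names) == 2

    def test_incomplete_cases_rejected(self):
        _, gm, table = simulate_once(7)
        table = table.copy()
        table.loc[0, "E"] = np.nan
        with pytest.raises(ValueError, match="complete cases"):
            fit_null_model(table, "Y", ["age", "sex"], exposure="E")


class TestBsplineBasis:
    def test_shape(self, rng):
        basis = bspline_basis(rng.normal(size=100), n_knots=3)
        assert basis.shape == (100, 6)

    def test_captures_quadratic(self, rng):
        x = rng.normal(size=300)
        y = 1.0 + 0.5 * x**2
        basis = np.column_stack([np.ones(300), bspline_basis(x, n_knots=3)])
        fitted = basis @ np.linalg.lstsq(basis, y, rcond=None)[0]
        assert np.max(np.abs(fitted - y)) < 0.05


class SingleVariantOracle:
    """Scalar brute-force robust score test matching the estimator contract:
    CR2-adjusted per-cluster variance shrunk toward the pooled one."""

    @staticmethod
    def pvalue(table, g_std, subjects, exposure_col="E"):
        lookup = {s: i for i, s in enumerate(subjects)}
        rows = [lookup[s] for s in table["subject"]]
        g_obs = g_std[rows]
        D = np.column_stack(
            [
                np.ones(len(table)),
                table["age"],
                table["age2"],
                table["sex"],
                table[exposure_col],
                g_obs,
            ]
        )
        y = table["Y"].to_numpy()
        r = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        z0 = g_obs * table[exposure_col].to_numpy()
        z = z0 - D @ np.linalg.lstsq(D, z0[:, None], rcond=None)[0][:, 0]
        U = float(z @ r)
        n, q = D.shape
        DtD_inv = np.linalg.inv(D.T @ D)
        v_cr2 = 0.0
        for i in range(n):  # all clusters singleton by construction
            h = D[i] @ DtD_inv @ D[i]
            v_cr2 += (z[i] * r[i]) ** 2 / (1.0 - h)
        sigma2 = float(np.mean(r**2)) * n / (n - q)
        v_pooled = sigma2 * float(z @ z)
        v = (1 - POOLED_SHRINKAGE) * v_cr2 + POOLED_SHRINKAGE * v_pooled
        return float(stats.chi2.sf(U * U / v, df=1))


class TestInteractionSetTest:
    def test_single_variant_equals_robust_score_test(self):
        for seed in range(5):
            _, gm, table = simulate_once(
                100 + seed, n=250, p=1, rho=0.0, two_exam_fraction=0.0,
                beta=0.2,
            )
            res = interaction_pvalue(gm, table)
            oracle = SingleVariantOracle.pvalue(
                table, standardize_genotypes(gm)[0][:, 0], gm.subjects
            )
            assert res.pvalue == pytest.approx(oracle, abs=1e-6)

    def test_allele_flip_invariance(self):
        _, gm, table = simulate_once(8)
        res = interaction_pvalue(gm, table)
        flipped = GenotypeMatrix(gm.subjects, gm.variants, 2.0 - gm.dosages)
        res_flip = interaction_pvalue(flipped, table)
        assert res.Q == pytest.approx(res_flip.Q, rel=1e-9)
        assert res.pvalue == pytest.approx(res_flip.pvalue, rel=1e-9)

    def test_variant_order_invariance(self):
        _, gm, table = simulate_once(9)
        res = interaction_pvalue(gm, table)
        perm = np.random.default_rng(0).permutation(gm.n_variants)
        gm_perm = GenotypeMatrix(
            gm.subjects, gm.variants.iloc[perm], gm.dosages[:, perm]
        )
        res_perm = interaction_pvalue(gm_perm, table)
        assert res.Q == pytest.approx(res_perm.Q, rel=1e-9)
        assert res.pvalue == pytest.approx(res_perm.pvalue, rel=1e-9)
        np.testing.assert_allclose(
            np.sort(res.eigenvalues), np.sort(res_perm.eigenvalues), rtol=1e-8
        )

    def test_weight_scale_invariance(self):
        _, gm, table = simulate_once(10)
        res1 = interaction_pvalue(gm, table, weights=np.ones(20))
        res2 = interaction_pvalue(gm, table, weights=np.full(20, 3.5))
        assert res2.Q == pytest.approx(res1.Q * 3.5**2, rel=1e-9)
        assert res1.pvalue == pytest.approx(res2.pvalue, rel=1e-9)

    def test_power_increases_with_effect(self):
        rates = []
        for gamma_val in (0.0, 1.2, 3.0):
            rejections = 0
            for rep in range(40):
                gamma = np.zeros(15)
                gamma[4] = gamma_val
                _, gm, table = simulate_once(
                    3000 + rep, n=500, p=15, beta=0.1, gamma=gamma
                )
                rejections += interaction_pvalue(gm, table).pvalue < 0.05
            rates.append(rejections / 40)
        assert rates[0] < rates[1] < rates[2]
        assert rates[2] > 0.5

    def test_type_one_error_small_run(self):
        # scaled-down calibration check; the full 2000-replicate version runs
        # in the acceptance suite
        pvals = []
        for rep in range(250):
            _, gm, table = simulate_once(20_000 + rep, n=400, p=20, beta=0.1)
            pvals.append(interaction_pvalue(gm, table).pvalue)
        pvals = np.array(pvals)
        for alpha in (0.05, 0.01):
            rate = (pvals < alpha).mean()
            half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / 250)
            assert abs(rate - alpha) < half_width + 0.01, (alpha, rate)

    def test_empty_block_rejected(self):
        _, gm, table = simulate_once(11)
        null = fit_null_model(table, "Y", ["age", "sex"], exposure="E")
        with pytest.raises(ValueError, match="empty"):
            interaction_set_test(
                null, np.empty((gm.n_subjects, 0)), table["E"].to_numpy(),
                block_subjects=gm.subjects,
            )

    def test_unknown_cov_estimator(self):
        _, gm, table = simulate_once(12)
        with pytest.raises(ValueError, match="covariance estimator"):
            interaction_pvalue(gm, table, cov_estimator="bootstrap")


class TestMarginalSetTest:
    def test_single_variant_oracle(self):
        for seed in range(3):
            _, gm, table = simulate_once(
                200 + seed, n=250, p=1, rho=0.0, two_exam_fraction=0.0
            )
            block, _, _ = standardize_genotypes(gm)
            res = marginal_set_test(
                table, block, ["age", "age2", "sex"], block_subjects=gm.subjects
            )
            # scalar oracle: same construction with covariate-only null
            lookup = {s: i for i, s in enumerate(gm.subjects)}
            rows = [lookup[s] for s in table["subject"]]
            D = np.column_stack(
                [np.ones(len(table)), table["age"], table["age2"], table["sex"]]
            )
            y = table["Y"].to_numpy()
            r = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
            z0 = block[rows, 0]
            z = z0 - D @ np.linalg.lstsq(D, z0[:, None], rcond=None)[0][:, 0]
            U = float(z @ r)
            n, q = D.shape
            # pooled estimator (the marginal-test default) for singleton
            # clusters is the df-corrected residual variance times z'z
            sigma2 = float(np.mean(r**2)) * n / (n - q)
            v = sigma2 * float(z @ z)
            oracle = float(stats.chi2.sf(U * U / v, df=1))
            assert res.pvalue == pytest.approx(oracle, abs=1e-6)

    def test_duplicated_variants_leave_p_unchanged(self):
        _, gm, table = simulate_once(13, p=10)
        block, _, _ = standardize_genotypes(gm)
        res1 = marginal_set_test(
            table, block, ["age", "sex"], block_subjects=gm.subjects
        )
        doubled = np.column_stack([block, block])
        res2 = marginal_set_test(
            table, doubled, ["age", "sex"], block_subjects=gm.subjects
        )
        assert res2.Q == pytest.approx(2 * res1.Q, rel=1e-9)
        assert res2.pvalue == pytest.approx(res1.pvalue, rel=1e-6)

    def test_detects_marginal_effect(self):
        _, gm, table = simulate_once(14, n=800, p=10, beta=1.5)
        block, _, _ = standardize_genotypes(gm)
        res = marginal_set_test(
            table, block, ["age", "age2", "sex"], block_subjects=gm.subjects
        )
        assert res.pvalue < 1e-4


class TestSplineProtection:
    def test_spline_null_controls_linear_null_inflates(self):
        # quadratic true exposure effect with exposure-genotype coupling;
        # scaled-down version of the acceptance criterion
        rejections = {0: 0, 3: 0}
        reps = 300
        for knots in rejections:
            for rep in range(reps):
                cfg = hrs_ea_like(
                    n_subjects=500,
                    beta=0.1,
                    exposure_continuous=True,
                    exposure_on_genotype=0.8,
                    region=RegionSpec(p=30, rho=0.5),
                )
                gen = np.random.default_rng(880_000 + rep)
                gm = simulate_genotypes(500, cfg.region, gen)
                table = simulate_cohort(
                    cfg, gm, gen, exposure_fn=lambda e: 1.2 * e**2
                )
                block, _, _ = standardize_genotypes(gm)
                adjustment = weighted_pca_adjustment(block)
                null = fit_null_model(
                    table, "Y", ["age", "age2", "sex"], exposure="E",
                    genotype_adjustment=adjustment,
                    adjustment_subjects=gm.subjects, n_knots=knots,
                )
                p = interaction_set_test(
                    null, block, table["E"].to_numpy(),
                    block_subjects=gm.subjects,
                ).pvalue
                rejections[knots] += p < 0.05
        spline_rate = rejections[3] / reps
        linear_rate = rejections[0] / reps
        assert spline_rate <= 0.065
        assert linear_rate > spline_rate
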