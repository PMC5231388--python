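"""PLSR fitting, model-order selection, LD folds and jackknife inference."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import evoenrich as ev
from evoenrich.plsr import (PLSRError, _pls1_path, _refit_coefficients,
                            build_design, fit_plsr, jackknife_ttest, ld_folds,
                            mhc_subset, residual_vs_totld)

from oracles import ols_coefficients


def _standardize(M):
    return (M - M.mean(axis=0)) / M.std(axis=0)


def _random_design(rng, n=400, p=5, names=None):
    X = _standardize(rng.standard_normal((n, p)))
    y = X @ rng.standard_normal(p) + rng.standard_normal(n)
    y = (y - y.mean()) / y.std()
    return ev.DesignMatrix(
        X=X, y=y, names=names or tuple(f"c{i}" for i in range(p)),
        x_mean=np.zeros(p), x_scale=np.ones(p), y_mean=0.0, y_scale=1.0,
    )


class TestBuildDesign:
    def test_centering_scaling_and_order(self, score_frame):
        z = np.array([0.1, -0.5, 1.0, 2.0, -1.2, 0.3])
        d = build_design(score_frame, z, evo_category="HAR",
                        covariates=("tot_ld",))
        assert d.names == ("HAR", "tot_ld")
        np.testing.assert_allclose(d.X.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(d.X.std(axis=0), 1.0, rtol=1e-12)
        assert abs(d.y.mean()) < 1e-12

    def test_destandardize_round_trip(self, score_frame):
        z = np.array([0.1, -0.5, 1.0, 2.0, -1.2, 0.3])
        d = build_design(score_frame, z, covariates=("HAR", "tot_ld"))
        raw = d.X * d.x_scale + d.x_mean
        np.testing.assert_allclose(raw[:, 0], score_frame["ld_HAR"], atol=1e-12)
        np.testing.assert_allclose(raw[:, 1], score_frame["tot_ld"], atol=1e-12)

    def test_absent_covariate_raises(self, score_frame):
        with pytest.raises(KeyError):
            build_design(score_frame, np.zeros(6), covariates=("nope",))

    def test_constant_covariate_named_in_error(self, score_frame):
        frame = score_frame.assign(flat=1.0)
        with pytest.raises(PLSRError, match="flat"):
            build_design(frame, np.arange(6, dtype=float),
                        covariates=("flat", "tot_ld"))


class TestFit:
    def test_single_covariate_equals_correlation(self):
        rng = np.random.default_rng(0)
        d = _random_design(rng, n=300, p=1)
        fit = fit_plsr(d)
        expect = float(np.corrcoef(d.X[:, 0], d.y)[0, 1]) * d.y.std() / d.X[:, 0].std()
        assert fit.n_lv == 1
        assert fit.coefficients[0] == pytest.approx(expect, rel=1e-10)

    def test_full_rank_reproduces_ols(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            d = _random_design(rng, n=500, p=7)
            fit = fit_plsr(d, var_threshold=0.99, max_lv=7)
            b_ols = ols_coefficients(d.X, d.y)
            if fit.n_lv == 7:
                np.testing.assert_allclose(fit.coefficients, b_ols, atol=1e-8)

    def test_matches_sklearn_pls_regression(self):
        """Independent cross-check against scikit-learn's PLS."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        d = _random_design(rng, n=400, p=6)
        for a in (1, 2, 4, 6):
            W, P, q, _ = _pls1_path(d.X, d.y, a)
            from evoenrich.plsr import _coefficients

            mine = _coefficients(W, P, q, a)
            ref = PLSRegression(n_components=a, scale=False).fit(d.X, d.y)
            np.testing.assert_allclose(mine, ref.coef_.ravel(), atol=1e-8)

    def test_orthogonal_response_gives_zero(self):
        rng = np.random.default_rng(3)
        X = _standardize(rng.standard_normal((200, 3)))
        # project y orthogonal to the covariate span
        y = rng.standard_normal(200)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]
        y /= y.std()
        d = ev.DesignMatrix(X=X, y=y, names=("a", "b", "c"),
                            x_mean=np.zeros(3), x_scale=np.ones(3),
                            y_mean=0.0, y_scale=1.0)
        fit = fit_plsr(d)
        np.testing.assert_allclose(fit.coefficients, 0.0, atol=1e-8)

    def test_order_selection_respects_variance_threshold(self):
        rng = np.random.default_rng(4)
        d = _random_design(rng, n=600, p=6)
        fit = fit_plsr(d, var_threshold=0.99)
        cum = np.cumsum(fit.x_variance_explained)
        assert cum[-1] > 0.99
        if fit.n_lv > 1:
            assert cum[-2] <= 0.99

    def test_more_covariates_than_rows_rejected(self):
        rng = np.random.default_rng(5)
        d = _random_design(rng, n=5, p=6)
        with pytest.raises(PLSRError):
            fit_plsr(d)


class TestFolds:
    def test_singleton_blocks_balanced(self):
        S = sp.identity(101, format="csr")
        folds = ld_folds(S, k=10, seed=0)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.max() - sizes.min() <= 1

    def test_block_never_split(self):
        n = 60
        S = sp.lil_matrix((n, n))
        S.setdiag(1.0)
        for i in range(0, 10):  # one 10-SNP perfect-LD block
            for j in range(10):
                S[i, j] = 1.0
        S = S.tocsr()
        folds = ld_folds(S, k=5, seed=3)
        assert len(np.unique(folds[:10])) == 1

    def test_no_cross_fold_ld_on_synthetic_blocks(self, small_scores):
        _, _, nbhd = small_scores
        S = nbhd.tag_submatrix()
        folds = ld_folds(S, k=20, seed=1)
        coo = sp.triu(S, k=1).tocoo()
        linked = coo.data >= nbhd.r2_floor
        assert (folds[coo.row[linked]] == folds[coo.col[linked]]).all()

    def test_too_few_blocks_raises(self):
        S = sp.csr_matrix(np.ones((5, 5)))
        with pytest.raises(ValueError, match="smaller k"):
            ld_folds(S, k=3)


class TestJackknife:
    def test_identical_refits_trigger_sentinel(self):
        rng = np.random.default_rng(6)
        X = _standardize(np.tile(rng.standard_normal((10, 2)), (10, 1)))
        beta = np.array([1.0, -0.5])
        y = X @ beta
        y = (y - y.mean()) / y.std()
        d = ev.DesignMatrix(X=X, y=y, names=("a", "b"), x_mean=np.zeros(2),
                            x_scale=np.ones(2), y_mean=0.0, y_scale=1.0)
        fit = fit_plsr(d)
        folds = np.repeat(np.arange(10), 10)  # folds = identical tiles
        fit = jackknife_ttest(d, fit, folds)
        assert np.isinf(fit.t_stat).all()
        np.testing.assert_array_equal(fit.p_value, 0.0)

    def test_sd_invariant_to_fold_relabeling(self):
        rng = np.random.default_rng(7)
        d = _random_design(rng, n=300, p=4)
        folds = rng.integers(0, 10, size=300)
        fit1 = jackknife_ttest(d, fit_plsr(d), folds)
        relabel = (folds + 3) % 10
        fit2 = jackknife_ttest(d, fit_plsr(d), relabel)
        np.testing.assert_allclose(fit1.jackknife_sd, fit2.jackknife_sd,
                                   rtol=1e-10)

    def test_strong_signal_detected(self):
        rng = np.random.default_rng(8)
        n = 2_000
        X = _standardize(rng.standard_normal((n, 3)))
        y = X @ np.array([0.5, 0.0, 0.0]) + 0.5 * rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        d = ev.DesignMatrix(X=X, y=y, names=("sig", "n1", "n2"),
                            x_mean=np.zeros(3), x_scale=np.ones(3),
                            y_mean=0.0, y_scale=1.0)
        fit = jackknife_ttest(d, fit_plsr(d), rng.integers(0, 50, size=n))
        assert fit.p_value[0] < 1e-6
        assert fit.coefficients[0] > 0

    def test_incomplete_folds_rejected(self):
        rng = np.random.default_rng(9)
        d = _random_design(rng, n=100, p=2)
        with pytest.raises(ValueError):
            jackknife_ttest(d, fit_plsr(d), np.zeros(50))


class TestPermutationInvariance:
    def test_row_shuffle_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(10)
        d = _random_design(rng, n=400, p=5)
        perm = rng.permutation(400)
        d2 = ev.DesignMatrix(X=d.X[perm], y=d.y[perm], names=d.names,
                             x_mean=d.x_mean, x_scale=d.x_scale,
                             y_mean=d.y_mean, y_scale=d.y_scale)
        np.testing.assert_allclose(
            fit_plsr(d).coefficients, fit_plsr(d2).coefficients, atol=1e-10
        )


class TestResidualVsTotLD:
    def test_bin_counts_cover_all_snps(self, small_scores):
        idx, table, _ = small_scores
        out = residual_vs_totld(table, idx.z, "SD", n_bins=8)
        assert set(out["stratum"]) == {"SD", "non-SD", "all"}
        assert out.loc[out["stratum"] == "all", "count"].sum() == len(table)

    def test_planted_totld_effect_has_positive_slope(self, small_scores):
        """With polygenic signal, residual z2 (model without TotLD, without
        the evo score) rises with TotLD."""
        idx, table, _ = small_scores
        out = residual_vs_totld(table, idx.z, "SD", n_bins=10,
                                drop_category=True)
        sub = out[out["stratum"] == "all"]
        slope = np.polyfit(sub["bin_center"], sub["mean_resid_z2"], 1)[0]
        assert slope > 0


class TestMHC:
    def test_boundaries_inclusive(self):
        df = pd.DataFrame(
            {"chrom": ["6", "6", "6", "1"],
             "pos": [25_652_428, 25_652_429, 33_421_466, 30_000_000]}
        )
        keep = mhc_subset(df, "exclude")
        np.testing.assert_array_equal(keep, [True, False, False, True])

    def test_partition(self, small_scores):
        _, table, _ = small_scores
        region = ("6", 3_000_000, 5_000_000)
        excl = mhc_subset(table, "exclude", region)
        only = mhc_subset(table, "only", region)
        assert (excl ^ only).all()

    def test_empty_subset_raises(self):
        df = pd.DataFrame({"chrom": ["1"], "pos": [100]})
        with pytest.raises(ValueError):
            mhc_subset(df, "only")
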