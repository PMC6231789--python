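import numpy as np
import pandas as pd
import pytest

from trialcea import cea_engine as ce


def _synthetic_cea_data(seed, n=400, delta_cost=-200.0, delta_effect=0.1, rho=0.4):
    """Trial-shaped data with known incremental cost and effect."""
    rng = np.random.default_rng(seed)
    arm = (np.arange(n) < n // 2).astype(float)
    base_prod = rng.gamma(2.0, 300.0, n)
    base_ids = rng.normal(25, 6, n)
    cov = np.array([[400.0**2, rho * 400 * 0.3], [rho * 400 * 0.3, 0.3**2]])
    errs = rng.multivariate_normal([0, 0], cov, size=n)
    cost = 1500 + delta_cost * arm + 0.8 * base_prod + errs[:, 0]
    effect = 0.2 + delta_effect * arm - 0.005 * (base_ids - 25) + errs[:, 1]
    return pd.DataFrame(
        {
            "arm": arm,
            "cost_total": cost,
            "effect": effect,
            "prod_m0": base_prod,
            "ids_m0": base_ids,
        }
    )


DESIGN = ce.CeaDesign(
    cost_col="cost_total",
    effect_col="effect",
    cost_covariates=("prod_m0",),
    effect_covariates=("ids_m0",),
)


class TestFitSure:
    def test_identical_regressors_equal_ols_exactly(self):
        # classical SUR identity, with statsmodels OLS as the oracle
        import statsmodels.api as sm

        df = _synthetic_cea_data(0)
        X = np.column_stack([df["arm"], df["prod_m0"]])
        fit = ce.fit_sure(
            df["cost_total"], df["effect"], df["arm"],
            cost_covariates=df[["prod_m0"]].to_numpy(),
            effect_covariates=df[["prod_m0"]].to_numpy(),
            cost_covariate_names=("prod_m0",),
            effect_covariate_names=("prod_m0",),
        )
        Xc = sm.add_constant(X)
        ols_c = sm.OLS(df["cost_total"], Xc).fit().params.to_numpy()
        ols_e = sm.OLS(df["effect"], Xc).fit().params.to_numpy()
        np.testing.assert_allclose(fit.params_cost, ols_c, rtol=1e-8)
        np.testing.assert_allclose(fit.params_effect, ols_e, rtol=1e-8)

    def test_parameter_recovery_large_n(self):
        # known truth dC=-200, dE=0.1 recovered within 3 Monte-Carlo SEs
        fits = [
            ce.fit_sure_table(_synthetic_cea_data(s, n=5000), DESIGN)
            for s in range(20)
        ]
        dc = np.array([f.delta_cost for f in fits])
        de = np.array([f.delta_effect for f in fits])
        assert abs(dc.mean() + 200) < 3 * dc.std(ddof=1) / np.sqrt(len(dc))
        assert abs(de.mean() - 0.1) < 3 * de.std(ddof=1) / np.sqrt(len(de))

    def test_exactly_uncorrelated_residuals_leave_ols_unchanged(self):
        # construct residuals lying in their projection spaces with exactly
        # zero cross-covariance: the GLS step must then be a no-op
        rng = np.random.default_rng(2)
        n = 200
        arm = (np.arange(n) < n // 2).astype(float)
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        X1 = np.column_stack([np.ones(n), arm, z1])
        X2 = np.column_stack([np.ones(n), arm, z2])
        P = lambda X: np.eye(n) - X @ np.linalg.inv(X.T @ X) @ X.T  # noqa: E731
        e1 = P(X1) @ rng.normal(size=n)
        cand = P(X2) @ rng.normal(size=n)
        b = P(X2) @ e1
        e2 = cand - (e1 @ cand) / (e1 @ b) * b
        assert abs(e1 @ e2) < 1e-8
        y1 = X1 @ np.array([100.0, -20.0, 5.0]) + e1
        y2 = X2 @ np.array([0.2, 0.1, 0.01]) + e2
        fit = ce.fit_sure(
            y1, y2, arm,
            cost_covariates=z1[:, None], effect_covariates=z2[:, None],
            cost_covariate_names=("z1",), effect_covariate_names=("z2",),
        )
        b1 = np.linalg.lstsq(X1, y1, rcond=None)[0]
        b2 = np.linalg.lstsq(X2, y2, rcond=None)[0]
        np.testing.assert_allclose(fit.params_cost, b1, rtol=1e-6)
        np.testing.assert_allclose(fit.params_effect, b2, rtol=1e-6)

    def test_residual_covariance_symmetric_psd(self):
        fit = ce.fit_sure_table(_synthetic_cea_data(3), DESIGN)
        s = fit.resid_cov
        assert s[0, 1] == s[1, 0]
        assert np.all(np.linalg.eigvalsh(s) >= -1e-9)

    def test_too_few_observations_rejected(self):
        df = _synthetic_cea_data(0, n=5)
        with pytest.raises(ValueError):
            ce.fit_sure_table(df, DESIGN)


class TestBootstrap:
    def test_identity_resample_equals_point_estimate(self):
        df = _synthetic_cea_data(4, n=150)
        fit = ce.fit_sure_table(df, DESIGN)
        arm = df["arm"].to_numpy(float)
        X1, _ = ce._stack_design(arm, df[["prod_m0"]].to_numpy(float), ("prod_m0",))
        X2, _ = ce._stack_design(arm, df[["ids_m0"]].to_numpy(float), ("ids_m0",))
        idx = np.arange(len(df))[None, :]
        dc, de = ce._batch_sure_arm_coefs(
            df["cost_total"].to_numpy(float), df["effect"].to_numpy(float),
            X1, X2, idx,
        )
        assert dc[0] == pytest.approx(fit.delta_cost, rel=1e-8)
        assert de[0] == pytest.approx(fit.delta_effect, rel=1e-8)

    def test_batched_path_matches_per_fit_loop(self):
        df = _synthetic_cea_data(5, n=120)
        rng = np.random.default_rng(0)
        arm = df["arm"].to_numpy(float)
        idx = rng.integers(0, len(df), size=(8, len(df)))
        X1, _ = ce._stack_design(arm, df[["prod_m0"]].to_numpy(float), ("prod_m0",))
        X2, _ = ce._stack_design(arm, df[["ids_m0"]].to_numpy(float), ("ids_m0",))
        y1 = df["cost_total"].to_numpy(float)
        y2 = df["effect"].to_numpy(float)
        dc, de = ce._batch_sure_arm_coefs(y1, y2, X1, X2, idx)
        for b in range(idx.shape[0]):
            sub = df.iloc[idx[b]].reset_index(drop=True)
            f = ce.fit_sure_table(sub, DESIGN)
            assert dc[b] == pytest.approx(f.delta_cost, rel=1e-7)
            assert de[b] == pytest.approx(f.delta_effect, rel=1e-7)

    def test_cloud_mean_near_point_estimate(self):
        df = _synthetic_cea_data(6)
        fit = ce.fit_sure_table(df, DESIGN)
        cloud = ce.bootstrap_cloud([df], DESIGN, B=800, seed=1)
        for col, point in ((0, fit.delta_cost), (1, fit.delta_effect)):
            reps = cloud.replicates[:, col]
            se = reps.std(ddof=1)
            assert abs(reps.mean() - point) < 3 * se / np.sqrt(len(reps)) + 0.05 * se

    def test_same_seed_identical_clouds(self):
        df = _synthetic_cea_data(7)
        a = ce.bootstrap_cloud([df], DESIGN, B=50, seed=42)
        b = ce.bootstrap_cloud([df], DESIGN, B=50, seed=42)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_stratified_resampling_preserves_arm_sizes(self):
        # no degenerate single-arm resamples by construction: every replicate
        # is finite even on a tiny, very unbalanced cohort
        df = _synthetic_cea_data(8, n=40)
        df = pd.concat([df[df.arm == 1].head(6), df[df.arm == 0]])
        cloud = ce.bootstrap_cloud([df], DESIGN, B=200, seed=0)
        assert np.isfinite(cloud.replicates).all()

    def test_pooling_over_imputations(self):
        dfs = [_synthetic_cea_data(s) for s in (1, 2, 3)]
        cloud = ce.bootstrap_cloud(dfs, DESIGN, B=10, seed=0)
        assert len(cloud.replicates) == 30 and cloud.m == 3 and cloud.pooled_over_m


class TestIcer:
    @pytest.mark.parametrize(
        "dc,de,cls,ratio",
        [
            (-225.0, 0.07, "dominant", None),
            (225.0, -0.07, "dominated", None),
            (100.0, 0.1, "ratio", 1000.0),
            (-100.0, -0.1, "ratio", 1000.0),
            (50.0, 0.0, "undefined-ratio", None),
        ],
    )
    def test_classification(self, dc, de, cls, ratio):
        res = ce.icer(dc, de)
        assert res.classification == cls
        if ratio is None:
            assert res.ratio_value is None
        else:
            assert res.ratio_value == pytest.approx(ratio)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ce.icer(np.nan, 0.1)


def _cloud(reps):
    reps = np.asarray(reps, dtype=float)
    return ce.BootstrapCloud(replicates=reps, B=len(reps), m=1, effect_kind="qaly")


class TestQuadrants:
    def test_all_southeast(self):
        q = ce.quadrant_shares(_cloud([[-10, 0.1]] * 5))
        assert q.se == 100.0 and q.ne == q.sw == q.nw == 0.0

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(1)
        reps = rng.normal(size=(500, 2))
        mirrored = np.vstack([reps, -reps])
        q = ce.quadrant_shares(_cloud(mirrored))
        assert q.ne == pytest.approx(q.sw) and q.se == pytest.approx(q.nw)

    def test_matches_brute_force_and_sums_to_100(self):
        rng = np.random.default_rng(2)
        reps = rng.normal(size=(999, 2)) * [300, 0.1]
        q = ce.quadrant_shares(_cloud(reps))
        dc, de = reps[:, 0], reps[:, 1]
        n = len(reps)
        assert q.se == pytest.approx(100 * np.sum((de > 0) & (dc < 0)) / n)
        assert q.ne == pytest.approx(100 * np.sum((de > 0) & (dc >= 0)) / n)
        assert q.ne + q.se + q.sw + q.nw == pytest.approx(100.0, abs=0.1)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            ce.quadrant_shares(_cloud(np.empty((0, 2))))


class TestCeac:
    def test_lambda_zero_is_cost_saving_fraction(self):
        rng = np.random.default_rng(3)
        reps = rng.normal(size=(1000, 2)) * [300, 0.1]
        cloud = _cloud(reps)
        curve = ce.ceac(cloud, np.array([0.0]))
        assert curve.probability[0] == pytest.approx(np.mean(reps[:, 0] < 0))
        # complement identity without ties
        assert curve.probability[0] + np.mean(reps[:, 0] >= 0) == pytest.approx(1.0)

    def test_all_southeast_cloud_is_certain(self):
        curve = ce.ceac(_cloud([[-10, 0.1]] * 4), np.arange(0, 80001, 1000.0))
        assert (curve.probability == 1.0).all()

    def test_matches_brute_force_nmb_count(self):
        rng = np.random.default_rng(4)
        reps = rng.normal(size=(500, 2)) * [300, 0.05]
        cloud = _cloud(reps)
        grid = np.arange(0, 80001, 1000.0)
        curve = ce.ceac(cloud, grid)
        for lam in (0.0, 20000.0, 80000.0):
            expected = np.mean(lam * reps[:, 1] - reps[:, 0] > 0)
            assert curve.probability[grid == lam][0] == pytest.approx(expected)

    def test_large_lambda_limit_is_effective_fraction(self):
        rng = np.random.default_rng(5)
        reps = rng.normal(size=(400, 2)) * [300, 0.1]
        cloud = _cloud(reps)
        lam = 1e12
        curve = ce.ceac(cloud, np.array([lam]))
        assert curve.probability[0] == pytest.approx(np.mean(reps[:, 1] > 0))

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            ce.ceac(_cloud([[1, 1]]), np.array([]))
        with pytest.raises(ValueError):
            ce.ceac(_cloud([[1, 1]]), np.array([-5.0, 0.0]))


class TestPooling:
    def _fits(self, seeds):
        return [ce.fit_sure_table(_synthetic_cea_data(s, n=300), DESIGN) for s in seeds]

    def test_single_fit_identity(self):
        (fit,) = self._fits([0])
        pooled = ce.pool_point_estimates([fit])
        assert pooled.delta_cost == fit.delta_cost
        assert pooled.between == (0.0, 0.0)

    def test_identical_fits_zero_between_variance(self):
        (fit,) = self._fits([1])
        pooled = ce.pool_point_estimates([fit, fit, fit])
        assert pooled.between == (0.0, 0.0)
        assert pooled.delta_effect == pytest.approx(fit.delta_effect)

    def test_matches_rubin_formula_brute_force(self):
        fits = self._fits([1, 2, 3, 4, 5])
        pooled = ce.pool_point_estimates(fits)
        m = len(fits)
        dc = np.array([f.delta_cost for f in fits])
        wc = np.array([f.var_delta[0] for f in fits])
        assert pooled.delta_cost == pytest.approx(dc.mean())
        assert pooled.var_delta_cost == pytest.approx(
            wc.mean() + (1 + 1 / m) * dc.var(ddof=1)
        )
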