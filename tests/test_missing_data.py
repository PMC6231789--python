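import numpy as np
import pandas as pd
import pytest

from trialcea import costing as co
from trialcea import missing_data as md
from trialcea import study_runner as sr
from trialcea import trial_data as td


@pytest.fixture(scope="module")
def analysis_table(default_trial, price_table, friction):
    cfg = sr.ScenarioConfig()
    breakdowns = sr.compute_breakdowns(default_trial, price_table, friction, cfg)
    return md.build_analysis_table(default_trial, breakdowns)


def _mar_table(seed, n=300):
    """Synthetic wide table with MAR 3-month outcomes (~30% missing)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "arm": rng.integers(0, 2, n).astype(float),
            "age": rng.normal(43, 13, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.integers(0, 2, n).astype(float),
            "employment": rng.integers(0, 2, n).astype(float),
            "ids_m0": rng.normal(25, 6, n),
            "jseq0": rng.normal(11, 5, n),
            "pss0": rng.normal(21, 5, n),
            "gad7_0": rng.normal(10, 4, n),
        },
        index=pd.Index([f"P{i:03d}" for i in range(n)], name="participant_id"),
    )
    truth = (
        10
        + 0.8 * df["ids_m0"]
        + 0.5 * df["gad7_0"]
        - 0.1 * df["age"]
        - 2.0 * df["arm"]
        + rng.normal(0, 4, n)
    )
    logit = -1.2 + 0.12 * (df["gad7_0"] - 10) - 0.02 * (df["age"] - 43)
    miss = rng.uniform(size=n) < 1 / (1 + np.exp(-logit))
    observed = truth.copy()
    observed[miss] = np.nan
    df["ids_m3"] = observed
    return df, truth


class TestPmm:
    def test_no_missingness_is_identity(self, analysis_table):
        complete = analysis_table.dropna()
        out = md.impute_pmm(complete, md.ImputationConfig(m=3, seed=0))
        assert out.m == 3
        for ds in out.datasets:
            pd.testing.assert_frame_equal(ds, complete)

    def test_observed_cells_preserved_and_only_donor_values_imputed(
        self, analysis_table
    ):
        out = md.impute_pmm(analysis_table, md.ImputationConfig(m=5, seed=1))
        for col in ("ids_m3", "hc_m3", "prod_m3", "ids_m6"):
            obs_mask = ~analysis_table[col].isna()
            donors = set(analysis_table.loc[obs_mask, col])
            for ds in out.datasets:
                # observed cells identical across copies
                assert (ds.loc[obs_mask, col] == analysis_table.loc[obs_mask, col]).all()
                # every imputed value is a real observed value
                assert set(ds.loc[~obs_mask, col]).issubset(donors)

    def test_imputed_scores_respect_observed_range(self, analysis_table):
        out = md.impute_pmm(analysis_table, md.ImputationConfig(m=2, seed=3))
        lo, hi = analysis_table["ids_m3"].min(), analysis_table["ids_m3"].max()
        for ds in out.datasets:
            assert ds["ids_m3"].between(lo, hi).all()

    def test_same_seed_identical_datasets(self, analysis_table):
        a = md.impute_pmm(analysis_table, md.ImputationConfig(m=3, seed=7))
        b = md.impute_pmm(analysis_table, md.ImputationConfig(m=3, seed=7))
        for x, y in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(x, y)

    def test_mar_bias_below_half_point(self):
        # simulation oracle: pooled imputed mean vs complete-data truth
        biases = []
        for seed in range(100):
            df, truth = _mar_table(seed)
            out = md.impute_pmm(df, md.ImputationConfig(m=5, seed=seed))
            pooled_mean = np.mean([ds["ids_m3"].mean() for ds in out.datasets])
            biases.append(pooled_mean - truth.mean())
        assert abs(np.mean(biases)) < 0.5

    def test_too_few_donors_rejected(self, analysis_table):
        tiny = analysis_table.iloc[:6]
        with pytest.raises(ValueError):
            md.impute_pmm(tiny, md.ImputationConfig(m=1, pmm_donors=50))


class TestRegressionImputation:
    def test_screen_recovers_constructed_predictors(self):
        rng = np.random.default_rng(5)
        n = 600
        df = pd.DataFrame(
            {
                "arm": rng.integers(0, 2, n).astype(float),
                "age": rng.normal(43, 13, n),
                "sex": rng.integers(0, 2, n).astype(float),
                "education": rng.integers(0, 2, n).astype(float),
                "employment": rng.integers(0, 2, n).astype(float),
                "ids_m0": rng.normal(25, 6, n),
                "jseq0": rng.normal(11, 5, n),
                "pss0": rng.normal(21, 5, n),
                "gad7_0": rng.normal(10, 4, n),
            }
        )
        outcome = 20 + 1.2 * df["jseq0"] + 0.8 * df["pss0"] + rng.normal(0, 5, n)
        logit = -1.0 + 0.25 * (df["gad7_0"] - 10) - 0.05 * (df["age"] - 43)
        miss = rng.uniform(size=n) < 1 / (1 + np.exp(-logit))
        df["ids_m3"] = outcome.where(~miss)
        selected = md.screen_predictors(df)
        assert selected[0] == "arm"
        assert {"gad7_0", "age", "jseq0", "pss0"}.issubset(set(selected))
        assert not {"sex", "education", "employment", "ids_m0"} & set(selected[1:])

    def test_no_missingness_is_identity(self, analysis_table):
        complete = analysis_table.dropna()
        out = md.impute_regression(complete)
        assert out.m == 1
        pd.testing.assert_frame_equal(out.datasets[0], complete)

    def test_imputed_values_are_exact_linear_predictions(self, analysis_table):
        out = md.impute_regression(analysis_table)
        ds = out.datasets[0]
        selected = list(out.predictors["selected"])
        miss = analysis_table["ids_m3"].isna()
        obs = ~miss
        X = np.column_stack(
            [np.ones(len(ds))] + [ds[c].to_numpy(float) for c in selected]
        )
        beta = np.linalg.lstsq(
            X[obs.to_numpy()], analysis_table.loc[obs, "ids_m3"].to_numpy(float),
            rcond=None,
        )[0]
        yhat = X @ beta
        np.testing.assert_allclose(
            ds.loc[miss, "ids_m3"].to_numpy(), yhat[miss.to_numpy()], rtol=1e-10
        )


class TestLocf:
    def test_carry_forward_definitions(self):
        df = pd.DataFrame(
            {
                "ids_m0": [20.0, 30.0],
                "ids_m3": [np.nan, 16.0],
                "ids_m6": [np.nan, np.nan],
                "hc_m0": [50.0, 10.0],
                "hc_m3": [np.nan, 60.0],
                "hc_m6": [np.nan, np.nan],
            },
            index=["a", "b"],
        )
        out = md.impute_locf(df).datasets[0]
        # scores carry unchanged; both follow-ups inherit baseline when lost early
        assert out.loc["a", "ids_m3"] == 20.0 and out.loc["a", "ids_m6"] == 20.0
        assert out.loc["b", "ids_m6"] == 16.0
        # cost subtotals rescale by the recall-window ratio (1 month -> 3 months)
        assert out.loc["a", "hc_m3"] == pytest.approx(150.0)
        assert out.loc["b", "hc_m6"] == pytest.approx(60.0)

    def test_no_missingness_is_identity(self, analysis_table):
        complete = analysis_table.dropna()
        pd.testing.assert_frame_equal(md.impute_locf(complete).datasets[0], complete)


class TestAttrition:
    def test_printed_trial_attrition_statistic(self):
        stat, dof = md.attrition_chi2(68, 165, 24, 164)
        assert dof == 1
        assert round(stat, 1) == 28.8

    def test_equal_proportions_give_zero(self):
        stat, _ = md.attrition_chi2(20, 100, 20, 100)
        assert stat == pytest.approx(0.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n_a, n_b = int(rng.integers(20, 200)), int(rng.integers(20, 200))
            lost_a = int(rng.integers(1, n_a))
            lost_b = int(rng.integers(1, n_b))
            stat, _ = md.attrition_chi2(lost_a, n_a, lost_b, n_b)
            obs = np.array(
                [[lost_a, n_a - lost_a], [lost_b, n_b - lost_b]], dtype=float
            )
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            md.attrition_chi2(0, 100, 0, 100)
        with pytest.raises(ValueError):
            md.attrition_chi2(101, 100, 5, 100)


def test_missingness_report_counts(analysis_table):
    rep = md.missingness_report(analysis_table)
    expected = int(analysis_table["ids_m3"].isna().sum())
    assert rep.loc[rep.variable == "ids_m3", "n_missing"].item() == expected
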