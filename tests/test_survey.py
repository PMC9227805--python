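import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from glycoload import clinical, survey
from glycoload.errors import (
    DegenerateStandardizationError,
    LonelyPSUError,
    SingularDesignError,
)
from glycoload.survey import fit_model_grid, standardize, survey_mean, weighted_ols


class TestStandardize:
    def test_two_point_symmetry_population_sd(self):
        assert standardize([1.0, 3.0]).tolist() == [-1.0, 1.0]

    def test_idempotent(self):
        x = np.array([2.0, 5.0, 9.0, 1.0])
        z = standardize(x)
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_weighted_moments(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([1.0, 1.0, 1.0, 9.0])
        z = standardize(x, w)
        # oracle: direct weighted-moment arithmetic
        mean = np.sum(w * x) / w.sum()
        sd = np.sqrt(np.sum(w * (x - mean) ** 2) / w.sum())
        np.testing.assert_allclose(z, (x - mean) / sd, atol=1e-12)
        assert np.average(z, weights=w) == pytest.approx(0.0, abs=1e-12)
        assert np.average(z**2, weights=w) == pytest.approx(1.0, rel=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateStandardizationError):
            standardize([4.0, 4.0, 4.0])


def _toy_data(n=80, k=2, seed=5, het=True):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    scale = 1 + 0.5 * np.abs(X["x1"]) if het else 1.0
    y = 1.0 + 2.0 * X["x1"] - 1.0 * X["x2"] + rng.normal(size=n) * scale
    return y.to_numpy(), X


class TestWeightedOLS:
    def test_design_collapse_matches_textbook_ols(self):
        """Equal weights, one stratum, each unit its own PSU → OLS point
        estimates; Taylor covariance equals the independent cluster-robust
        oracle up to the n/(n−1) with-replacement factor."""
        y, X = _toy_data()
        n = len(y)
        fit = weighted_ols(y, X, np.zeros(n), np.arange(n), np.ones(n))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-8)
        sm_clu = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": np.arange(n), "use_correction": False}
        )
        np.testing.assert_allclose(
            fit.cov.to_numpy(), sm_clu.cov_params().to_numpy() * n / (n - 1), rtol=1e-8
        )
        assert fit.df == n - 1

    def test_perfect_fit_recovers_beta_with_zero_se(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=40), "x2": rng.normal(size=40)})
        beta = np.array([2.0, -1.0, 0.5])
        y = X.to_numpy() @ beta
        fit = weighted_ols(y, X, np.zeros(40), np.arange(40) // 4, np.ones(40))
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)
        assert np.all(fit.se.to_numpy() < 1e-10)

    def test_cluster_oracle_agreement(self):
        """With one stratum and several PSUs the Taylor covariance matches the
        statsmodels cluster sandwich times G/(G−1)."""
        rng = np.random.default_rng(2)
        n, G = 200, 20
        groups = np.repeat(np.arange(G), n // G)
        X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=n)})
        y = 1 + 0.5 * X["x1"].to_numpy() + rng.normal(size=G)[groups] + rng.normal(size=n)
        fit = weighted_ols(y, X, np.zeros(n), groups, np.ones(n))
        smf = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": groups, "use_correction": False}
        )
        np.testing.assert_allclose(
            fit.cov.to_numpy(), smf.cov_params().to_numpy() * G / (G - 1), rtol=1e-8
        )
        assert fit.df == G - 1

    def test_robust_se_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(3)
        n = 120
        y, X = _toy_data(n=n, seed=3)
        w = rng.uniform(0.5, 3.0, n)
        strat = np.repeat([0, 1], n // 2)
        psu = np.arange(n) // 10
        f1 = weighted_ols(y, X, strat, psu, w)
        f2 = weighted_ols(y, X, strat, psu, w * 7.3)
        np.testing.assert_allclose(f1.params, f2.params, rtol=1e-10)
        np.testing.assert_allclose(f1.se, f2.se, rtol=1e-10)

    def test_rank_deficiency_names_collinear_column(self):
        y, X = _toy_data()
        X["x1_copy"] = X["x1"]
        with pytest.raises(SingularDesignError) as err:
            weighted_ols(y, X, np.zeros(len(y)), np.arange(len(y)), np.ones(len(y)))
        assert {"x1", "x1_copy"} & set(err.value.columns)

    def test_lonely_psu_error_and_merge(self):
        y, X = _toy_data(n=40)
        psu = np.arange(40) // 5
        stratum = np.where(psu == 7, "lonely", "big")  # one stratum holds one PSU
        with pytest.raises(LonelyPSUError):
            weighted_ols(y, X, stratum, psu, np.ones(40))
        fit = weighted_ols(y, X, stratum, psu, np.ones(40), lonely_psu="merge")
        assert fit.n_strata == 1 and fit.n_psu == 8


def test_survey_mean_collapses_to_classical_sem():
    rng = np.random.default_rng(4)
    y = rng.normal(10, 2, 50)
    est = survey_mean(y, np.zeros(50), np.arange(50), np.ones(50))
    assert est["mean"] == pytest.approx(y.mean())
    assert est["se"] == pytest.approx(y.std(ddof=1) / np.sqrt(50), rel=1e-10)


class TestModelGrid:
    def _prep(self, cohort):
        students = clinical.prepare_students(cohort.students)
        retained, _ = clinical.exclusion_filter(students)
        return retained

    def test_full_grid_has_24_cells(self, small_cohort):
        retained = self._prep(small_cohort)
        res = fit_model_grid(retained, small_cohort.day_metrics)
        assert len(res) == 24
        assert set(res["stratum_group"]) == {"NW", "OW"}
        assert res["p_value"].between(0, 1).all()
        assert (res["df"] == res["df"].iloc[0]).all()  # same design → same df

    def test_empty_stratum_halves_the_grid(self, small_cohort):
        retained = self._prep(small_cohort)
        nw_only = retained[retained["weight_stratum"] == "NW"]
        res = fit_model_grid(nw_only, small_cohort.day_metrics)
        assert len(res) == 12
        assert set(res["stratum_group"]) == {"NW"}

    def test_whole_sample_standardization_scope(self, small_cohort):
        retained = self._prep(small_cohort)
        res = fit_model_grid(
            retained, small_cohort.day_metrics, standardization_scope="whole_sample"
        )
        assert len(res) == 24

    def test_generated_sign_pattern_recovered(self, small_cohort):
        """The generator plants a positive insulin–AvGL effect in NW and a
        positive insulin–AvGI effect in OW; the fitted grid shows them."""
        retained = self._prep(small_cohort)
        res = fit_model_grid(retained, small_cohort.day_metrics).set_index(
            ["stratum_group", "marker", "metric"]
        )
        assert res.loc[("NW", "insulin", "av_gl"), "beta"] > 0
        assert res.loc[("OW", "insulin", "av_gi"), "beta"] > 0
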