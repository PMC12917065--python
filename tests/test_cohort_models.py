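import numpy as np
import pandas as pd
import pytest

from tilspatial.models.cohort import (
    HeterogeneityModel,
    LogSlopeModel,
    NegativeBinomialMixedModel,
)


def _covariates(n, rng):
    return {
        "sex": rng.choice(["male", "female"], n),
        "age": rng.uniform(50, 85, n),
        "grade": rng.choice(["G1", "G2", "G3"], n, p=[0.2, 0.5, 0.3]),
        "stage": rng.choice(["I", "II", "III"], n, p=[0.3, 0.55, 0.15]),
    }


def _slope_cohort(rng, n_per_arm=30, ratio=2.0, naive_median=0.008, sd=0.6):
    n = 2 * n_per_arm
    arm = np.array(["naive"] * n_per_arm + ["NAT"] * n_per_arm)
    beta = np.exp(
        np.log(naive_median) + np.log(ratio) * (arm == "NAT")
        + sd * rng.standard_normal(n)
    )
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "treatment": arm, "beta": beta, **_covariates(n, rng),
    })


class TestLogSlopeModel:
    def test_coefficient_exponentiates_to_slope_ratio(self, rng):
        res = LogSlopeModel(_slope_cohort(rng)).fit()
        assert res.slope_ratio == pytest.approx(np.exp(res.treatment_coef))
        # the log-scale difference reported as 0.72 implies a 2.05 ratio
        assert round(float(np.exp(0.72)), 2) == 2.05

    def test_recovers_true_ratio_two(self, rng):
        res = LogSlopeModel(_slope_cohort(rng, ratio=2.0)).fit()
        assert 1.5 <= res.slope_ratio <= 2.7

    def test_nonpositive_slopes_excluded_and_reported(self, rng):
        tab = _slope_cohort(rng)
        tab.loc[0, "beta"] = -0.006
        res = LogSlopeModel(tab, policy="exclude").fit()
        assert res.excluded_nonpositive == ["S0"]
        assert res.n_used == len(tab) - 1
        shifted = LogSlopeModel(tab, policy="shift", shift=0.01).fit()
        assert shifted.n_used == len(tab)

    def test_treatment_coef_invariant_to_age_rescaling(self, rng):
        tab = _slope_cohort(rng)
        res1 = LogSlopeModel(tab).fit()
        tab2 = tab.copy()
        tab2["age"] = (tab2["age"] - tab2["age"].mean()) / tab2["age"].std()
        res2 = LogSlopeModel(tab2).fit()
        assert res1.treatment_coef == pytest.approx(res2.treatment_coef, abs=1e-9)

    def test_single_level_covariate_dropped_with_warning(self, rng, caplog):
        tab = _slope_cohort(rng)
        tab["grade"] = "G2"
        with caplog.at_level("WARNING"):
            res = LogSlopeModel(tab).fit()
        assert "grade" in res.dropped_covariates
        assert "single level" in caplog.text

    def test_type_one_error_calibrated_under_null(self, rng):
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            tab = _slope_cohort(rng, n_per_arm=20, ratio=1.0)
            if LogSlopeModel(tab).fit().treatment_pvalue < 0.05:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.08


class TestHeterogeneityModel:
    def _het_cohort(self, rng, shift=-13.0, n_per_arm=30):
        n = 2 * n_per_arm
        arm = np.array(["naive"] * n_per_arm + ["NAT"] * n_per_arm)
        sd_cancer = 30.0 + shift * (arm == "NAT") + rng.normal(0, 6, n)
        return pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)], "treatment": arm,
            "quadrat_sd_cancer": np.clip(sd_cancer, 1, None),
            **_covariates(n, rng),
        })

    def test_recovers_negative_shift(self, rng):
        res = HeterogeneityModel(self._het_cohort(rng, shift=-13.0)).fit()
        assert res.treatment_effect < 0
        assert 8.0 <= abs(res.treatment_effect) <= 18.0

    def test_null_effect_within_two_se(self, rng):
        inside = 0
        n_rep = 200
        for _ in range(n_rep):
            tab = self._het_cohort(rng, shift=0.0, n_per_arm=15)
            res = HeterogeneityModel(tab).fit()
            se = float(res.bse[res.treatment_term])
            inside += abs(res.treatment_effect) < 2 * se
        assert inside / n_rep >= 0.90

    def test_from_summaries_join(self, rng):
        from tilspatial.spatial import QuadratSummary

        summaries = [QuadratSummary(f"S{i}", 50, 28.0, 25.0 + i, 5.0, 4.0)
                     for i in range(8)]
        clin = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(8)],
            "treatment": ["naive"] * 4 + ["NAT"] * 4,
            **_covariates(8, rng),
        })
        model = HeterogeneityModel.from_summaries(summaries, clin)
        assert len(model.table) == 8
        assert "quadrat_sd_cancer" in model.table


def _glmm_data(rng, n_per_arm=12, n_quadrats=80, b0=None, bc=0.0047,
               bt=0.1, bx=0.0022, sigma=0.5, theta=2.0):
    if b0 is None:
        b0 = float(np.log(4) - bc * 28)
    rows = []
    for j in range(2 * n_per_arm):
        arm = "NAT" if j >= n_per_arm else "naive"
        u = rng.normal(0, sigma) if sigma > 0 else 0.0
        cancer = rng.poisson(rng.gamma(1.2, 28 / 1.2, n_quadrats))
        eta = b0 + bc * cancer + (bt + bx * cancer) * (arm == "NAT") + u
        mu = np.exp(eta)
        cd8 = rng.poisson(rng.gamma(theta, mu / theta))
        rows.append(pd.DataFrame({
            "subject_id": f"S{j}", "cancer": cancer, "cd8": cd8,
            "treatment": arm,
        }))
    return pd.concat(rows, ignore_index=True)


class TestNBMixedModel:
    def test_laplace_and_agq_agree(self, rng):
        df = _glmm_data(rng, n_per_arm=8, n_quadrats=60)
        model = NegativeBinomialMixedModel(df)
        lap = model.fit(method="laplace")
        agq = model.fit(method="agq", agq_nodes=7)
        rel = np.abs(
            (agq.fe_params - lap.fe_params) / np.maximum(np.abs(lap.fe_params), 1e-3)
        )
        assert float(rel.max()) < 0.01

    def test_zero_variance_collapses_to_pooled_glm(self, rng):
        from statsmodels.discrete.discrete_model import NegativeBinomial

        df = _glmm_data(rng, n_per_arm=10, n_quadrats=100, bt=0.5, sigma=0.0)
        model = NegativeBinomialMixedModel(df)
        res = model.fit(method="laplace")
        pooled = NegativeBinomial(model.y, model.X, loglike_method="nb2").fit(disp=0)
        rel = np.abs((res.fe_params.to_numpy() - pooled.params[:4])
                     / np.maximum(np.abs(pooled.params[:4]), 1e-2))
        assert rel.max() < 0.02

    def test_loglik_monotone_over_iterations(self, rng):
        df = _glmm_data(rng, n_per_arm=6, n_quadrats=50)
        res = NegativeBinomialMixedModel(df).fit(track_iterations=True)
        lls = np.array(res.diagnostics["iteration_loglikes"])
        assert np.all(np.diff(lls) >= -1e-6)

    def test_fold_change_reading_of_fixed_effects(self):
        # at the reported estimates: 1.60 naive, 1.99 NAT, ratio 1.25
        from tilspatial.models.cohort import MixedModelResults

        fe = pd.Series([0.0, 0.0047, 0.1, 0.0022],
                       index=["intercept", "cancer", "treatment",
                              "cancer_x_treatment"])
        res = MixedModelResults(fe, fe * 0 + 0.001, fe * 0 + 0.5, 2.0, 0.5,
                                0.0, True, "laplace", 100, 10)
        fc = res.fold_changes(100)
        assert round(fc["naive"], 2) == 1.60
        assert round(fc["NAT"], 2) == 1.99
        assert round(fc["ratio"], 2) == 1.25

    def test_rejects_underpowered_data(self, rng):
        df = _glmm_data(rng, n_per_arm=2, n_quadrats=5)
        with pytest.raises(ValueError, match="too few pooled quadrats"):
            NegativeBinomialMixedModel(df)
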