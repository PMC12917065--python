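import numpy as np
import pandas as pd
import pytest

from tilspatial.io import Window
from tilspatial.models.subject import SubjectSlopeModel
from tilspatial.simulate import (
    SyntheticTruth,
    cohort_to_cell_table,
    simulate_cancer_pattern,
    simulate_cd8_given_cancer,
    simulate_clinical_and_survival,
    simulate_cohort,
    simulate_quadrat_counts,
)
from tilspatial.spatial import make_quadrat_grid
from tilspatial.io import SubjectPattern


class TestCancerPattern:
    def test_zero_parent_intensity_gives_empty(self, rng):
        truth = SyntheticTruth(kappa_per_mm2=1e-12)
        pts = simulate_cancer_pattern(truth, rng)
        assert len(pts) == 0

    def test_mean_count_matches_thomas_intensity(self):
        truth = SyntheticTruth(kappa_per_mm2=2.0, mu_offspring=50.0,
                               sigma_mm=0.05, window_mm=(10.0, 8.0))
        w = truth.window()
        counts = [len(simulate_cancer_pattern(truth, np.random.default_rng(s), w))
                  for s in range(100)]
        expected = truth.kappa_per_mm2 * w.area * truth.mu_offspring
        # small edge loss: clusters near the border lose ~sigma-width strips
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)

    def test_sigma_zero_offspring_coincide_with_parents(self, rng):
        truth = SyntheticTruth(sigma_mm=0.0, kappa_per_mm2=0.5, mu_offspring=20)
        pts = simulate_cancer_pattern(truth, rng)
        uniq = np.unique(np.round(pts, 9), axis=0)
        assert len(uniq) <= truth.kappa_per_mm2 * truth.window().area * 3

    def test_desk_scale_guard(self, rng):
        truth = SyntheticTruth(kappa_per_mm2=1e4, mu_offspring=1e4)
        with pytest.raises(ValueError, match="desk-scale"):
            simulate_cancer_pattern(truth, rng)


class TestCd8GivenCancer:
    def _grid(self, rng, truth=None):
        truth = truth or SyntheticTruth(window_mm=(4.0, 4.0))
        cancer = simulate_cancer_pattern(truth, rng)
        pat = SubjectPattern("A", cancer, np.empty((0, 2)), truth.window())
        return cancer, make_quadrat_grid(pat, 0.5)

    def test_null_coupling_flat_mean(self, rng):
        truth = SyntheticTruth(window_mm=(8.0, 8.0))
        cancer, grid = self._grid(rng, truth)
        pts = simulate_cd8_given_cancer(cancer, grid, np.log(5), 0.0, 50.0, rng)
        pat = SubjectPattern("A", cancer, pts, Window(0, 8, 0, 8))
        g = make_quadrat_grid(pat, 0.5)
        # per-quadrat cd8 mean ~5 regardless of cancer count
        assert g.cd8_counts.mean() == pytest.approx(5.0, rel=0.15)
        lo = g.cd8_counts[g.cancer_counts < np.median(g.cancer_counts)].mean()
        hi = g.cd8_counts[g.cancer_counts >= np.median(g.cancer_counts)].mean()
        assert abs(hi - lo) < 2.0

    def test_closed_loop_slope_recovery(self, rng):
        cancer, cd8 = simulate_quadrat_counts(300, np.log(5) - 0.017 * 28,
                                              0.017, 2.0, rng)
        res = SubjectSlopeModel(cancer, cd8).fit()
        assert abs(res.beta - 0.017) < 3 * res.beta_se

    def test_nb_moment_identity(self, rng):
        m, theta = 6.0, 2.0
        lam = rng.gamma(theta, m / theta, 10_000)
        draws = rng.poisson(lam)
        assert draws.mean() == pytest.approx(m, rel=0.05)
        assert draws.var() == pytest.approx(m + m**2 / theta, rel=0.15)

    def test_continuous_mode_b_zero_is_poisson(self, rng):
        cancer, grid = self._grid(rng)
        pts = simulate_cd8_given_cancer(cancer, grid, np.log(30), 0.0, 2.0,
                                        rng, mode="continuous")
        pat = SubjectPattern("A", cancer, pts, Window(0, 4, 0, 4))
        g = make_quadrat_grid(pat, 0.5)
        ratio = g.cd8_counts.var() / g.cd8_counts.mean()
        assert ratio == pytest.approx(1.0, abs=0.35)

    def test_invalid_mode(self, rng):
        cancer, grid = self._grid(rng)
        with pytest.raises(ValueError, match="unknown mode"):
            simulate_cd8_given_cancer(cancer, grid, 0, 0, 2, rng, mode="nope")


class TestClinicalSurvival:
    def _slopes(self, n=66, rng=None):
        rng = rng or np.random.default_rng(5)
        arm = np.array(["naive"] * 27 + ["NAT"] * (n - 27))
        return pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "treatment": arm,
            "beta": np.exp(np.log(0.012) + 0.6 * rng.standard_normal(n)),
        })

    def test_event_fraction_near_73_percent(self):
        truth = SyntheticTruth()
        fracs = []
        for seed in range(8):
            clin = simulate_clinical_and_survival(
                truth, self._slopes(), np.random.default_rng(seed))
            fracs.append(clin["event"].mean())
        assert abs(np.mean(fracs) - 0.73) <= 0.05

    def test_null_hazard_groups_similar(self):
        truth = SyntheticTruth(loghr_slope_group=0.0, loghr_treatment=0.0)
        from lifelines.statistics import logrank_test

        pvals = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            clin = simulate_clinical_and_survival(truth, self._slopes(rng=rng), rng)
            g = clin.merge(self._slopes(rng=np.random.default_rng(seed)),
                           on="subject_id")
            hi = g["beta"] >= g["beta"].median()
            res = logrank_test(g.loc[hi, "time"], g.loc[~hi, "time"],
                               g.loc[hi, "event"], g.loc[~hi, "event"])
            pvals.append(res.p_value)
        # under the null, small p-values are not enriched
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_covariate_margins(self):
        clin = simulate_clinical_and_survival(
            SyntheticTruth(), self._slopes(n=600), np.random.default_rng(1))
        assert clin["sex"].eq("male").mean() == pytest.approx(0.545, abs=0.08)
        assert clin["grade"].value_counts(normalize=True)["G2"] == pytest.approx(
            0.50, abs=0.08)
        assert abs(np.median(clin["age"]) - 70) < 3
        assert (clin["time"] > 0).all()


class TestCohortDeterminism:
    def test_same_seed_identical_tables(self, small_truth):
        a = simulate_cohort(small_truth, seed=42)
        b = simulate_cohort(small_truth, seed=42)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        pd.testing.assert_frame_equal(
            cohort_to_cell_table(a), cohort_to_cell_table(b))
        pd.testing.assert_frame_equal(a.subject_params, b.subject_params)

    def test_different_seed_differs(self, small_truth):
        a = simulate_cohort(small_truth, seed=1)
        b = simulate_cohort(small_truth, seed=2)
        assert not cohort_to_cell_table(a).equals(cohort_to_cell_table(b))

    def test_cohort_scale_matches_study_conditions(self, small_cohort):
        for p in small_cohort.patterns:
            assert 100 <= p.n_cancer <= 10_000
            assert p.n_cd8 >= 30
        assert set(small_cohort.clinical.columns) >= {
            "subject_id", "treatment", "sex", "age", "grade", "stage",
            "time", "event"}


def test_asymptotic_unbiasedness_of_generative_twin(rng):
    """With many quadrats, the fitted slope converges on the generator's."""
    cancer, cd8 = simulate_quadrat_counts(1000, np.log(5) - 0.0078 * 28,
                                          0.0078, 2.0, rng)
    res = SubjectSlopeModel(cancer, cd8).fit()
    assert res.beta == pytest.approx(0.0078, abs=2.5 * res.beta_se)
    assert res.beta_se < 0.004
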