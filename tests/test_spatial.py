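import numpy as np
import pytest
from hypothesis import given, strategies as st

from tilspatial.io import SubjectPattern, Window
from tilspatial.spatial import (
    density_map,
    filter_tils,
    make_quadrat_grid,
    nearest_cancer_distance,
    quadrat_summaries,
)


class TestNearestDistance:
    def test_coincident_is_zero(self):
        assert nearest_cancer_distance([[0.0, 0.0]], [[0.0, 0.0]])[0] == 0.0

    def test_three_four_five_triangle(self):
        # 0.03/0.04 mm legs -> 0.05 mm = 50 um hypotenuse
        d = nearest_cancer_distance([[0.0, 0.0]], [[0.03, 0.04]])
        assert d[0] == pytest.approx(50.0, abs=1e-9)

    def test_empty_cancer_set_errors(self):
        with pytest.raises(ValueError, match="no cancer cells"):
            nearest_cancer_distance([[0.0, 0.0]], np.empty((0, 2)))

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        cd8 = rng.uniform(0, 8, size=(200, 2))
        cancer = rng.uniform(0, 8, size=(500, 2))
        fast = nearest_cancer_distance(cd8, cancer)
        brute = np.sqrt(
            ((cd8[:, None, :] - cancer[None, :, :]) ** 2).sum(-1)
        ).min(axis=1) * 1e3
        np.testing.assert_allclose(fast, brute, atol=1e-9)


def _pattern_with_distances(dists_um):
    """CD8 cells along the x-axis at given um distances from one cancer cell."""
    cancer = np.array([[0.0, 0.0]])
    cd8 = np.column_stack([np.asarray(dists_um) * 1e-3, np.zeros(len(dists_um))])
    all_x = np.concatenate([cd8[:, 0], [0.0]])
    w = Window(min(all_x) - 0.01, max(all_x) + 0.01, -0.01, 0.01)
    return SubjectPattern("A", cancer, cd8, w)


class TestFilterTils:
    def test_exactly_50_um_is_kept(self):
        pat = _pattern_with_distances([50.0])
        assert filter_tils(pat).n_cd8 == 1

    def test_just_over_50_um_is_removed(self):
        pat = _pattern_with_distances([50.1])
        assert filter_tils(pat).n_cd8 == 0

    def test_oracle_count(self, rng):
        dists = rng.uniform(0, 150, 100)
        expected = int((dists <= 50.0).sum())
        pat = _pattern_with_distances(dists)
        filt = filter_tils(pat)
        assert filt.n_cd8 == expected
        assert filt.n_cancer == pat.n_cancer  # cancer untouched

    def test_precomputed_distance_column_takes_precedence(self):
        pat = _pattern_with_distances([10.0])
        pat.cd8_dist_um = np.array([120.0])  # platform says: far from gland
        filt = filter_tils(pat)
        assert filt.n_cd8 == 0
        assert filt.dist_source == "platform"
        geo = filter_tils(pat, use_precomputed=False)
        assert geo.n_cd8 == 1 and geo.dist_source == "nearest-centroid"

    def test_idempotent_and_monotone(self, rng):
        pat = _pattern_with_distances(rng.uniform(0, 120, 60))
        once = filter_tils(pat)
        twice = filter_tils(once)
        assert once.n_cd8 == twice.n_cd8
        assert filter_tils(pat, 30.0).n_cd8 <= filter_tils(pat, 80.0).n_cd8


class TestQuadratGrid:
    def test_single_point_conserved_on_2x2(self):
        pat = SubjectPattern("A", [[0.3, 0.8]], np.empty((0, 2)), Window(0, 1, 0, 1))
        g = make_quadrat_grid(pat, 0.5)
        assert (g.n_rows, g.n_cols) == (2, 2)
        assert g.cancer_counts.sum() == 1

    def test_interior_boundary_goes_right(self):
        pat = SubjectPattern("A", [[0.5, 0.25]], [[0.1, 0.1]], Window(0, 1, 0, 1))
        g = make_quadrat_grid(pat, 0.5)
        assert g.cancer_counts[0, 1] == 1  # x == x0 + 0.5 -> right-hand quadrat

    def test_max_edge_point_not_lost(self):
        pat = SubjectPattern("A", [[1.0, 1.0]], [[0.0, 0.0]], Window(0, 1, 0, 1))
        g = make_quadrat_grid(pat, 0.5)
        assert g.cancer_counts.sum() == 1
        assert g.cancer_counts[1, 1] == 1

    def test_counts_match_brute_force_binning(self, rng):
        pts = rng.uniform(0, 7.3, size=(1000, 2))
        cd8 = rng.uniform(0, 7.3, size=(400, 2))
        w = Window(0, 7.3, 0, 7.3)
        g = make_quadrat_grid(SubjectPattern("A", pts, cd8, w), 0.5)
        n = g.n_cols
        brute = np.zeros((g.n_rows, n), dtype=int)
        for x, y in pts:  # independent per-point loop oracle
            j = min(int(x / 0.5), n - 1)
            i = min(int(y / 0.5), g.n_rows - 1)
            brute[i, j] += 1
        np.testing.assert_array_equal(g.cancer_counts, brute)
        assert g.cancer_counts.sum() == 1000
        assert g.cd8_counts.sum() == 400

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_translation_equivariance(self, dx, dy):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 3, size=(60, 2))
        w = Window(0, 3, 0, 3)
        g0 = make_quadrat_grid(SubjectPattern("A", pts, pts[:10], w), 0.5)
        shift = np.array([dx, dy])
        w1 = Window(dx, 3 + dx, dy, 3 + dy)
        g1 = make_quadrat_grid(SubjectPattern("A", pts + shift, pts[:10] + shift, w1), 0.5)
        np.testing.assert_array_equal(g0.cancer_counts, g1.cancer_counts)

    def test_active_mask_definition(self):
        pat = SubjectPattern("A", [[0.1, 0.1]], [[0.9, 0.9]], Window(0, 1, 0, 1))
        g = make_quadrat_grid(pat, 0.5)
        assert g.active_mask.sum() == 2  # one cancer-only + one cd8-only quadrat


class TestQuadratSummaries:
    def _grid(self, cancer, cd8):
        cancer, cd8 = np.atleast_2d(cancer), np.atleast_2d(cd8)
        from tilspatial.spatial import QuadratGrid

        return QuadratGrid("A", (0, 0), 0.5, cancer.shape[0], cancer.shape[1],
                           cancer, cd8)

    def test_constant_counts(self):
        s = quadrat_summaries(self._grid([[2, 2, 2]], [[1, 1, 1]]))
        assert s.quadrat_mean_cancer == 2 and s.quadrat_sd_cancer == 0

    def test_hand_arithmetic_sample_sd(self):
        # active counts cancer {0,4}, cd8 {1,0}; sample SD of {0,4} = sqrt(8)
        s = quadrat_summaries(self._grid([[0, 4]], [[1, 0]]))
        assert s.quadrat_mean_cancer == 2.0
        assert s.quadrat_sd_cancer == pytest.approx(np.sqrt(8.0))

    def test_single_active_quadrat_warns_sd_zero(self, caplog):
        with caplog.at_level("WARNING"):
            s = quadrat_summaries(self._grid([[5, 0]], [[0, 0]]))
        assert s.quadrat_sd_cancer == 0.0
        assert "single active quadrat" in caplog.text

    def test_zero_zero_quadrats_excluded_from_summaries(self):
        s_with = quadrat_summaries(self._grid([[5, 3, 0, 0]], [[1, 0, 0, 0]]))
        assert s_with.n_active == 2
        assert s_with.quadrat_mean_cancer == 4.0


class TestDensityMap:
    def test_single_point_mass_conserved(self):
        w = Window(0, 2, 0, 2)
        dm = density_map(np.array([[1.0, 1.0]]), w, bandwidth=0.3, resolution=0.02)
        mass = dm.values.sum() * dm.pixel_size**2
        assert mass == pytest.approx(1.0, rel=0.02)
        assert (dm.values >= 0).all()

    def test_linearity_for_coincident_points(self):
        w = Window(0, 2, 0, 2)
        one = density_map(np.array([[1.0, 1.0]]), w, 0.3, 0.02)
        two = density_map(np.array([[1.0, 1.0], [1.0, 1.0]]), w, 0.3, 0.02)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)

    def test_uniform_pattern_mean_intensity(self, rng):
        pts = rng.uniform(0, 1, size=(10_000, 2))
        dm = density_map(pts, Window(0, 1, 0, 1), bandwidth=0.1, resolution=0.02)
        # interior pixels, away from uncorrected edges
        vals = dm.values[10:-10, 10:-10]
        assert vals.mean() == pytest.approx(10_000, rel=0.05)

    def test_bad_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            density_map(np.array([[0.5, 0.5]]), Window(0, 1, 0, 1), bandwidth=0.0)
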