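import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_pairs
from smlmnet.graphnet import (
    build_graph,
    degrees,
    find_scales,
    merge_blinks,
    randomize,
    ripley_h,
    RipleyCurve,
)
from smlmnet.locio import LocalizationTable
from smlmnet.simulate import simulate_corners, simulate_csr


class TestBuildGraph:
    def test_collinear_points(self):
        table = LocalizationTable(coords=np.array(
            [[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]]))
        g = build_graph(table, 12.0)
        assert set(map(tuple, g.edge_pairs())) == {(0, 1), (1, 2)}

    def test_r_zero_no_edges(self, small_table):
        assert build_graph(small_table, 0.0).n_edges == 0

    def test_exact_distance_is_an_edge(self):
        table = LocalizationTable(coords=np.array([[0.0, 0.0], [10.0, 0.0]]))
        assert build_graph(table, 10.0).n_edges == 1

    def test_empty_table(self):
        g = build_graph(LocalizationTable(coords=np.empty((0, 2))), 5.0)
        assert g.n_nodes == 0 and g.n_edges == 0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 80))
        coords = rng.uniform(0, 100, size=(n, 2))
        r = float(rng.uniform(1, 40))
        g = build_graph(LocalizationTable(coords=coords), r)
        assert sorted(map(tuple, g.edge_pairs())) == brute_force_pairs(coords, r)

    def test_edge_distances_below_r(self, small_table):
        g = build_graph(small_table, 30.0)
        assert np.all(g.edge_dist <= 30.0)


class TestDegrees:
    @pytest.mark.parametrize("coords,r,expected", [
        # equilateral triangle, all pairs connected
        (np.array([[0.0, 0], [10, 0], [5, 8.66]]), 12, [2, 2, 2]),
        # path of three collinear points
        (np.array([[0.0, 0], [10, 0], [20, 0]]), 12, [1, 2, 1]),
        # isolated node far from a connected pair
        (np.array([[0.0, 0], [5, 0], [500, 0]]), 12, [1, 1, 0]),
    ])
    def test_known_degree_vectors(self, coords, r, expected):
        g = build_graph(LocalizationTable(coords=coords), r)
        np.testing.assert_array_equal(degrees(g), expected)

    def test_degree_sum_is_twice_edges(self, small_table):
        g = build_graph(small_table, 40.0)
        assert degrees(g).sum() == 2 * g.n_edges


class TestMergeBlinks:
    def test_close_pair_replaced_by_midpoint(self):
        table = LocalizationTable(coords=np.array([[0.0, 0.0], [5.0, 0.0]]))
        merged, mmap = merge_blinks(table, 10.0)
        assert merged.n == 1
        np.testing.assert_allclose(merged.coords, [[2.5, 0.0]])
        np.testing.assert_array_equal(mmap, [0, 0])

    def test_far_pair_unchanged(self):
        table = LocalizationTable(coords=np.array([[0.0, 0.0], [15.0, 0.0]]))
        merged, mmap = merge_blinks(table, 10.0)
        np.testing.assert_array_equal(merged.coords, table.coords)

    def test_closest_pair_first_hand_trace(self):
        # 0, 8, 16: ties 0-1 and 1-2 both at 8 nm -> lowest index pair first,
        # centroid 4; then d(4, 16) = 12 > 10 stops the iteration
        table = LocalizationTable(
            coords=np.array([[0.0, 0.0], [8.0, 0.0], [16.0, 0.0]]))
        merged, mmap = merge_blinks(table, 10.0)
        assert sorted(merged.coords[:, 0].tolist()) == [4.0, 16.0]
        # rows 0 and 1 merged together; row 2 alone
        assert mmap[0] == mmap[1] != mmap[2]

    def test_zero_threshold_is_identity(self, small_table):
        merged, mmap = merge_blinks(small_table, 0.0)
        np.testing.assert_array_equal(merged.coords, small_table.coords)
        np.testing.assert_array_equal(mmap, np.arange(small_table.n))

    @settings(max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_contraction_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 60, size=(30, 2))
        table = LocalizationTable(coords=coords)
        merged, mmap = merge_blinks(table, 8.0)
        assert merged.n <= table.n
        assert mmap.max() == merged.n - 1
        # output has no pair closer than the threshold
        if merged.n >= 2:
            from scipy.spatial.distance import pdist
            assert pdist(merged.coords).min() > 8.0
        again, mmap2 = merge_blinks(merged, 8.0)
        np.testing.assert_array_equal(again.coords, merged.coords)
        np.testing.assert_array_equal(mmap2, np.arange(merged.n))


class TestRipleyH:
    def test_two_point_k_formula(self):
        # K(r) = measure * count / (n (n-1)); two points 10 nm apart in a
        # 1000x1000 box: K(5) = 0, K(15) = 1e6 * 2 / 2 = 1e6
        table = LocalizationTable(
            coords=np.array([[500.0, 500.0], [510.0, 500.0]]),
            roi=np.array([[0.0, 1000.0], [0.0, 1000.0]]),
        )
        curve = ripley_h(table, np.array([5.0, 15.0]))
        K5 = np.pi * (curve.H[0] + 5.0) ** 2
        K15 = np.pi * (curve.H[1] + 15.0) ** 2
        assert K5 == pytest.approx(0.0)
        assert K15 == pytest.approx(1e6)

    def test_csr_mean_near_zero(self):
        # the H expectation is 0 under CSR; average a few modest fields
        roi = np.array([[0.0, 5000.0], [0.0, 5000.0]])
        radii = np.arange(10.0, 51.0, 10.0)
        H = np.mean(
            [ripley_h(simulate_csr(2000, roi, seed=s), radii).H
             for s in range(8)],
            axis=0,
        )
        assert np.abs(H).max() < 2.0

    def test_insufficient_points(self):
        table = LocalizationTable(coords=np.array([[1.0, 1.0]]),
                                  roi=np.array([[0, 10.0], [0, 10.0]]))
        with pytest.raises(ValueError, match="insufficient"):
            ripley_h(table, np.array([1.0, 2.0]))

    def test_radii_must_increase(self, small_table):
        with pytest.raises(ValueError):
            ripley_h(small_table, np.array([5.0, 5.0]))

    def test_3d_normalization(self):
        # two points 10 nm apart in a 100^3 box: K(15) = 1e6*2/2 = 1e6,
        # L = (3K/4pi)^(1/3)
        table = LocalizationTable(
            coords=np.array([[50.0, 50, 50], [60.0, 50, 50]]),
            roi=np.tile([0.0, 100.0], (3, 1)),
        )
        curve = ripley_h(table, np.array([15.0]))
        expected_L = (3 * 1e6 / (4 * np.pi)) ** (1 / 3)
        assert curve.H[0] == pytest.approx(expected_L - 15.0)


class TestFindScales:
    def _curve(self, radii, H):
        return RipleyCurve(radii=np.asarray(radii, float),
                           H=np.asarray(H, float), n=100,
                           region_measure=1e6, dim=2)

    def test_symmetric_bump_peak(self):
        radii = np.arange(100.0, 137.0, 2.0)
        H = -((radii - 118.0) ** 2)
        scales = find_scales(self._curve(radii, H))
        assert scales.peak_radius == 118.0

    def test_two_scale_synthetic(self):
        # tight sub-clusters on a pore-scale ring: the H peak sits within
        # one grid step of the ring scale
        from smlmnet.simulate import preset_config, simulate_npc_field
        cfg = preset_config("nup96_2d", n_pores=40, loc_sd=3.0, seed=5)
        table, _ = simulate_npc_field(cfg)
        radii = np.arange(4.0, 250.0, 4.0)
        scales = find_scales(ripley_h(table, radii))
        assert scales.has_peak
        # the argmax of H for an octagon field sits near the ring scale
        assert 80.0 <= scales.peak_radius <= 160.0

    def test_monotone_decreasing_is_flagged(self):
        radii = np.arange(1.0, 11.0)
        scales = find_scales(self._curve(radii, -radii))
        assert not scales.has_peak and scales.peak_radius is None

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            find_scales(self._curve([1, 2, 3], [0, 1, 0]))


class TestRandomize:
    def test_preserves_n_and_respects_roi(self, small_table):
        out = randomize(small_table, seed=3)
        assert out.n == small_table.n
        assert np.all(out.coords >= small_table.roi[:, 0])
        assert np.all(out.coords <= small_table.roi[:, 1])

    def test_seed_reproducibility(self, small_table):
        a = randomize(small_table, seed=5)
        b = randomize(small_table, seed=5)
        c = randomize(small_table, seed=6)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)

    def test_csr_mean_degree_matches_brute_force(self):
        roi = np.array([[0.0, 2000.0], [0.0, 2000.0]])
        table = simulate_csr(500, roi, seed=9)
        out = randomize(table, seed=11)
        r = 50.0
        deg = degrees(build_graph(out, r))
        brute = len(brute_force_pairs(out.coords, r))
        assert deg.sum() == 2 * brute
        # CSR expectation (ignoring edges): (n-1) * pi r^2 / A
        expected = (out.n - 1) * np.pi * r**2 / 4e6
        assert deg.mean() == pytest.approx(expected, rel=0.35)
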