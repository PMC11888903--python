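"""Vietoris-Rips engine: examples, closed forms and engine cross-checks."""

import numpy as np
import pytest

from phca import (
    FiltrationParams,
    PointCloud,
    UnsupportedError,
    brute_force_persistence,
    h0_persistence_mst,
    max_scale,
    total_lifespan,
    vr_persistence,
)
from phca.persistence import h0_total_lifespan
from phca.synthetic import make_shape_cloud

from conftest import diagram_multiset, random_cloud

SQRT2_2 = np.sqrt(2.0) / 2.0


class TestMaxScale:
    @pytest.mark.parametrize(
        "coords, expected",
        [
            ([(0, 0), (3, 4)], 2.5),          # half of d = 5
            ([0, 1, 3], 1.5),                 # half the line diameter
            ([(7, 7)], 0.0),                  # no pair exists
            ([], 0.0),
        ],
    )
    def test_half_max_pairwise_distance(self, coords, expected):
        assert max_scale(PointCloud.from_coords(coords)) == pytest.approx(expected)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            PointCloud.from_coords([(0.0, np.nan)])


class TestVRPersistence:
    def test_two_points_merge_at_half_distance(self):
        diagram = vr_persistence(PointCloud.from_coords([(0, 0), (3, 4)]))
        assert diagram_multiset(diagram) == [(0, 0.0, 2.5), (0, 0.0, 2.5)]
        assert diagram.capped.sum() == 1

    def test_collinear_mst_merges(self):
        diagram = vr_persistence(PointCloud.from_coords([0, 1, 3]))
        dim0 = diagram.in_dims({0})
        assert diagram_multiset(dim0) == [(0, 0.0, 0.5), (0, 0.0, 1.0), (0, 0.0, 1.5)]
        # any 1-cycle on a line fills instantly: no positive-lifespan loops
        dim1 = diagram.in_dims({1})
        assert np.all(dim1.lifespans() == 0)

    def test_unit_square_loop(self, unit_square):
        diagram = vr_persistence(unit_square, FiltrationParams(max_dimension=1))
        assert diagram_multiset(diagram.in_dims({0})) == [
            (0, 0.0, 0.5)] * 3 + [(0, 0.0, round(SQRT2_2, 9))]
        loops = diagram_multiset(diagram.in_dims({1}), drop_zero=True)
        assert loops == [(1, 0.5, round(SQRT2_2, 9))]

    def test_empty_cloud_gives_empty_diagram(self):
        assert len(vr_persistence(PointCloud(np.zeros((0, 2))))) == 0

    def test_single_point_is_one_capped_bar(self):
        diagram = vr_persistence(PointCloud.from_coords([(7, 7)]))
        assert diagram.rows() == [(0, 0.0, 0.0, True)]

    def test_dimension_two_unsupported(self, unit_square):
        with pytest.raises(UnsupportedError):
            vr_persistence(unit_square, FiltrationParams(max_dimension=2))

    def test_explicit_horizon_caps_unmerged_components(self):
        # horizon below the merge scale: both components stay alive
        diagram = vr_persistence(
            PointCloud.from_coords([(0, 0), (3, 4)]),
            FiltrationParams(max_dimension=0, max_scale=1.0),
        )
        assert diagram.rows() == [(0, 0.0, 1.0, True), (0, 0.0, 1.0, True)]


class TestH0MSTPath:
    def test_matches_line_example(self):
        diagram = h0_persistence_mst(PointCloud.from_coords([0, 1, 3]))
        assert diagram_multiset(diagram) == [(0, 0.0, 0.5), (0, 0.0, 1.0), (0, 0.0, 1.5)]

    def test_two_points(self):
        diagram = h0_persistence_mst(PointCloud.from_coords([(0, 0), (3, 4)]))
        assert diagram_multiset(diagram) == [(0, 0.0, 2.5), (0, 0.0, 2.5)]

    def test_duplicate_points_yield_zero_bars(self):
        diagram = h0_persistence_mst(PointCloud.from_coords([(1, 1), (1, 1), (4, 5)]))
        assert diagram_multiset(diagram) == [(0, 0.0, 0.0), (0, 0.0, 2.5), (0, 0.0, 2.5)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_general_engine_dim0(self, seed):
        cloud = random_cloud(seed, n=30, dim=3)
        fast = diagram_multiset(h0_persistence_mst(cloud))
        general = diagram_multiset(vr_persistence(cloud, FiltrationParams(0)).in_dims({0}))
        assert fast == general


class TestBruteForceOracle:
    def test_equilateral_triangle_fills_instantly(self):
        side = PointCloud.from_coords([(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)])
        diagram = brute_force_persistence(side)
        assert diagram_multiset(diagram.in_dims({0})) == [(0, 0.0, 0.5)] * 3
        assert np.all(diagram.in_dims({1}).lifespans() == pytest.approx(0.0))

    def test_unit_square_loop(self, unit_square):
        diagram = brute_force_persistence(unit_square)
        loops = diagram_multiset(diagram.in_dims({1}), drop_zero=True)
        assert loops == [(1, 0.5, round(SQRT2_2, 9))]

    def test_single_point(self):
        diagram = brute_force_persistence(PointCloud.from_coords([(7, 7)]))
        assert diagram.rows() == [(0, 0.0, 0.0, True)]

    def test_size_limit(self):
        with pytest.raises(ValueError):
            brute_force_persistence(PointCloud(np.zeros((11, 2))))


class TestTotalLifespan:
    def test_empty_diagram(self):
        assert total_lifespan(vr_persistence(PointCloud(np.zeros((0, 1)))), {0}) == 0.0

    def test_two_point_total(self):
        diagram = vr_persistence(PointCloud.from_coords([(0, 0), (3, 4)]))
        assert total_lifespan(diagram, {0}) == pytest.approx(5.0)

    def test_unit_square_both_dims(self, unit_square):
        diagram = vr_persistence(unit_square, FiltrationParams(1))
        assert total_lifespan(diagram, {0, 1}) == pytest.approx(1.5 + SQRT2_2 + (SQRT2_2 - 0.5))

    def test_empty_dims_rejected(self, unit_square):
        with pytest.raises(ValueError):
            total_lifespan(vr_persistence(unit_square), set())


class TestEngineProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_h0_total_equals_mst_closed_form(self, seed):
        """Total H0 lifespan = maxsc + half the MST edge-weight sum."""
        rng = np.random.default_rng(seed)
        cloud = PointCloud(rng.normal(size=(int(rng.integers(2, 40)), int(rng.integers(1, 6)))))
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial.distance import pdist, squareform

        mst_sum = minimum_spanning_tree(squareform(pdist(cloud.points))).sum()
        expected = max_scale(cloud) + mst_sum / 2.0
        assert h0_total_lifespan(cloud) == pytest.approx(expected, abs=1e-10)
        assert total_lifespan(vr_persistence(cloud, FiltrationParams(0)), {0}) == pytest.approx(
            expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_small_clouds(self, seed):
        """Fast engine and boundary-matrix oracle agree modulo zero bars."""
        cloud = random_cloud(seed)
        fast = diagram_multiset(vr_persistence(cloud), drop_zero=True)
        oracle = diagram_multiset(brute_force_persistence(cloud), drop_zero=True)
        assert fast == oracle

    @pytest.mark.parametrize("scale", [0.5, 2.0, 17.0])
    def test_scaling_coordinates_scales_diagram(self, scale):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        base = vr_persistence(PointCloud(pts))
        scaled = vr_persistence(PointCloud(pts * scale))
        assert np.allclose(scaled.births, base.births * scale)
        assert np.allclose(scaled.deaths, base.deaths * scale)

    @pytest.mark.parametrize("seed", range(8))
    def test_all_deaths_capped_at_horizon(self, seed):
        cloud = random_cloud(seed, n=15)
        diagram = vr_persistence(cloud)
        horizon = max_scale(cloud)
        assert np.all(diagram.deaths <= horizon + 1e-12)
        assert np.all(diagram.births <= diagram.deaths + 1e-12)
        dim0 = diagram.in_dims({0})
        assert int(dim0.capped.sum()) == 1

    def test_dense_circle_has_one_dominant_loop(self):
        cloud = make_shape_cloud("circle", n=100, noise=0.0, seed=0)
        lifespans = np.sort(vr_persistence(cloud).in_dims({1}).lifespans())
        assert lifespans[-1] > 5 * lifespans[-2]


class TestSerialization:
    def test_csv_round_trip(self, tmp_path, unit_square):
        diagram = vr_persistence(unit_square)
        path = tmp_path / "diagram.csv"
        diagram.to_csv(path)
        back = type(diagram).from_csv(path, diagram.source_max_scale)
        assert diagram_multiset(back, decimals=15) == diagram_multiset(diagram, decimals=15)
        assert list(back.capped) == list(diagram.capped)
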