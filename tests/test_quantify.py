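"""Network statistics: counts, angles, orientation, distance/density fields,
zone comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import conduitmap as cm
from conduitmap import VolumeImage
from conduitmap.network import ConduitNetwork
from conduitmap.quantify import REFERENCE_AXES


def straight_edge_net(length=10.0, radius=1.45, direction=(1.0, 0.0, 0.0)):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    net = ConduitNetwork()
    a = net.add_vertex((0, 0, 0))
    b = net.add_vertex(d * length)
    net.add_edge(a, b, [[0, 0, 0, radius], [*(d * length), radius]])
    return net


class TestSegmentStats:
    def test_cylinder_volume(self):
        net = straight_edge_net(length=10.0, radius=1.45)
        stats = cm.segment_stats(net)
        assert stats.n_segments == 1
        assert stats.total_length == pytest.approx(10.0)
        assert stats.conduit_volume == pytest.approx(np.pi * 1.45**2 * 10, rel=1e-9)

    def test_empty_network_all_zero(self):
        stats = cm.segment_stats(ConduitNetwork())
        assert stats.n_segments == 0 and stats.n_vertices == 0
        assert stats.total_length == 0.0 and stats.conduit_volume == 0.0

    def test_density_from_region_volume(self):
        net = straight_edge_net()
        stats = cm.segment_stats(net, region_volume=1e-4)
        assert stats.segment_density == pytest.approx(1e4)


class TestBranchingAngles:
    def planar_y(self, arm=20.0):
        net = ConduitNetwork()
        c = net.add_vertex((0, 0, 0))
        for k in range(3):
            ang = np.radians(120 * k)
            tip = np.array([np.cos(ang), np.sin(ang), 0.0]) * arm
            v = net.add_vertex(tip)
            net.add_edge(c, v, [[0, 0, 0, 1], [*tip, 1]])
        return net

    def test_symmetric_y_gives_120_degrees(self):
        angles = cm.branching_angles(self.planar_y())
        assert len(angles) == 3
        assert np.allclose(angles, 120.0, atol=1.0)

    def test_short_edges_filtered(self):
        net = self.planar_y()
        c = 0
        tip = net.add_vertex((0.0, 0.0, 3.0))
        net.add_edge(c, tip, [[0, 0, 0, 1], [0, 0, 3, 1]])  # 3 um arm
        angles = cm.branching_angles(net, min_len=4.0)
        assert len(angles) == 3  # the short arm contributes no pairs

    def test_degree_two_vertices_emit_nothing(self):
        net = ConduitNetwork()
        a = net.add_vertex((0, 0, 0)); b = net.add_vertex((10, 0, 0))
        c = net.add_vertex((20, 5, 0))
        net.add_edge(a, b, [[0, 0, 0, 1], [10, 0, 0, 1]])
        net.add_edge(b, c, [[10, 0, 0, 1], [20, 5, 0, 1]])
        assert len(cm.branching_angles(net)) == 0


class TestOrientationDistribution:
    def test_axis_aligned_segments(self):
        net = straight_edge_net(direction=(1, 0, 0))
        dist = cm.orientation_distribution(net)
        expected_max = 1.0 / (1.0 + 4.0 / np.sqrt(2) + 4.0 / np.sqrt(3))
        assert dist.weights[0] == pytest.approx(expected_max, abs=1e-9)
        assert dist.weights[0] == dist.weights.max()
        # axes orthogonal to x get zero projection
        ortho = [i for i, ax in enumerate(REFERENCE_AXES) if abs(ax[0]) < 1e-12]
        assert np.allclose(dist.weights[ortho], 0.0)
        assert dist.weights.sum() == pytest.approx(1.0)

    def test_subdivision_invariance(self):
        rng = np.random.default_rng(5)
        net = ConduitNetwork()
        whole = straight_edge_net(direction=rng.normal(size=3), length=20.0)
        w1 = cm.orientation_distribution(whole).weights
        # same segment split into two collinear halves
        d = whole.edges[0].xyz[1] / 20.0
        a = net.add_vertex((0, 0, 0))
        m = net.add_vertex(d * 8.0)
        b = net.add_vertex(d * 20.0)
        net.add_edge(a, m, [[0, 0, 0, 1], [*(d * 8.0), 1]])
        net.add_edge(m, b, [[*(d * 8.0), 1], [*(d * 20.0), 1]])
        w2 = cm.orientation_distribution(net).weights
        assert np.abs(w1 - w2).max() < 1e-9

    def test_isotropic_segments_balance_axis_classes(self):
        rng = np.random.default_rng(7)
        net = ConduitNetwork()
        for _ in range(20000):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            a = net.add_vertex(rng.uniform(0, 100, 3))
            p = net.vertices[a]
            q = p + d * 6.0
            b = net.add_vertex(q)
            net.add_edge(a, b, [[*p, 1], [*q, 1]])
        w = cm.orientation_distribution(net).weights
        coord, face, body = w[:3], w[3:9], w[9:]
        for group in (coord, face, body):
            assert group.max() / group.min() < 1.05


class TestDistanceField:
    def test_conduit_voxels_have_zero_distance(self):
        data = np.zeros((8, 8, 8), np.uint8)
        data[4, 4, 4] = 1
        df = cm.distance_field(VolumeImage(data, role="mask"))
        assert df.grid[4, 4, 4] == 0.0

    def test_three_four_five(self):
        data = np.zeros((10, 10, 10), np.uint8)
        data[0, 0, 0] = 1
        df = cm.distance_field(VolumeImage(data, role="mask"))
        assert df.grid[0, 4, 3] == pytest.approx(5.0)

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(6, 24))
            data = (rng.random((n, n, n)) < 0.03).astype(np.uint8)
            data[tuple(rng.integers(0, n, 3))] = 1
            vol = VolumeImage(data, role="mask")
            df = cm.distance_field(vol)
            pts = np.argwhere(np.ones_like(data))
            lit = np.argwhere(data > 0)
            oracle = cdist(pts, lit).min(axis=1).reshape(data.shape)
            assert np.allclose(df.grid, oracle, atol=1e-9)

    def test_fraction_ordering_and_eval_mask(self):
        rng = np.random.default_rng(3)
        data = (rng.random((16, 16, 16)) < 0.02).astype(np.uint8)
        data[8, 8, 8] = 1
        ev = VolumeImage((rng.random((16, 16, 16)) < 0.5).astype(np.uint8),
                         role="mask")
        df = cm.distance_field(VolumeImage(data, role="mask"), eval_mask=ev)
        f = df.fractions
        assert f[4.0] <= f[6.0] <= f[8.0] <= 1.0

    def test_monotone_under_added_foreground(self):
        rng = np.random.default_rng(4)
        data = (rng.random((12, 12, 12)) < 0.02).astype(np.uint8)
        data[6, 6, 6] = 1
        a = cm.distance_field(VolumeImage(data, role="mask")).grid
        more = data.copy()
        more[2, 9, 3] = 1
        b = cm.distance_field(VolumeImage(more, role="mask")).grid
        assert (b <= a + 1e-12).all()

    def test_empty_conduit_mask_rejected(self):
        with pytest.raises(ValueError):
            cm.distance_field(VolumeImage(np.zeros((4, 4, 4), np.uint8),
                                          role="mask"))


class TestDensityField:
    def test_full_mask_is_255(self):
        vol = VolumeImage(np.ones((30, 30, 30), np.uint8), role="mask")
        df = cm.density_field(vol, cube_radius=5.0, step=2.0)
        assert (df.grid == 255).all()

    def test_empty_mask_is_0(self):
        vol = VolumeImage(np.zeros((30, 30, 30), np.uint8), role="mask")
        df = cm.density_field(vol, cube_radius=5.0, step=2.0)
        assert (df.grid == 0).all()

    def test_half_space_fractions_exact(self):
        data = np.zeros((41, 41, 41), np.uint8)
        data[:, :, 21:] = 1  # half space filled above x = 21
        vol = VolumeImage(data, role="mask")
        df = cm.density_field(vol, cube_radius=2.0, step=1.0)
        # 5-voxel cube centered at x=20 covers 2 of 5 filled columns
        assert df.grid[20, 20, 20] == np.rint(2 / 5 * 255)
        assert df.grid[20, 20, 19] == np.rint(1 / 5 * 255)
        # half coverage sits exactly between levels; ties round to even
        assert np.rint(0.5 * 255) == 128

    def test_cube_smaller_than_voxel_rejected(self):
        vol = VolumeImage(np.zeros((8, 8, 8), np.uint8), role="mask")
        with pytest.raises(ValueError):
            cm.density_field(vol, cube_radius=0.2)


class TestCompareZones:
    def test_identical_groups_t_zero_p_one(self):
        df = pd.DataFrame({"n_segments": [10, 12, 14, 16]})
        out = cm.compare_zones(df, df.copy())
        assert out.loc["n_segments", "t_statistic"] == pytest.approx(0.0)
        assert out.loc["n_segments", "p_value"] == pytest.approx(1.0)

    def test_same_distribution_not_significant(self):
        rng = np.random.default_rng(21)
        a = pd.DataFrame({"m": rng.normal(100, 10, 10)})
        b = pd.DataFrame({"m": rng.normal(100, 10, 10)})
        out = cm.compare_zones(a, b)
        assert out.loc["m", "p_value"] > 0.05

    def test_doubled_group_detected(self):
        rng = np.random.default_rng(22)
        deep = pd.DataFrame({"n": rng.normal(100, 10, 5)})
        sup = pd.DataFrame({"n": rng.normal(200, 20, 5)})
        out = cm.compare_zones(deep, sup)
        assert out.loc["n", "p_value"] < 0.05
        assert out.loc["n", "mean_deep"] < out.loc["n", "mean_superficial"]
        assert out.loc["n", "significance"] in ("*", "**", "***", "****")

    def test_zero_variance_reported_undefined(self):
        a = pd.DataFrame({"m": [5.0, 5.0, 5.0]})
        out = cm.compare_zones(a, a.copy())
        assert np.isnan(out.loc["m", "p_value"])
        assert out.loc["m", "significance"] == "undefined"

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            cm.compare_zones(pd.DataFrame({"m": [1.0]}),
                             pd.DataFrame({"m": [1.0, 2.0]}))


class TestSubregions:
    def test_centers_disjoint_inside_zone_and_deterministic(self):
        a = cm.propose_subregion_centers(5, "deep", 130.0, 250.0, seed=1)
        b = cm.propose_subregion_centers(5, "deep", 130.0, 250.0, seed=1)
        assert [r.center for r in a] == [r.center for r in b]
        centers = np.array([r.center for r in a])
        assert (np.linalg.norm(centers, axis=1) <= 130.0 - 50.0 + 1e-9).all()
        d = cdist(centers, centers) + np.eye(5) * 1e9
        assert d.min() >= 100.0

    def test_superficial_band_respected(self):
        regs = cm.propose_subregion_centers(4, "superficial", 130.0, 260.0,
                                            seed=2)
        r = np.linalg.norm(np.array([x.center for x in regs]), axis=1)
        assert ((r >= 180.0 - 1e-9) & (r <= 210.0 + 1e-9)).all()

    def test_impossible_zone_raises(self):
        with pytest.raises(RuntimeError):
            cm.propose_subregion_centers(5, "superficial", 130.0, 230.0,
                                         seed=3)
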