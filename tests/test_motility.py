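"""T-cell walk simulation: branch choice, propagation, Cm estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import conduitmap as cm
from conduitmap.network import ConduitNetwork


def line_net(length=1000.0):
    net = ConduitNetwork()
    a = net.add_vertex((0, 0, 0))
    b = net.add_vertex((length, 0, 0))
    net.add_edge(a, b, [[0, 0, 0, 1.0], [length, 0, 0, 1.0]])
    return net


def line_cfg(**kw):
    base = dict(mean_speed=13.0, speed_cv=0.0, n_cells=8, duration=60.0,
                sample_interval=5.0, start_radius=0.5,
                start_center=(0.0, 0.0, 0.0), seed=1)
    base.update(kw)
    return cm.MotilityConfig(**base)


class TestBranchProbabilities:
    def test_single_branch_is_certain(self):
        p = cm.branch_probabilities(np.array([1.0, 0, 0]),
                                    [np.array([0.2, 0.6, 0.0])])
        assert p == pytest.approx([1.0])

    def test_cos4_weighting(self):
        out = [np.array([1.0, 0.0, 0.0]),
               np.array([0.5, np.sqrt(3) / 2, 0.0])]  # 0 and 60 degrees
        p = cm.branch_probabilities(np.array([1.0, 0, 0]), out)
        assert p == pytest.approx([1 / 1.0625, 0.0625 / 1.0625], abs=1e-9)

    def test_backward_turns_get_floor_weight(self):
        out = [np.array([-0.5, np.sqrt(3) / 2, 0.0])]  # 120 degrees
        p = cm.branch_probabilities(np.array([1.0, 0, 0]), out,
                                    exponent=4.0, floor=0.001)
        assert p == pytest.approx([1.0])  # normalized, but weight was floor
        out2 = out + [np.array([1.0, 0.0, 0.0])]
        p2 = cm.branch_probabilities(np.array([1.0, 0, 0]), out2)
        assert p2[0] == pytest.approx(0.001 / 1.001, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(-1, 1),
                              st.floats(-1, 1)), min_size=2, max_size=6))
    def test_sums_to_one_and_permutation_invariant(self, raw):
        dirs = []
        for t in raw:
            v = np.asarray(t)
            n = np.linalg.norm(v)
            if n < 1e-3:
                v = np.array([1.0, 0.0, 0.0])
                n = 1.0
            dirs.append(v / n)
        inc = np.array([0.0, 0.0, 1.0])
        p = cm.branch_probabilities(inc, dirs)
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()
        perm = np.array(dirs)[::-1]
        q = cm.branch_probabilities(inc, list(perm))
        assert np.allclose(q, p[::-1])


class TestSimulate:
    def test_zero_speed_is_stationary(self):
        tracks = cm.simulate(line_net(), line_cfg(mean_speed=0.0))
        assert np.allclose(tracks.positions, tracks.positions[:, :1, :])
        assert cm.estimate_cm(tracks).cm == 0.0

    def test_straight_run_position(self):
        tracks = cm.simulate(line_net(1000.0), line_cfg())
        # no junction within 780 um: every cell sits at x = 13 * t
        for j, t in enumerate(tracks.times):
            assert np.allclose(tracks.positions[:, j, 0], 13.0 * t)

    def test_triangle_wave_on_short_edge(self):
        tracks = cm.simulate(line_net(100.0), line_cfg())
        # distance traveled 780 um on a 100 um edge bouncing between ends:
        # 780 mod 200 = 180 -> 20 um from the start end
        assert np.allclose(tracks.positions[:, -1, 0], 20.0, atol=1e-9)

    def test_arc_length_consistency(self, walk_phantom):
        cfg = cm.MotilityConfig(n_cells=20, seed=3, start_radius=25.0,
                                duration=30.0, sample_interval=5.0)
        tracks = cm.simulate(walk_phantom, cfg)
        step = np.linalg.norm(np.diff(tracks.positions, axis=1), axis=2)
        bound = tracks.speeds[:, None] * cfg.sample_interval + 1e-9
        assert (step <= bound).all()

    def test_deterministic_given_seed(self, walk_phantom):
        cfg = cm.MotilityConfig(n_cells=15, seed=9, start_radius=25.0,
                                duration=20.0, sample_interval=5.0)
        a = cm.simulate(walk_phantom, cfg)
        b = cm.simulate(walk_phantom, cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.speeds, b.speeds)

    def test_symmetric_cross_arm_occupancy(self):
        net = ConduitNetwork()
        c = net.add_vertex((0, 0, 0))
        arms = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                (0, 0, 1), (0, 0, -1)]
        L = 40.0
        for d in arms:
            tip = np.array(d, dtype=float) * L
            v = net.add_vertex(tip)
            net.add_edge(c, v, [[0, 0, 0, 1.0], [*tip, 1.0]])
        cfg = cm.MotilityConfig(mean_speed=13.0, speed_cv=0.0, n_cells=1200,
                                duration=60.0, sample_interval=5.0,
                                start_radius=1.0, start_center=(0, 0, 0),
                                seed=5)
        tracks = cm.simulate(net, cfg)
        final = tracks.positions[:, -1, :]
        arm_idx = np.argmax(np.abs(final), axis=1) * 2 + (
            np.take_along_axis(final, np.argmax(np.abs(final), axis=1)[:, None],
                               axis=1)[:, 0] < 0)
        counts = np.bincount(arm_idx, minlength=6)
        expected = cfg.n_cells / 6
        assert (np.abs(counts - expected) < 5 * np.sqrt(expected)).all()

    def test_empty_start_sphere_rejected(self):
        with pytest.raises(ValueError):
            cm.simulate(line_net(), line_cfg(start_center=(0, 500.0, 0)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            cm.MotilityConfig(sample_interval=7.0, duration=60.0)
        with pytest.raises(ValueError):
            cm.MotilityConfig(n_cells=0)


class TestEstimateCm:
    def test_direct_formula(self):
        times = np.array([0.0, 60.0])
        pos = np.zeros((5, 2, 3))
        pos[:, 1, 0] = 60.0  # every cell displaced exactly 60 um
        tracks = cm.TrackSet(times, pos, np.full(5, 1.0), [])
        res = cm.estimate_cm(tracks, T=60.0)
        assert res.cm == pytest.approx(3600 / 360)

    def test_straight_line_closed_form(self):
        tracks = cm.simulate(line_net(1000.0), line_cfg())
        res = cm.estimate_cm(tracks)
        assert res.cm == pytest.approx(13.0**2 * 60.0 / 6.0, rel=1e-12)
        assert res.msd[0] == 0.0

    def test_unsampled_time_rejected(self):
        tracks = cm.simulate(line_net(), line_cfg(n_cells=2))
        with pytest.raises(ValueError):
            cm.estimate_cm(tracks, T=42.0)


class TestSpiderTracks:
    def test_first_n_tracks_translated_to_origin(self, walk_phantom):
        cfg = cm.MotilityConfig(n_cells=30, seed=2, start_radius=25.0,
                                duration=20.0, sample_interval=5.0)
        tracks = cm.simulate(walk_phantom, cfg)
        df = cm.spider_tracks(tracks, n=20)
        assert set(df.cell_id) == set(range(20))
        first = df[df.t_min == 0.0]
        assert np.allclose(first[["x", "y", "z"]].to_numpy(), 0.0)


class TestVesselPathsEffect:
    def test_including_sparse_vessels_leaves_cm_within_noise(self):
        """Adding a sparse vessel tree as extra migration paths should not
        change the motility coefficient beyond Monte-Carlo noise."""
        # a single thin vessel through a well-filled conduit domain, so the
        # vessel contributes only a small fraction of the available paths
        spec = cm.PhantomSpec(domain_radius=30.0, deep_radius=14.0,
                              density_deep=2.5e6, density_superficial=2.5e6,
                              vessel_count=1, vessel_diameter_range=(4.0, 5.0),
                              noise_sd=5.0, z_modulation_amplitude=0.0, seed=6)
        ph = cm.generate_phantom(spec)

        def cm_of(image, vessel_image, subtract):
            mask = cm.segment(image, window=25.0, offset=50.0)
            if subtract:
                vmask = cm.segment(vessel_image, window=25.0, offset=50.0)
                mask = cm.mask_combine(mask, vmask, "subtract",
                                       grow=spec.sleeve_thickness + 1.0)
            else:
                vmask = cm.segment(vessel_image, window=25.0, offset=50.0)
                mask = cm.mask_combine(mask, vmask, "union")
            mask = cm.largest_component(mask)
            net = cm.heal(cm.trace(cm.skeletonize(mask), mask))
            cfg = cm.MotilityConfig(n_cells=500, seed=8, start_radius=22.0,
                                    duration=60.0, sample_interval=5.0)
            tracks = cm.simulate(net, cfg)
            disp = tracks.positions[:, -1, :] - tracks.positions[:, 0, :]
            d2 = np.sum(disp**2, axis=1)
            return d2.mean() / 360.0, d2.std(ddof=1) / np.sqrt(len(d2)) / 360.0

        cm_with, se_with = cm_of(ph.image_conduit, ph.image_vessel, False)
        cm_wo, se_wo = cm_of(ph.image_conduit, ph.image_vessel, True)
        assert abs(cm_with - cm_wo) < 3 * np.sqrt(se_with**2 + se_wo**2)
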