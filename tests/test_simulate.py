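"""Synthetic vasculature, microbubble flow, and frame rendering."""
import numpy as np
import pytest

from ulmkit import (
    DomainError,
    NoiseModel,
    generate_vessel_tree,
    get_preset,
    render_frame_stack,
    simulate_mb_flow,
)
from ulmkit.simulate import VesselSegment, _point_segment_distance


@pytest.fixture(scope="module")
def small_tree():
    return generate_vessel_tree(seed=11, fov_um=(800.0, 800.0), n_roots=2, branch_levels=3)


def _single_segment_tree(speed=1000.0, radius=15.0, fov=(600.0, 600.0)):
    tree = generate_vessel_tree(seed=0, fov_um=fov, n_roots=1, branch_levels=0)
    seg = tree.segments[0]
    seg.mean_speed_um_s = speed
    seg.radius_um = radius
    return tree


class TestVesselTree:
    def test_no_branching_gives_single_segment(self):
        tree = generate_vessel_tree(seed=3, fov_um=(500, 500), n_roots=1, branch_levels=0)
        assert len(tree.segments) == 1

    def test_full_binary_tree_segment_count(self, small_tree):
        # 2 roots × (2^(levels+1) − 1) segments
        assert len(small_tree.segments) == 2 * (2 ** 4 - 1)

    def test_same_seed_reproduces_tree(self, small_tree):
        again = generate_vessel_tree(seed=11, fov_um=(800.0, 800.0), n_roots=2, branch_levels=3)
        for a, b in zip(small_tree.segments, again.segments):
            np.testing.assert_allclose(a.start, b.start)
            np.testing.assert_allclose(a.end, b.end)
            assert a.radius_um == b.radius_um

    def test_geometry_inside_fov_and_connected(self, small_tree):
        for i, seg in enumerate(small_tree.segments):
            assert np.all(seg.start >= 0) and np.all(seg.end >= 0)
            assert seg.start[0] <= 800 and seg.end[0] <= 800
            assert seg.start[1] <= 800 and seg.end[1] <= 800
            for c in seg.children:
                np.testing.assert_allclose(small_tree.segments[c].start, seg.end)

    def test_murray_radius_rule_and_poiseuille_speeds(self, small_tree):
        for seg in small_tree.segments:
            if not seg.children:
                continue
            r3 = sum(small_tree.segments[c].radius_um ** 3 for c in seg.children)
            assert r3 == pytest.approx(seg.radius_um ** 3, rel=1e-9)
            for c in seg.children:
                child = small_tree.segments[c]
                expected = seg.mean_speed_um_s * (child.radius_um / seg.radius_um) ** 2
                assert child.mean_speed_um_s == pytest.approx(expected, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            generate_vessel_tree(seed=0, fov_um=(0, 100))
        with pytest.raises(DomainError):
            generate_vessel_tree(seed=0, n_roots=0)
        with pytest.raises(DomainError):
            VesselSegment(np.zeros(2), np.zeros(2), 5.0, 100.0)


class TestMBFlow:
    def test_zero_concentration_gives_no_transits(self, small_tree):
        assert simulate_mb_flow(small_tree, 0.0, 1000.0, 1.0, seed=1) == []

    def test_kinematics_one_micron_per_frame(self):
        tree = _single_segment_tree(speed=1000.0)
        trajs = simulate_mb_flow(tree, 30.0, 1000.0, 1.0, seed=4, lateral_jitter_um=0.0)
        assert trajs
        for tr in trajs:
            if len(tr) < 3:
                continue
            steps = np.hypot(np.diff(tr.zs_um), np.diff(tr.xs_um))
            np.testing.assert_allclose(steps, 1.0, rtol=1e-6)

    def test_frames_consecutive_and_inside_lumen(self, small_tree):
        trajs = simulate_mb_flow(small_tree, 20.0, 1000.0, 1.0, seed=5)
        assert trajs
        for tr in trajs:
            assert np.all(np.diff(tr.frames) == 1)
            pts = np.stack([tr.zs_um, tr.xs_um], axis=1)
            for sid in np.unique(tr.segment_ids):
                seg = small_tree.segments[int(sid)]
                sel = pts[tr.segment_ids == sid]
                d = _point_segment_distance(sel, seg.start, seg.end)
                assert np.all(d <= seg.radius_um + 1e-6)

    def test_poisson_calibration_of_inplane_count(self, small_tree):
        target = 25.0 * 0.64  # concentration × fov area in mm²
        means = []
        for s in range(15):
            trajs = simulate_mb_flow(small_tree, 25.0, 1000.0, 2.0, seed=100 + s)
            counts = np.zeros(2000)
            for tr in trajs:
                counts[tr.frames] += 1
            means.append(counts.mean())
        assert np.mean(means) == pytest.approx(target, rel=0.10)

    def test_doubling_concentration_doubles_count(self, small_tree):
        def mean_count(conc):
            vals = []
            for s in range(15):
                trajs = simulate_mb_flow(small_tree, conc, 1000.0, 2.0, seed=200 + s)
                counts = np.zeros(2000)
                for tr in trajs:
                    counts[tr.frames] += 1
                vals.append(counts.mean())
            return np.mean(vals)

        assert mean_count(30.0) / mean_count(15.0) == pytest.approx(2.0, rel=0.07)


class TestRendering:
    def test_single_static_mb_peaks_at_position(self):
        tree = _single_segment_tree()
        from ulmkit.simulate import MBTrajectory

        traj = MBTrajectory(frames=np.array([0]), zs_um=np.array([300.0]),
                            xs_um=np.array([200.0]), segment_ids=np.array([0]),
                            y_um=0.0, amplitude=1.0)
        spec = get_preset("MS-550S")
        stack = render_frame_stack([traj], tree, spec, 1000.0, n_frames=1,
                                   noise=NoiseModel(clutter_db=None, noise_std=0.0),
                                   attenuation_db_cm_mhz=0.0, seed=0)
        iz, ix = np.unravel_index(np.argmax(stack.frame(0)), stack.frame(0).shape)
        assert abs(iz * stack.pixel_dz_um - 300.0) <= stack.pixel_dz_um / 2 + 1e-9
        assert abs(ix * stack.pixel_dx_um - 200.0) <= stack.pixel_dx_um / 2 + 1e-9

    def test_frame_count_follows_duration(self):
        tree = _single_segment_tree()
        spec = get_preset("MS-550S")
        stack = render_frame_stack([], tree, spec, 1000.0, duration_s=0.3,
                                   noise=NoiseModel(clutter_db=None, noise_std=0.0), seed=0)
        assert stack.n_t == 300

    def test_rendering_is_linear_with_noise_disabled(self, small_tree):
        spec = get_preset("MS-550S")
        trajs = simulate_mb_flow(small_tree, 10.0, 1000.0, 0.2, seed=8)
        assert len(trajs) >= 2
        half = len(trajs) // 2
        kwargs = dict(frame_rate_hz=1000.0, duration_s=0.2, seed=42,
                      noise=NoiseModel(clutter_db=20.0, noise_std=0.0))
        full = render_frame_stack(trajs, small_tree, spec, **kwargs)
        part_a = render_frame_stack(trajs[:half], small_tree, spec, **kwargs)
        part_b = render_frame_stack(trajs[half:], small_tree, spec, **kwargs)
        background = render_frame_stack([], small_tree, spec, **kwargs)
        lhs = full.data.astype(np.float64)
        rhs = part_a.data.astype(np.float64) + part_b.data.astype(np.float64) - background.data
        np.testing.assert_allclose(lhs, rhs, atol=1e-4 * np.abs(lhs).max())

    def test_two_mb_separability_by_distance(self):
        tree = _single_segment_tree()
        from ulmkit.simulate import MBTrajectory

        spec = get_preset("MS-550S")
        lam = spec.wavelength_um()
        lateral_fwhm = 2 * lam

        def render_pair(separation):
            trajs = [
                MBTrajectory(np.array([0]), np.array([300.0]), np.array([200.0]),
                             np.array([0]), 0.0, 1.0),
                MBTrajectory(np.array([0]), np.array([300.0]), np.array([200.0 + separation]),
                             np.array([0]), 0.0, 1.0),
            ]
            stack = render_frame_stack(trajs, tree, spec, 1000.0, n_frames=1,
                                       noise=NoiseModel(clutter_db=None, noise_std=0.0),
                                       attenuation_db_cm_mhz=0.0, seed=0)
            frame = stack.frame(0)
            from scipy.ndimage import maximum_filter

            peaks = (maximum_filter(frame, 3) == frame) & (frame > 0.1 * frame.max())
            return int(peaks.sum())

        assert render_pair(3 * lateral_fwhm) == 2
        assert render_pair(0.5 * lateral_fwhm) == 1

    def test_noise_grows_with_depth(self):
        tree = _single_segment_tree()
        spec = get_preset("MS-550S")
        stack = render_frame_stack([], tree, spec, 1000.0, duration_s=0.3,
                                   noise=NoiseModel(clutter_db=None, noise_std=0.1,
                                                    noise_depth_gain=2.0), seed=1)
        row_std = stack.data.std(axis=(1, 2))
        assert row_std[-1] / row_std[0] == pytest.approx(3.0, rel=0.15)

    def test_clutter_dominates_mb_signal(self, small_tree):
        spec = get_preset("MS-550S")
        stack = render_frame_stack([], small_tree, spec, 1000.0, duration_s=0.1,
                                   noise=NoiseModel(clutter_db=20.0, noise_std=0.0), seed=3)
        frame_peaks = np.abs(stack.data).reshape(-1, stack.n_t).max(axis=0)
        assert frame_peaks.min() >= 10.0  # ≥ 20 dB above unit MB amplitude

    def test_coarse_grid_rejected(self):
        tree = _single_segment_tree()
        spec = get_preset("MS-550S")
        with pytest.raises(DomainError):
            render_frame_stack([], tree, spec, 1000.0, n_frames=2,
                               pixel_um=spec.wavelength_um())  # > λ/2


class TestThinning:
    def test_thinning_is_a_subset_with_binomial_size(self, small_tree):
        from ulmkit import thin_trajectories

        trajs = simulate_mb_flow(small_tree, 30.0, 1000.0, 2.0, seed=9)
        thin = thin_trajectories(trajs, 0.5, seed=3)
        ids = {id(t) for t in trajs}
        assert all(id(t) in ids for t in thin)
        n, k = len(trajs), len(thin)
        assert abs(k - 0.5 * n) < 4 * np.sqrt(n * 0.25)  # ~4σ binomial band

    def test_thinning_deterministic_and_bounds_checked(self, small_tree):
        from ulmkit import DomainError, thin_trajectories

        trajs = simulate_mb_flow(small_tree, 20.0, 1000.0, 1.0, seed=9)
        a = thin_trajectories(trajs, 0.3, 5)
        b = thin_trajectories(trajs, 0.3, 5)
        assert [id(t) for t in a] == [id(t) for t in b]
        assert [id(t) for t in thin_trajectories(trajs, 1.0, 5)] == [id(t) for t in trajs]
        assert thin_trajectories(trajs, 0.0, 5) == []
        with pytest.raises(DomainError):
            thin_trajectories(trajs, 1.5, 5)
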