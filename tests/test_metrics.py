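"""FRC resolution and exponential saturation modelling."""
import numpy as np
import pytest

from ulmkit import (
    DomainError,
    Track,
    accumulate,
    fit_saturation,
    frc,
    frc_crossing_um,
    resolution,
    saturation_curve,
    split_tracks,
    threshold_half_bit,
    threshold_two_sigma,
)
from ulmkit.maps import ULMImage


def _track(points, tid=0):
    return Track(np.array(points, dtype=float), id=tid)


def _image(counts, pixel=1.0):
    return ULMImage(counts=np.asarray(counts, dtype=float), pixel_um=pixel)


def _random_tracks(n, rng, fov=200.0, length=12):
    tracks = []
    for i in range(n):
        z0, x0 = rng.uniform(20, fov - 20, 2)
        dz, dx = rng.uniform(-1.5, 1.5, 2)
        f0 = rng.integers(0, 400)
        tracks.append(_track([[f0 + k, z0 + dz * k, x0 + dx * k] for k in range(length)], i))
    return tracks


class TestSplitTracks:
    def test_deterministic_given_seed(self):
        tracks = _random_tracks(50, np.random.default_rng(0))
        a1, b1 = split_tracks(tracks, seed=7)
        a2, b2 = split_tracks(tracks, seed=7)
        assert [t.id for t in a1] == [t.id for t in a2]
        assert [t.id for t in b1] == [t.id for t in b2]

    def test_split_is_roughly_balanced(self):
        tracks = _random_tracks(1000, np.random.default_rng(1))
        a, b = split_tracks(tracks, seed=3)
        assert abs(len(a) - 500) < 80  # ~3σ of a fair binomial

    def test_two_tracks_always_one_per_side(self):
        tracks = _random_tracks(2, np.random.default_rng(2))
        for seed in range(20):
            a, b = split_tracks(tracks, seed)
            assert len(a) == 1 and len(b) == 1

    def test_fewer_than_two_tracks_rejected(self):
        with pytest.raises(DomainError):
            split_tracks(_random_tracks(1, np.random.default_rng(3)), 0)


class TestFRC:
    def test_identical_images_correlate_to_unity(self):
        rng = np.random.default_rng(4)
        img = _image(rng.poisson(2.0, (64, 64)).astype(float))
        curve = frc(img, img)
        nonempty = curve.n_per_ring > 0
        assert np.all(np.abs(curve.correlation[nonempty] - 1.0) < 1e-9)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(5)
        a = _image(rng.poisson(1.0, (48, 48)).astype(float))
        b = _image(rng.poisson(1.0, (48, 48)).astype(float))
        np.testing.assert_array_equal(frc(a, b).correlation, frc(b, a).correlation)

    def test_independent_noise_stays_below_three_sigma(self):
        rng = np.random.default_rng(6)
        a = _image(rng.poisson(4.0, (128, 128)).astype(float))
        b = _image(rng.poisson(4.0, (128, 128)).astype(float))
        curve = frc(a, b)
        sel = (curve.n_per_ring >= 8) & (curve.ring_freqs_per_um > 0)
        bound = 3.0 / np.sqrt(curve.n_per_ring[sel])
        frac_below = np.mean(np.abs(curve.correlation[sel]) < bound)
        assert frac_below >= 0.95

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DomainError):
            frc(_image(np.ones((8, 8))), _image(np.ones((16, 16))))


class TestThresholds:
    def test_half_bit_asymptote(self):
        assert threshold_half_bit(1e12) == pytest.approx(0.2071 / 1.2071, rel=1e-4)

    def test_two_sigma_closed_form(self):
        assert threshold_two_sigma(8) == pytest.approx(1.0, rel=1e-12)

    def test_half_bit_at_n_100(self):
        # (0.2071 + 0.19102) / (1.2071 + 0.09102)
        assert threshold_half_bit(100) == pytest.approx(0.30669, rel=1e-4)

    def test_monotone_decreasing_in_n(self):
        n = np.arange(1, 500)
        assert np.all(np.diff(threshold_half_bit(n)) < 0)
        assert np.all(np.diff(threshold_two_sigma(n)) < 0)

    def test_invalid_counts_rejected(self):
        for fn in (threshold_half_bit, threshold_two_sigma):
            with pytest.raises(DomainError):
                fn(0)


class TestResolution:
    def _jittered_tracks(self, rng, sigma_um, n_points=400, n_obs=24, fov=256.0):
        """Localization-microscopy analogue: a fixed point set observed many
        times with Gaussian jitter σ; FRC resolution tracks the jitter FWHM."""
        pts = rng.uniform(30, fov - 30, (n_points, 2))
        tracks = []
        tid = 0
        for p in pts:
            for _ in range(n_obs):
                q = p + rng.normal(0, sigma_um, 2)
                f0 = rng.integers(0, 1000)
                tracks.append(_track([[f0, q[0], q[1]], [f0 + 1, q[0], q[1]]], tid))
                tid += 1
        return tracks

    def _line_tracks(self, rng, fov=256.0, n_lines=12, per_line=120):
        """Short tracks lying on a fixed set of lines: a shared structure whose
        two random halves can be compared spectrally."""
        tracks = []
        tid = 0
        for _ in range(n_lines):
            p = rng.uniform(30, fov - 30, 2)
            ang = rng.uniform(0, np.pi)
            d = np.array([np.cos(ang), np.sin(ang)])
            for _ in range(per_line):
                q = p + rng.uniform(-80, 80) * d
                if not (10 < q[0] < fov - 10 and 10 < q[1] < fov - 10):
                    continue
                f0 = rng.integers(0, 1000)
                tracks.append(_track([[f0, q[0], q[1]],
                                      [f0 + 1, q[0] + d[0], q[1] + d[1]]], tid))
                tid += 1
        return tracks

    @pytest.mark.parametrize("sigma_b", [3.0, 5.0])
    def test_crossing_matches_known_blur_band_limit(self, sigma_b):
        """Half-images of a shared structure, band-limited by a Gaussian blur
        with independent post-blur noise: the FRC crossing must land within
        25% of the analytic blur FWHM."""
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(7)
        tracks = self._line_tracks(rng)
        vals = []
        for rep in range(3):
            a, b = split_tracks(tracks, seed=rep)
            ga = gaussian_filter(accumulate(a, 1.0, (256.0, 256.0)).counts, sigma_b)
            gb = gaussian_filter(accumulate(b, 1.0, (256.0, 256.0)).counts, sigma_b)
            na = _image(np.maximum(ga + rng.normal(0, 0.05 * ga.max(), ga.shape), 0))
            nb = _image(np.maximum(gb + rng.normal(0, 0.05 * gb.max(), gb.shape), 0))
            vals.append(frc_crossing_um(frc(na, nb), "half_bit"))
        assert all(v is not None for v in vals)
        assert np.mean(vals) == pytest.approx(2.3548 * sigma_b, rel=0.25)

    def test_more_tracks_do_not_worsen_resolution(self):
        rng = np.random.default_rng(8)
        few = self._jittered_tracks(rng, 4.0, n_points=150, n_obs=6)
        rng2 = np.random.default_rng(8)
        many = self._jittered_tracks(rng2, 4.0, n_points=150, n_obs=24)
        r_few = resolution(few, (256.0, 256.0), criterion="half_bit", n_repeats=3, seed=1)
        r_many = resolution(many, (256.0, 256.0), criterion="half_bit", n_repeats=3, seed=1)
        assert r_many.mean_um <= r_few.mean_um * 1.05

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        tracks = self._jittered_tracks(rng, 3.0, n_points=200, n_obs=10, fov=200.0)
        moved = [
            Track(t.points + np.array([0.0, 7.0, 11.0]), id=t.id) for t in tracks
        ]
        r0 = resolution(tracks, (240.0, 240.0), n_repeats=3, seed=2)
        r1 = resolution(moved, (240.0, 240.0), n_repeats=3, seed=2)
        assert r1.mean_um == pytest.approx(r0.mean_um, rel=0.05)

    def test_identical_halves_never_cross_and_flag_bound(self):
        rng = np.random.default_rng(10)
        img = _image(rng.poisson(3.0, (64, 64)).astype(float))
        assert frc_crossing_um(frc(img, img)) is None
        # duplicated track set: every split yields near-identical halves
        base = _random_tracks(30, rng)
        doubled = base + [Track(t.points.copy(), id=100 + t.id) for t in base]
        est = resolution(doubled, (200.0, 200.0), n_repeats=2, seed=0)
        assert est.bound_flagged


class TestSaturation:
    def test_static_track_constant_after_first_bin(self):
        tr = _track([[f, 50.0, 50.0] for f in range(10)])
        t, filled = saturation_curve([tr], 2.0, (100.0, 100.0), 5, 1000.0,
                                     duration_s=0.05)
        assert filled[0] == filled[-1] > 0

    def test_disjoint_tracks_one_per_bin_gives_linear_curve(self):
        tracks = []
        for i in range(6):
            f0 = i * 100
            tracks.append(_track([[f0 + k, 10.0 + 12.0 * i, 10.0 + 2.0 * k]
                                  for k in range(10)], i))
        t, filled = saturation_curve(tracks, 2.0, (100.0, 100.0), 6, 1000.0)
        steps = np.diff(filled)
        assert np.all(steps > 0)
        assert np.ptp(steps) <= 1  # equal increments up to rasterization

    def test_curve_non_decreasing_on_random_scenes(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            tracks = _random_tracks(40, rng)
            _, filled = saturation_curve(tracks, 2.0, (200.0, 200.0), 10, 1000.0)
            assert np.all(np.diff(filled) >= 0)

    def test_exact_exponential_recovered(self):
        t = np.linspace(5, 300, 30)
        s = 1e4 * (1 - np.exp(-t / 60.0))
        fit = fit_saturation(t, s)
        assert fit.s_inf == pytest.approx(1e4, rel=1e-6)
        assert fit.tau_s == pytest.approx(60.0, rel=1e-6)

    def test_t90_is_tau_ln10(self):
        t = np.linspace(5, 300, 30)
        fit = fit_saturation(t, 500.0 * (1 - np.exp(-t / 60.0)))
        assert fit.t90_s == pytest.approx(60.0 * np.log(10.0), rel=1e-9)
        assert fit.t90_s == pytest.approx(138.155, rel=1e-4)

    def test_one_percent_noise_recovers_tau_within_5_percent(self):
        rng = np.random.default_rng(11)
        t = np.linspace(2, 240, 40)
        s = 8e3 * (1 - np.exp(-t / 60.0))
        noisy = s * (1 + rng.normal(0, 0.01, len(t)))
        noisy = np.maximum.accumulate(noisy)  # keep the curve non-decreasing
        fit = fit_saturation(t, noisy)
        assert fit.tau_s == pytest.approx(60.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            fit_saturation(np.arange(4), np.arange(4.0))

    def test_decreasing_curve_rejected(self):
        with pytest.raises(DomainError):
            fit_saturation(np.arange(6), np.array([0, 1, 2, 1.5, 3, 4.0]))
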