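"""Vascular metrics: velocity stats, tortuosity, diameters, fractal
dimension, density and the qualitative classifications."""

import numpy as np
import pytest

from ulmkit import metrics as vm, reconstruction as rec, tracking as trk


def _track(points, start_frame=0):
    locs = [rec.Localization(start_frame + k, float(a), float(l), 1.0)
            for k, (a, l) in enumerate(points)]
    return trk.Track(locs)


def _full_roi(shape=(64, 64), px=50.0):
    return vm.ROIMask(np.ones(shape, bool), px)


def _sr_from_mask(mask, spacing=5.0, factor=10):
    return rec.SRMap(mask.astype(np.int64), factor, spacing)


class TestVelocityStats:
    def test_single_track(self):
        tr = _track([(100, 100), (100, 300)])  # 16 mm/s at 80 Hz
        mean, mx = vm.roi_velocity_stats([tr], _full_roi(), 80.0)
        assert mean == pytest.approx(16.0)
        assert mx == pytest.approx(16.0)

    def test_two_tracks_mean_and_max(self):
        t10 = _track([(100, 100), (100, 225)])   # 10 mm/s
        t20 = _track([(300, 100), (300, 350)])   # 20 mm/s
        mean, mx = vm.roi_velocity_stats([t10, t20], _full_roi(), 80.0)
        assert mean == pytest.approx(15.0)
        assert mx == pytest.approx(20.0)
        assert mx >= mean

    def test_no_in_roi_track_flagged_nan(self):
        roi = vm.ROIMask(np.zeros((64, 64), bool) | _corner_mask(), 50.0)
        tr = _track([(3000, 3000), (3000, 3100)])
        mean, mx = vm.roi_velocity_stats([tr], roi, 80.0)
        assert np.isnan(mean) and np.isnan(mx)

    def test_known_speed_set_recovered(self):
        tracks = [_track([(100 * (i + 1), 100),
                          (100 * (i + 1), 100 + s * 1000 / 80.0)])
                  for i, s in enumerate((5.0, 10.0, 20.0))]
        mean, mx = vm.roi_velocity_stats(tracks, _full_roi(), 80.0)
        assert mean == pytest.approx(35.0 / 3, rel=0.05)
        assert mx == pytest.approx(20.0, rel=0.05)


def _corner_mask():
    m = np.zeros((64, 64), bool)
    m[:4, :4] = True
    return m


class TestTortuosity:
    def test_collinear_track_is_one(self):
        assert vm.track_tortuosity(_track([(0, 0), (0, 100), (0, 200)])) == \
            pytest.approx(1.0)

    def test_semicircular_track_is_half_pi(self):
        th = np.linspace(0, np.pi, 400)
        pts = np.stack([1000 * np.sin(th), 1000 * np.cos(th)], axis=1) + 2000
        assert vm.track_tortuosity(_track(pts)) == pytest.approx(np.pi / 2,
                                                                 rel=1e-4)

    def test_closed_loop_flagged(self):
        th = np.linspace(0, 2 * np.pi, 100)
        pts = np.stack([500 * np.sin(th), 500 * np.cos(th)], axis=1) + 2000
        pts[-1] = pts[0]  # exactly closed
        assert np.isnan(vm.track_tortuosity(_track(pts)))

    def test_sinusoid_matches_dense_arc_length_oracle(self):
        x = np.linspace(0, 2000, 300)
        y = 300 * np.sin(2 * np.pi * x / 1000)
        pts = np.stack([y + 1600, x], axis=1)
        tort = vm.track_tortuosity(_track(pts))
        # oracle: numeric arc length on a 100x denser grid
        xd = np.linspace(0, 2000, 30_000)
        yd = 300 * np.sin(2 * np.pi * xd / 1000)
        path = np.hypot(np.diff(yd), np.diff(xd)).sum()
        assert tort == pytest.approx(path / 2000.0, rel=0.01)

    def test_tortuosity_at_least_one(self, rng):
        for _ in range(50):
            pts = np.cumsum(rng.uniform(-50, 80, size=(6, 2)), axis=0) + 1600
            t = vm.track_tortuosity(_track(pts))
            assert np.isnan(t) or t >= 1.0 - 1e-12


class TestDiameters:
    def test_straight_bar_width(self):
        mask = np.zeros((64, 64), bool)
        mask[27:37, 5:60] = True  # 10 SR pixels wide at 5 um spacing
        sr = _sr_from_mask(mask)
        mean, mx = vm.vessel_diameters(sr, binary_mask=mask)
        assert mx == pytest.approx(50.0, abs=5.0)
        assert mean == pytest.approx(50.0, abs=7.5)

    def test_one_pixel_line_minimum_diameter(self):
        mask = np.zeros((64, 64), bool)
        mask[30, 5:60] = True
        sr = _sr_from_mask(mask)
        mean, mx = vm.vessel_diameters(sr, binary_mask=mask)
        assert mx == pytest.approx(2 * 5.0, abs=5.0)  # grid-spacing scale

    def test_two_bars_largest(self):
        mask = np.zeros((80, 80), bool)
        mask[10:14, 5:75] = True    # width 4
        mask[40:50, 5:75] = True    # width 10
        sr = _sr_from_mask(mask)
        mean, mx = vm.vessel_diameters(sr, binary_mask=mask)
        assert mx == pytest.approx(10 * 5.0, abs=5.0)
        assert mx >= mean

    def test_empty_mask_flagged(self):
        sr = _sr_from_mask(np.zeros((16, 16), bool))
        mean, mx = vm.vessel_diameters(sr, binary_mask=np.zeros((16, 16), bool))
        assert np.isnan(mean) and np.isnan(mx)


def _sierpinski(n_iter=7):
    m = np.array([[True]])
    for _ in range(n_iter):
        z = np.zeros_like(m)
        m = np.block([[m, m], [m, z]])
    return m


class TestFractalDimension:
    def test_line_square_sierpinski(self):
        line = np.zeros((128, 128), bool)
        line[64, :] = True
        assert vm.fractal_dimension(line) == pytest.approx(1.0, abs=0.05)
        square = np.ones((128, 128), bool)
        assert vm.fractal_dimension(square) == pytest.approx(2.0, abs=0.05)
        assert vm.fractal_dimension(_sierpinski()) == pytest.approx(
            np.log(3) / np.log(2), abs=0.05)

    def test_monotone_with_added_structure(self):
        line = np.zeros((128, 128), bool)
        line[64, :] = True
        grid = line.copy()
        grid[::8, :] = True
        grid[:, ::8] = True
        assert vm.fractal_dimension(grid) > vm.fractal_dimension(line)

    def test_single_pixel_degenerate(self):
        m = np.zeros((64, 64), bool)
        m[10, 10] = True
        assert np.isnan(vm.fractal_dimension(m))


class TestMVD:
    def test_formula_exact(self):
        roi = np.zeros((20, 20), bool)
        roi[:10, :10] = True  # 100 px
        tracked = np.zeros((20, 20), bool)
        tracked[0, :5] = True  # 5 px inside ROI
        assert vm.microvascular_density(tracked, roi) == pytest.approx(5.0)

    def test_zero_tracked_area(self):
        roi = np.ones((10, 10), bool)
        assert vm.microvascular_density(np.zeros((10, 10), bool), roi) == 0.0

    def test_invariant_under_grid_refinement(self):
        # same geometry on a 2x finer grid: MVD within 10%
        roi = np.zeros((40, 40), bool)
        roi[5:35, 5:35] = True
        tracked = np.zeros((40, 40), bool)
        tracked[18:22, 5:35] = True
        coarse = vm.microvascular_density(tracked, roi)
        fine = vm.microvascular_density(np.kron(tracked, np.ones((2, 2), bool)),
                                        np.kron(roi, np.ones((2, 2), bool)))
        assert fine == pytest.approx(coarse, rel=0.10)


class TestDistribution:
    def _disc_roi(self, n=64, r=28):
        yy, xx = np.mgrid[:n, :n]
        mask = (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= r ** 2
        return vm.ROIMask(mask, 50.0)

    def test_outer_annulus_peripheral(self, rng):
        roi = self._disc_roi()
        th = rng.uniform(0, 2 * np.pi, 200)
        rad = rng.uniform(0.8, 0.95, 200) * 28 * 50.0
        pts = np.stack([1600 + rad * np.sin(th), 1600 + rad * np.cos(th)], axis=1)
        assert vm.classify_distribution(pts, roi) == "peripheral"

    def test_all_at_centroid_central(self):
        roi = self._disc_roi()
        pts = np.tile([1600.0, 1600.0], (20, 1))
        assert vm.classify_distribution(pts, roi) == "central"

    def test_uniform_fill_diffuse(self):
        roi = self._disc_roi()
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            th = r.uniform(0, 2 * np.pi, 300)
            rad = 28 * 50.0 * np.sqrt(r.uniform(0, 1, 300))  # uniform on disc
            pts = np.stack([1600 + rad * np.sin(th), 1600 + rad * np.cos(th)],
                           axis=1)
            hits += vm.classify_distribution(pts, roi) == "diffuse"
        assert hits / n_seeds >= 0.95

    def test_roi_with_hole_uses_distance_transform(self):
        roi_mask = np.zeros((64, 64), bool)
        roi_mask[10:54, 10:54] = True
        roi_mask[28:36, 28:36] = False  # hole -> not simply connected
        roi = vm.ROIMask(roi_mask, 50.0)
        pts = np.array([[600.0, 600.0]])
        label = vm.classify_distribution(pts, roi)
        assert label in {"central", "peripheral", "diffuse"}


class TestFlowDirection:
    def test_all_deeper_away(self):
        tr = _track([(100, 500), (200, 500), (300, 500)])
        assert vm.classify_flow_direction([tr], _full_roi(), 80.0) == "away"

    def test_all_shallower_toward(self):
        tr = _track([(300, 500), (200, 500), (100, 500)])
        assert vm.classify_flow_direction([tr], _full_roi(), 80.0) == "toward"

    def test_exact_tie_indeterminate(self):
        down = _track([(100, 500), (200, 500)])
        up = _track([(200, 700), (100, 700)])
        assert vm.classify_flow_direction([down, up], _full_roi(), 80.0) == \
            "indeterminate"

    def test_majority_downflow_away(self):
        rngs = range(10)
        hits = 0
        for seed in rngs:
            r = np.random.default_rng(seed)
            tracks = []
            for k in range(10):
                sign = 1 if k < 7 else -1  # 70% of flow volume downward
                start = r.uniform(500, 2000, 2)
                pts = [start + [sign * 100 * s, 10 * s] for s in range(4)]
                tracks.append(_track(pts))
            hits += vm.classify_flow_direction(tracks, _full_roi(), 80.0) == "away"
        assert hits / len(rngs) >= 0.95
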