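"""Phase maps, singularity detection, tip tracking, DF, APD dispersion."""

import numpy as np
import pytest

from atrikir.geometry import make_geometry
from atrikir.metrics import (
    dominant_frequency, find_singularities, phase_map, spiral_metrics,
    track_tips, apd_dispersion_map,
)


def rotating_spiral_movie(n=40, dx=0.5, period_ms=120.0, frame_ms=4.0,
                          n_frames=120, x0=None, y0=None, chirality=+1):
    """Synthetic Archimedean-spiral voltage movie with a known core/period."""
    x = (np.arange(n) + 0.5) * dx
    X, Y = np.meshgrid(x, x, indexing="ij")
    x0 = x.mean() if x0 is None else x0
    y0 = x.mean() if y0 is None else y0
    theta = np.arctan2(Y - y0, X - x0)
    r = np.hypot(X - x0, Y - y0)
    t = np.arange(n_frames) * frame_ms
    movie = np.empty((n_frames, n, n))
    for k, tk in enumerate(t):
        phase = chirality * theta + 0.5 * r - 2 * np.pi * tk / period_ms
        movie[k] = -40.0 + 40.0 * np.cos(phase)
    return movie, t


class TestPhaseMap:
    def test_periodic_trace_winds_through_two_pi(self):
        t = np.arange(0.0, 1000.0, 2.0)
        v = -40.0 + 40.0 * np.sin(2 * np.pi * t / 200.0)
        phase, pt = phase_map(v[:, None], t, embed_delay=50.0)
        unwrapped = np.unwrap(phase[:, 0])
        total = unwrapped[-1] - unwrapped[0]
        cycles = (pt[-1] - pt[0]) / 200.0
        assert abs(abs(total) / (2 * np.pi) - cycles) < 0.5

    def test_constant_trace_flagged_undefined(self):
        t = np.arange(0.0, 200.0, 2.0)
        v = np.full((t.size, 3), -80.0)
        phase, _ = phase_map(v, t, embed_delay=10.0)
        assert np.all(np.isnan(phase))

    def test_window_shorter_than_delay_rejected(self):
        t = np.arange(0.0, 4.0, 2.0)
        with pytest.raises(ValueError):
            phase_map(np.zeros((2, 3)), t, embed_delay=10.0)

    def test_rotating_spiral_period_recovered(self):
        movie, t = rotating_spiral_movie(period_ms=120.0)
        phase, pt = phase_map(movie, t, embed_delay=8.0)
        probe = np.unwrap(phase[:, 10, 10])
        period = 2 * np.pi * (pt[-1] - pt[0]) / abs(probe[-1] - probe[0])
        assert period == pytest.approx(120.0, rel=0.05)


class TestSingularities:
    def test_plane_wave_has_no_singularities(self):
        x = np.linspace(0, 4 * np.pi, 50)
        phase = np.tile(((x + np.pi) % (2 * np.pi) - np.pi)[:, None], (1, 50))
        assert find_singularities(phase, dx=0.5) == []

    def test_analytic_singular_field_single_positive_tip(self):
        n, dx = 40, 0.5
        xc = (np.arange(n) + 0.5) * dx
        X, Y = np.meshgrid(xc, xc, indexing="ij")
        x0 = y0 = 10.12
        phase = np.arctan2(Y - y0, X - x0)
        tips = find_singularities(phase, dx=dx)
        assert len(tips) == 1
        x, y, charge = tips[0]
        assert charge == +1
        assert abs(x - x0) <= dx and abs(y - y0) <= dx

    def test_figure_of_eight_total_charge_zero(self):
        n, dx = 60, 0.5
        xc = (np.arange(n) + 0.5) * dx
        X, Y = np.meshgrid(xc, xc, indexing="ij")
        p1 = np.arctan2(Y - 15.0, X - 10.0)
        p2 = -np.arctan2(Y - 15.0, X - 20.0)
        phase = (p1 + p2 + np.pi) % (2 * np.pi) - np.pi
        tips = find_singularities(phase, dx=dx)
        assert len(tips) == 2
        assert sum(c for _, _, c in tips) == 0


class TestTracking:
    def test_stationary_tip_one_track_small_meander(self):
        frames = [[(10.0, 10.0, 1)]] * 50
        times = np.arange(50) * 4.0
        tracks = track_tips(frames, times)
        assert len(tracks) == 1
        assert len(tracks[0]) == 50

    def test_square_path_hull_area(self):
        # tip tracing a 10x10 mm square: convex hull area 100 mm^2
        corners = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]
        path = []
        for k in range(40):
            a = corners[(k // 10) % 4]
            b = corners[(k // 10 + 1) % 4]
            f = (k % 10) / 10.0
            path.append((a[0] + f * (b[0] - a[0]), a[1] + f * (b[1] - a[1]), 1))
        frames = [[p] for p in path]
        times = np.arange(len(path)) * 10.0
        geom = make_geometry("sheet", (20.0, 20.0), 0.5)
        movie = np.zeros((len(path), *geom.shape))
        movie[:, 0, 0] = 100.0 * np.sin(np.arange(len(path)))  # non-flat
        # feed pre-computed tips through the tracking + hull path
        tracks = track_tips(frames, times)
        assert len(tracks) == 1
        from atrikir.metrics import _hull_area
        pts = np.array([(x, y) for _, x, y, _ in tracks[0]])
        assert _hull_area(pts) == pytest.approx(100.0, rel=0.01)

    def test_distant_tips_start_new_tracks(self):
        frames = [[(5.0, 5.0, 1)], [(25.0, 25.0, 1)]]
        tracks = track_tips(frames, [0.0, 4.0], gate_mm=2.0)
        assert len(tracks) == 2


class TestDominantFrequency:
    def test_five_hz_sinusoid(self):
        t = np.arange(0.0, 5000.0, 1.0)  # 5 s at 1 kHz
        v = 20.0 * np.sin(2 * np.pi * 5.0 * t / 1000.0)
        assert dominant_frequency(v, fs_khz=1.0) == pytest.approx(5.0, abs=0.25)

    def test_largest_peak_wins(self):
        t = np.arange(0.0, 5000.0, 1.0)
        v = (10.0 * np.sin(2 * np.pi * 4.0 * t / 1000.0)
             + 3.0 * np.sin(2 * np.pi * 8.0 * t / 1000.0))
        assert dominant_frequency(v, fs_khz=1.0) == pytest.approx(4.0, abs=0.25)

    def test_quiescent_trace_reported_absent(self):
        v = np.full(5000, -78.0) + 0.01 * np.random.default_rng(0).normal(
            size=5000)
        assert dominant_frequency(v, fs_khz=1.0) is None

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            dominant_frequency(np.zeros(500), fs_khz=1.0)

    def test_time_shift_invariance(self):
        t = np.arange(0.0, 4000.0, 1.0)
        v = 30.0 * np.sin(2 * np.pi * 6.0 * t / 1000.0)
        assert dominant_frequency(v, 1.0) == dominant_frequency(
            np.roll(v, 500), 1.0)


class TestSpiralMetrics:
    def test_synthetic_rotor_lifespan_and_single_tip(self):
        movie, t = rotating_spiral_movie(n_frames=150)
        geom = make_geometry("sheet", (20.0, 20.0), 0.5)
        sm = spiral_metrics(movie, t, geom)
        assert sm.lifespan_s == pytest.approx((t[-1]) / 1000.0, abs=0.02)
        assert sm.n_tips_final == 1
        assert sm.meander_area_mm2 < 4.0  # stationary core

    def test_empty_movie_zero_lifespan(self):
        t = np.arange(20) * 4.0
        movie = np.tile(-80.0 + np.sin(np.arange(20))[:, None, None] * 15.0,
                        (1, 30, 30))
        geom = make_geometry("sheet", (15.0, 15.0), 0.5)
        sm = spiral_metrics(movie, t, geom)
        assert sm.lifespan_s == 0.0


class TestAPDDispersion:
    def test_two_region_synthetic_movie(self):
        """Nodes with regionally distinct repolarisation times give a
        dispersion equal to the imposed APD difference."""
        geom = make_geometry("junction", 20.0, 0.5, regions=("A", "B"),
                             split_mm=10.0)
        t = np.arange(0.0, 500.0, 1.0)
        movie = np.empty((t.size, 40))
        for k in range(40):
            apd = 200.0 if k < 20 else 260.0
            v = np.where(t < 2.0, -80 + 50 * t, np.where(t < apd, 20.0, -80.0))
            movie[:, k] = v
        amap = apd_dispersion_map(movie, t, geom)
        assert amap.delta_apd == pytest.approx(60.0, abs=2.0)
        assert amap.excited.all()

    def test_unexcited_nodes_masked(self):
        geom = make_geometry("cable", 10.0, 0.5)
        t = np.arange(0.0, 400.0, 1.0)
        movie = np.full((t.size, 20), -80.0)
        ap = np.where(t < 2.0, -80 + 50 * t, np.where(t < 250.0, 15.0, -80.0))
        movie[:, :10] = ap[:, None]
        amap = apd_dispersion_map(movie, t, geom)
        assert amap.excited[:10].all()
        assert not amap.excited[10:].any()
        assert np.isnan(amap.apd_plus[10:]).all()
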