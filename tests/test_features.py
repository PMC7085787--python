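import numpy as np
import pytest
from hypothesis import given, strategies as st

from pentascore.config import PeakParams, RunConfig, Thresholds
from pentascore.features import (
    RATIO_SENTINEL,
    aspect_ratio,
    cluster_dispersions,
    count_angles,
    count_updown_transitions,
    detect_velocity_peaks,
    interlock_distance,
    opening_flag,
    tremor_flag,
)
from pentascore.sensor_io import compute_velocity, split_figures
from pentascore.synthgen import DrawingSpec, generate_trace

from conftest import make_trace


class TestVelocityPeaks:
    def test_constant_velocity_has_no_interior_peaks(self, cfg):
        v = np.full(50, 800.0)
        assert detect_velocity_peaks(v, cfg.peaks, cfg.sample_dt) == 0

    @pytest.mark.parametrize("n_vertices", [4, 5, 6])
    def test_one_peak_per_edge_on_synthetic_figures(self, cfg, n_vertices):
        trace, _ = generate_trace(DrawingSpec(seed=6, vertices_fig1=n_vertices), cfg)
        v = compute_velocity(trace).v
        split = split_figures(trace)
        got = detect_velocity_peaks(v[: split.nf1 + 1], cfg.peaks, cfg.sample_dt)
        assert got == n_vertices

    def test_short_segment_returns_zero(self, cfg):
        assert detect_velocity_peaks(np.array([0.0, 5.0]), cfg.peaks, cfg.sample_dt) == 0


class TestCountAngles:
    def test_pentagon_identified_by_percentage(self):
        # match percentage above threshold wins over the peak count
        assert count_angles(90.71, 5, 75.0) == 5
        assert count_angles(100.0, 7, 75.0) == 5

    def test_peak_count_used_below_threshold(self):
        assert count_angles(23.88, 4, 75.0) == 4

    def test_threshold_boundary_inclusive(self):
        assert count_angles(75.0, 3, 75.0) == 5
        assert count_angles(74.99, 3, 75.0) == 3


class TestInterlockDistance:
    def test_coincident_endpoints(self):
        trace = make_trace([-1, 0], x=[50, 50], y=[60, 60])
        assert interlock_distance(trace, 0, 1, 0.004) == 0.0

    def test_overlapping_tips_negative(self):
        trace = make_trace([-1, 0], x=[100, 90], y=[50, 60])
        d = interlock_distance(trace, 0, 1, 0.004)
        assert d == pytest.approx(-np.sqrt(200) * 0.004)  # -0.0566 cm

    def test_separated_tips_positive(self):
        trace = make_trace([-1, 0], x=[90, 100], y=[50, 50])
        assert interlock_distance(trace, 0, 1, 0.004) == pytest.approx(0.04)

    def test_sign_flips_with_x_order_only(self):
        trace = make_trace([-1, 0], x=[100, 90], y=[50, 60])
        d12 = interlock_distance(trace, 0, 1, 0.004)
        d21 = interlock_distance(trace, 1, 0, 0.004, left_tip_is_n1=False)
        assert d12 == d21  # same geometry, same sign
        assert abs(d12) == abs(interlock_distance(trace, 1, 0, 0.004))


class TestAspectRatio:
    def test_plain_ratio(self):
        assert aspect_ratio((120, 50), (100, 45)) == pytest.approx(4.0)

    def test_zero_dx(self):
        assert aspect_ratio((10, 50), (10, 45)) == 0.0

    def test_zero_dy_sentinel(self):
        r = aspect_ratio((10, 50), (30, 50))
        assert r == RATIO_SENTINEL and r >= 1.12

    def test_coincident_points(self):
        assert aspect_ratio((10, 50), (10, 50)) == 0.0


class TestClusterDispersions:
    def _blobs(self, centers, spread, n_per, seed=0):
        rng = np.random.default_rng(seed)
        return np.vstack(
            [c + rng.normal(0, spread, (n_per, 2)) for c in np.asarray(centers, float)]
        )

    def test_tight_blobs_all_below_threshold(self):
        centers = [(0, 0), (500, 0), (250, 400), (0, 800), (500, 800)]
        pts = self._blobs(centers, spread=1.0, n_per=6)
        res = cluster_dispersions(pts, 5, seed=0, cm_per_px=0.004)
        assert res.k_used == 5 and not res.degenerate
        assert (res.dispersions_cm < 0.1).all()

    def test_stretched_cluster_detected(self):
        # two-point cluster separated by 2 x 0.15 cm -> dispersion 0.15 cm
        pts = np.array([[0.0, 0.0], [75.0, 0.0]])
        far = self._blobs([(600, 0), (300, 500), (0, 900), (600, 900)], 0.5, 5)
        res = cluster_dispersions(np.vstack([pts, far]), 5, seed=0, cm_per_px=0.004)
        over = res.dispersions_cm > 0.1
        assert over.sum() == 1
        assert res.dispersions_cm[over][0] == pytest.approx(0.15, abs=0.01)

    def test_same_seed_identical_assignments(self):
        pts = self._blobs([(0, 0), (100, 100), (300, 50)], 5.0, 8, seed=3)
        a = cluster_dispersions(pts, 3, seed=7, cm_per_px=0.004)
        b = cluster_dispersions(pts, 3, seed=7, cm_per_px=0.004)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(a.dispersions_cm, b.dispersions_cm)

    def test_fewer_distinct_points_degenerate(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        res = cluster_dispersions(pts, 5, seed=0, cm_per_px=0.004)
        assert res.degenerate and res.k_used == 2

    def test_no_points_degenerate(self):
        res = cluster_dispersions(np.empty((0, 2)), 5, seed=0, cm_per_px=0.004)
        assert res.degenerate and res.k_used == 0
        assert opening_flag(res.dispersions_cm, 0.1) == 0


class TestOpeningFlag:
    def test_published_open_and_closed_dispersion_lists(self):
        open_left = [0.054, 0.080, 0.015, 0.046, 0.179]
        closed_right = [0.027, 0.014, 0.022, 0.011, 0.035]
        assert opening_flag(np.array(open_left), 0.1) == 1
        assert opening_flag(np.array(closed_right), 0.1) == 0

    def test_all_zero_dispersions_closed(self):
        assert opening_flag(np.zeros(5), 0.1) == 0


class TestTremor:
    def test_examples(self):
        assert count_updown_transitions(np.array([0, 0, 1, -1, 0, 1, -1, 0])) == 2
        assert count_updown_transitions(np.array([-1, 0, 0, 0])) == 0

    def test_engineered_counts_five_and_nineteen(self, cfg):
        trace, _ = generate_trace(DrawingSpec(seed=12, tremor_fig1=5, tremor_fig2=19), cfg)
        split = split_figures(trace)
        assert count_updown_transitions(trace.e[: split.nf1 + 1]) == 5
        assert count_updown_transitions(trace.e[split.nf2 :]) == 19

    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=2, max_size=60))
    def test_matches_pair_scan_oracle(self, events):
        e = np.array(events)
        expected = sum(
            1 for a, b in zip(events[:-1], events[1:]) if a == 1 and b == -1
        )
        assert count_updown_transitions(e) == expected

    def test_flag_threshold_inclusive(self):
        assert tremor_flag(0, 5) == 0
        assert tremor_flag(4, 5) == 0
        assert tremor_flag(5, 5) == 1
        assert tremor_flag(19, 5) == 1
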