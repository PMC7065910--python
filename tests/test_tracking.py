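"""Segmentation, linking and spot detection against constructed rasters and
simulator ground truth."""

import numpy as np
import pytest

from forktrack.elasticity import DEFAULT_DSDNA, extension_per_bp_ds
from forktrack.pipeline import AnalysisConfig, analyze_trace
from forktrack.simulate import ForceSchedule, ImagingParams, SimCondition, simulate_trace
from forktrack.tether import TemplateSpec, bp_to_um
from forktrack.tracking import (
    EventTrack,
    Kymograph,
    detect_spots,
    link_events,
    segment_dark_regions,
)


def make_kymo(lines: np.ndarray) -> Kymograph:
    return Kymograph({"sytox": np.asarray(lines, float)}, 0.1, 0.1)


class TestSegmentation:
    def test_uniform_bright_line_no_intervals(self):
        img = np.full((3, 40), 100.0)
        img[0, 20] = 0.0  # avoid the constant-raster guard
        out = segment_dark_regions(make_kymo(img), ("absolute", 50.0))
        assert out[1] == [] and out[2] == []

    def test_single_dark_run_width_and_subpixel_edges(self):
        line = np.full(40, 100.0)
        line[10:15] = 0.0  # 5-pixel zero run
        img = np.vstack([line, line])
        out = segment_dark_regions(make_kymo(img), ("absolute", 50.0))
        assert len(out[0]) == 1
        left, right = out[0][0]
        # half-amplitude crossings sit half a pixel outside the zero run
        assert left == pytest.approx(9.5 * 0.1, abs=1e-9)
        assert right == pytest.approx(14.5 * 0.1, abs=1e-9)

    def test_boundary_touching_runs_dropped(self):
        line = np.full(40, 100.0)
        line[30:] = 0.0  # background beyond the tether end
        img = np.vstack([line, line])
        out = segment_dark_regions(make_kymo(img), ("absolute", 50.0))
        assert out[0] == []

    def test_constant_raster_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            segment_dark_regions(make_kymo(np.full((3, 40), 7.0)))

    def test_median_relative_gain_invariance(self):
        rng = np.random.default_rng(0)
        line = rng.poisson(55.0, size=60).astype(float)
        line[20:30] = rng.poisson(5.0, size=10)
        img = np.vstack([line, line])
        a = segment_dark_regions(make_kymo(img), ("median_frac", 0.5))
        b = segment_dark_regions(make_kymo(img * 3.7), ("median_frac", 0.5))
        assert a == b

    def test_noisy_edge_localization_rms_below_one_pixel(self):
        """Default-noise benchmark: tracked edges within 1 px RMS of truth."""
        tmpl = TemplateSpec(6_400, (2_200,))
        cond = SimCondition(
            velocity_mean=60.0, velocity_sd=0.0,
            initiation_force_quantiles=((30.0, 1.0),),
            initiation_wait_mean_s=1e-9, uni_direction="right",
        )
        imaging = ImagingParams(duration_s=60.0)
        sch = ForceSchedule.constant(30.0, 60.0)
        b = simulate_trace(tmpl, cond, imaging, sch, seed=17)
        cfg = AnalysisConfig()
        intervals = segment_dark_regions(b.kymo, cfg.threshold_spec)
        tracks = link_events(intervals, 0.1, 0.1)
        ev = max(tracks, key=lambda t: len(t.times_s))
        v = b.truth["v_right_bps"].iloc[0]
        t0 = b.truth["t_init_s"].iloc[0]
        errs = []
        for t, left, right in zip(ev.times_s, ev.left_um, ev.right_um):
            a_bp, b_bp = 2200.0, min(2200.0 + v * (t - t0), 6400.0)
            truth_um = bp_to_um(
                np.array([a_bp, b_bp]), [(a_bp, b_bp)], 30.0
            ) + imaging.bead_width_um
            errs.extend([left - truth_um[0], right - truth_um[1]])
        rms_px = np.sqrt(np.mean(np.square(errs))) / imaging.pixel_size_um
        assert rms_px <= 1.0


class TestLinking:
    def _growing_intervals(self, center, rate, n=40):
        out = []
        for k in range(n):
            w = 0.1 + rate * k
            out.append((center - w / 2, center + w / 2))
        return out

    def test_single_growing_event(self):
        per_line = [[iv] for iv in self._growing_intervals(5.0, 0.01)]
        events = link_events(per_line, 0.1, 0.1)
        assert len(events) == 1
        ev = events[0]
        # one edge moves left, the other right, symmetrically
        assert ev.left_um[-1] < ev.left_um[0]
        assert ev.right_um[-1] > ev.right_um[0]

    def test_two_disjoint_events(self):
        a = self._growing_intervals(3.0, 0.01)
        b = self._growing_intervals(8.0, 0.02)
        per_line = [[x, y] for x, y in zip(a, b)]
        events = link_events(per_line, 0.1, 0.1)
        assert len(events) == 2

    def test_gap_tolerance(self):
        ivs = self._growing_intervals(5.0, 0.01)
        per_line = [[iv] if k not in (10, 11) else [] for k, iv in enumerate(ivs)]
        events = link_events(per_line, 0.1, 0.1, max_gap_lines=2)
        assert len(events) == 1

    def test_min_filters_suppress_flickers(self):
        per_line = [[(5.0, 5.6)] if k < 3 else [] for k in range(20)]
        assert link_events(per_line, 0.1, 0.1, min_lines=5) == []

    def test_three_event_count_matches_truth(self, analyzed_three_events):
        bundle, res = analyzed_three_events
        n_truth = int((bundle.truth["class"] != "none").sum())
        assert len(res.tracks) == n_truth == 3

    def test_edge_order_invariant(self):
        with pytest.raises(ValueError):
            EventTrack(0, np.array([0.0, 1.0]), np.array([2.0, 2.0]), np.array([1.9, 2.5]))


class TestSpots:
    def test_missing_channel_disabled_not_error(self):
        img = np.random.default_rng(0).poisson(50, (10, 40)).astype(float)
        assert detect_spots(make_kymo(img), channel="egfp") == []

    def test_bidirectional_event_two_diverging_spots(self):
        tmpl = TemplateSpec(20_000, (10_000,))
        cond = SimCondition(
            velocity_mean=60.0, velocity_sd=0.0, p_bidirectional=1.0,
            bi_velocity_mean=120.0, bi_velocity_sd=0.0,
            initiation_force_quantiles=((30.0, 1.0),),
            initiation_wait_mean_s=1e-9, spot_channel=True,
        )
        imaging = ImagingParams(duration_s=60.0, noiseless=True)
        sch = ForceSchedule.constant(30.0, 60.0)
        b = simulate_trace(tmpl, cond, imaging, sch, seed=30)
        spots = detect_spots(b.kymo, min_snr=3.0)
        long_spots = [s for s in spots if len(s.times_s) > 100]
        assert len(long_spots) >= 2
        s0, s1 = sorted(long_spots, key=lambda s: -len(s.times_s))[:2]
        sep_start = abs(s0.positions_um[0] - s1.positions_um[0])
        sep_end = abs(s0.positions_um[-1] - s1.positions_um[-1])
        assert sep_end > sep_start + 1.0

    def test_unidirectional_event_at_least_one_spot_at_moving_edge(self):
        tmpl = TemplateSpec(20_000, (10_000,))
        cond = SimCondition(
            velocity_mean=80.0, velocity_sd=0.0,
            initiation_force_quantiles=((30.0, 1.0),),
            initiation_wait_mean_s=1e-9, uni_direction="right",
            spot_channel=True,
        )
        imaging = ImagingParams(duration_s=60.0, noiseless=True)
        sch = ForceSchedule.constant(30.0, 60.0)
        b = simulate_trace(tmpl, cond, imaging, sch, seed=31)
        spots = detect_spots(b.kymo, min_snr=3.0)
        assert len(spots) >= 1
        main = max(spots, key=lambda s: len(s.times_s))
        # spot intensity grows with the coil as the fork progresses
        assert main.intensities[-1] > main.intensities[0]
        # and the spot moves with the fork
        assert main.positions_um[-1] > main.positions_um[0] + 0.5
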