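"""Classification, rate estimation, required force, rewinding, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forktrack.elasticity import DEFAULT_DSDNA, extension_per_bp_ds
from forktrack.inference import (
    NO_UNWINDING,
    UnwindingEvent,
    classify_event,
    detect_rewinding,
    estimate_rate,
    fit_linear_region,
    growth_phase_end,
    required_force,
    summarize_condition,
    wilson_interval,
)
from forktrack.simulate import ForceSchedule
from forktrack.tracking import EventTrack, SpotTrack

X_DS_30 = extension_per_bp_ds(DEFAULT_DSDNA, 30.0)  # nm/bp


def duplex_track(v_left_bps=0.0, v_right_bps=60.0, n=400, dt=0.1, nick_um=5.0):
    """Duplex-frame event track with exactly linear edges."""
    t = np.arange(n) * dt
    left = nick_um - v_left_bps * X_DS_30 * t / 1000.0
    right = nick_um + v_right_bps * X_DS_30 * t / 1000.0
    return EventTrack(0, t, left, right)


class TestLinearRegion:
    def test_exact_line(self):
        t = np.linspace(0, 10, 50)
        fit = fit_linear_region(t, 3.0 * t + 1.0)
        assert fit.slope == pytest.approx(3.0, rel=1e-12)
        assert fit.n == 50 and fit.r2 == pytest.approx(1.0)

    def test_growth_phase_truncation_recovers_slope(self):
        t = np.linspace(0, 20, 200)
        y = np.minimum(2.0 * t, 20.0)  # grows, then saturates at t = 10
        g = growth_phase_end(y)
        fit = fit_linear_region(t[:g], y[:g])
        assert fit.slope == pytest.approx(2.0, rel=5e-3)

    def test_no_linear_region_returns_none(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 40)  # pure noise, no trend
        assert fit_linear_region(np.arange(40.0), y, r2_min=0.9) is None

    def test_too_few_points(self):
        assert fit_linear_region(np.arange(3.0), np.arange(3.0)) is None


class TestClassification:
    def test_one_moving_edge_unidirectional(self):
        assert classify_event(duplex_track(0.0, 60.0)) == "unidirectional"

    def test_two_moving_edges_bidirectional(self):
        assert classify_event(duplex_track(55.0, 60.0)) == "bidirectional"

    def test_static_event_ambiguous(self):
        assert classify_event(duplex_track(0.0, 0.0)) == "ambiguous"

    def test_diverging_edge_spots_upgrade_to_bidirectional(self):
        # both forks too slow for the edge criterion alone, but a spot rides
        # each edge and the pair diverges
        ev = duplex_track(30.0, 30.0, n=200)
        t = ev.times_s
        spots = [
            SpotTrack(0, t, ev.left_um.copy(), np.ones_like(t), event_id=0),
            SpotTrack(1, t, ev.right_um.copy(), np.ones_like(t), event_id=0),
        ]
        assert classify_event(ev, spots) == "bidirectional"

    def test_foreign_spots_ignored(self):
        ev = duplex_track(0.0, 60.0)
        t = ev.times_s
        spots = [
            SpotTrack(0, t, 5.0 - 0.05 * t, np.ones_like(t), event_id=7),
            SpotTrack(1, t, 5.0 + 0.05 * t, np.ones_like(t), event_id=7),
        ]
        assert classify_event(ev, spots) == "unidirectional"


class TestRates:
    def test_exact_recovery_unidirectional(self):
        est = estimate_rate(duplex_track(0.0, 60.0), 30.0)
        assert est.ratable
        assert est.rate_total_bps == pytest.approx(60.0, rel=1e-9)
        assert est.rate_right_bps == pytest.approx(60.0, rel=1e-9)
        assert est.rate_left_bps == 0.0

    def test_exact_recovery_bidirectional_sums(self):
        est = estimate_rate(duplex_track(50.0, 70.0), 30.0)
        assert est.rate_total_bps == pytest.approx(120.0, rel=1e-9)
        assert est.rate_left_bps + est.rate_right_bps == pytest.approx(
            est.rate_total_bps, rel=1e-9
        )

    def test_static_event_has_no_rate(self):
        est = estimate_rate(duplex_track(0.0, 0.0, n=50), 30.0)
        # no growth phase: flagged unratable rather than reporting a rate
        assert not est.ratable


class TestRequiredForce:
    SCHEDULE = ForceSchedule.step_protocol(10.0, 10.0, 40.0, 60.0)

    def test_first_initiation_after_30pN_step(self):
        assert required_force([130.0, 200.0], self.SCHEDULE) == 30.0

    def test_no_events_is_no_unwinding(self):
        assert required_force([], self.SCHEDULE) == NO_UNWINDING
        assert required_force([np.nan], self.SCHEDULE) == NO_UNWINDING

    def test_initiation_in_first_plateau(self):
        assert required_force([5.0], self.SCHEDULE) == 10.0


class TestRewinding:
    def _series(self, t, length):
        return pd.DataFrame(
            {"time_s": t, "force_pN": 30.0, "length_um": length}
        )

    def test_constant_width_and_length_neither(self):
        t = np.arange(100) * 0.1
        ev = EventTrack(0, t, np.full(100, 4.0), np.full(100, 6.0))
        series = self._series(t, np.full(100, 10.0))
        res = detect_rewinding(ev, series, t_switch_s=2.0, force_pN=30.0)
        assert not res.rewound and not res.continued

    def test_shrinking_width_with_falling_length_rewound(self):
        t = np.arange(200) * 0.1
        rate_bps = 50.0
        w0 = 3.0
        width = np.maximum(w0 - rate_bps * X_DS_30 * np.maximum(t - 5.0, 0) / 1000.0, 0.2)
        ev = EventTrack(0, t, 5.0 - width / 2, 5.0 + width / 2)
        length = 12.0 - 0.01 * np.maximum(t - 5.0, 0)
        res = detect_rewinding(ev, self._series(t, length), 5.0, 30.0)
        assert res.rewound
        assert res.rewind_rate_bps == pytest.approx(rate_bps, rel=0.05)

    def test_short_post_window_indeterminate(self):
        t = np.arange(100) * 0.1
        ev = EventTrack(0, t, np.full(100, 4.0), np.full(100, 6.0))
        res = detect_rewinding(ev, self._series(t, np.full(100, 10.0)), 9.8, 30.0)
        assert res.indeterminate


def make_event(klass, rate, ratable=True, eid=0):
    return UnwindingEvent(
        event_id=eid, klass=klass, rate_total_bps=rate, rate_left_bps=np.nan,
        rate_right_bps=np.nan, r2=0.99, n_spots=0, force_pN=30.0,
        bp_dark=1000.0, bp_dL=1000.0, t_init_s=1.0, ratable=ratable,
    )


class TestSummaries:
    def test_degenerate_rates_mean_and_sd(self):
        evs = [make_event("unidirectional", 60.0, eid=i) for i in range(3)]
        s = summarize_condition(evs, comparison=None)
        st = s.class_stats["unidirectional"]
        assert st["mean_bps"] == 60.0 and st["sd_bps"] == 0.0 and st["n"] == 3

    def test_pooled_t_test_hand_computed(self):
        """{1,2,3} vs {2,3,4}: pooled-variance t = −1.2247, p ≈ 0.287."""
        evs = [make_event("bidirectional", r, eid=i) for i, r in enumerate([1, 2, 3])]
        evs += [
            make_event("unidirectional", r, eid=i + 3)
            for i, r in enumerate([2, 3, 4])
        ]
        s = summarize_condition(evs)
        assert s.t_statistic == pytest.approx(-1.224744871, rel=1e-6)
        assert s.p_value == pytest.approx(0.2878641347, rel=1e-6)

    def test_unratable_events_excluded_from_class_counts(self):
        evs = [make_event("bidirectional", 100.0, eid=0)]
        evs += [make_event("unidirectional", 60.0, eid=1)]
        evs += [make_event("unidirectional", np.nan, ratable=False, eid=2)]
        s = summarize_condition(evs, comparison=None)
        assert s.fraction_bidirectional == pytest.approx(0.5)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        evs = [
            make_event(
                "bidirectional" if i % 2 else "unidirectional",
                float(rng.uniform(40, 120)),
                eid=i,
            )
            for i in range(12)
        ]
        a = summarize_condition(evs)
        b = summarize_condition(list(reversed(evs)))
        for c in a.class_stats:
            assert a.class_stats[c]["n"] == b.class_stats[c]["n"]
            assert a.class_stats[c]["mean_bps"] == pytest.approx(
                b.class_stats[c]["mean_bps"]
            )
            assert a.class_stats[c]["sd_bps"] == pytest.approx(
                b.class_stats[c]["sd_bps"]
            )
        assert a.t_statistic == pytest.approx(b.t_statistic)

    def test_empty_comparison_class_is_nan_not_error(self):
        evs = [make_event("unidirectional", 60.0, eid=i) for i in range(4)]
        s = summarize_condition(evs)
        assert np.isnan(s.t_statistic) and np.isnan(s.p_value)

    @pytest.mark.parametrize("k,n", [(0, 10), (5, 10), (22, 40), (40, 40)])
    def test_wilson_interval_matches_scipy(self, k, n):
        lo, hi = wilson_interval(k, n)
        ref = stats.binomtest(k, n).proportion_ci(0.95, method="wilson")
        assert lo == pytest.approx(ref.low, abs=1e-9)
        assert hi == pytest.approx(ref.high, abs=1e-9)
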