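"""Synthetic-trace generator: determinism, physical consistency, protocols."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forktrack.conditions import condition
from forktrack.elasticity import DEFAULT_SSDNA, extension_per_nt_ss
from forktrack.simulate import (
    ForceSchedule,
    ImagingParams,
    SimCondition,
    simulate_channel_switch,
    simulate_trace,
)
from forktrack.tether import TemplateSpec, TetherComposition, template_preset, tether_length_um


LAMBDA = template_preset("lambda_48502")


def test_seed_determinism_bit_identical():
    cond = condition("blm_alone_30pN")
    imaging = ImagingParams(duration_s=20.0)
    sch = ForceSchedule.constant(30.0, 20.0)
    a = simulate_trace(LAMBDA, cond, imaging, sch, seed=9)
    b = simulate_trace(LAMBDA, cond, imaging, sch, seed=9)
    for name in a.kymo.channels:
        assert np.array_equal(a.kymo.channels[name], b.kymo.channels[name])
    pd.testing.assert_frame_equal(a.series, b.series)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_zero_events_constant_length():
    cond = condition("blm_alone_30pN")
    imaging = ImagingParams(duration_s=10.0, noiseless=True)
    sch = ForceSchedule.constant(30.0, 10.0)
    b = simulate_trace(LAMBDA, cond, imaging, sch, seed=3, n_events=0)
    assert b.truth.empty
    assert np.ptp(b.series["length_um"].to_numpy()) == 0.0
    # every scan line identical: no dark regions anywhere
    img = b.kymo.channels["sytox"]
    assert np.all(img == img[0])


def test_noiseless_growth_rates_single_fork():
    """A 100 bp/s fork at 30 pN: dark width grows ≈52.8 nm/s and the tether
    lengthens ≈18.8 nm/s."""
    tmpl = TemplateSpec(20_000, (10_000,))
    cond = SimCondition(
        velocity_mean=100.0, velocity_sd=0.0,
        initiation_force_quantiles=((30.0, 1.0),),
        initiation_wait_mean_s=1e-9, uni_direction="right",
    )
    imaging = ImagingParams(duration_s=40.0, noiseless=True)
    sch = ForceSchedule.constant(30.0, 40.0)
    b = simulate_trace(tmpl, cond, imaging, sch, seed=1)
    widths = np.array(
        [sum(r - l for l, r in iv) for iv in b.unwound_per_line]
    ) * extension_per_nt_ss(DEFAULT_SSDNA, 30.0)
    t = b.series["time_s"].to_numpy()
    sel = widths > 0
    w_slope = np.polyfit(t[sel], widths[sel], 1)[0]  # bp·(nm/nt) = nm/s
    l_slope = np.polyfit(t[sel], b.series["length_um"].to_numpy()[sel], 1)[0] * 1000
    assert w_slope == pytest.approx(52.7879, rel=1e-3)
    assert l_slope == pytest.approx(18.8283, rel=1e-3)


def test_length_series_matches_tether_model_everywhere():
    cond = condition("blm_rpa_30pN")
    imaging = ImagingParams(duration_s=30.0, noiseless=True)
    sch = ForceSchedule.constant(30.0, 30.0)
    b = simulate_trace(LAMBDA, cond, imaging, sch, seed=13)
    for k, unwound in enumerate(b.unwound_per_line):
        n_ss = sum(bb - aa for aa, bb in unwound)
        comp = TetherComposition(48_502 - n_ss, n_ss, n_ss, 30.0)
        assert b.series["length_um"].iloc[k] == pytest.approx(
            tether_length_um(comp), abs=1e-6
        )


def test_photon_counts_nonnegative_integers():
    cond = condition("blm_rpa_30pN")
    imaging = ImagingParams(duration_s=10.0)
    sch = ForceSchedule.constant(30.0, 10.0)
    b = simulate_trace(LAMBDA, cond, imaging, sch, seed=2)
    for img in b.kymo.channels.values():
        assert np.all(img >= 0)
        assert np.all(img == np.rint(img))


def test_collision_stops_forks():
    tmpl = TemplateSpec(20_000, (9_000, 9_500))
    cond = SimCondition(
        velocity_mean=100.0, velocity_sd=0.0,
        initiation_force_quantiles=((30.0, 1.0),),
        initiation_wait_mean_s=1e-9, uni_direction="right",
    )
    imaging = ImagingParams(duration_s=30.0, noiseless=True)
    sch = ForceSchedule.constant(30.0, 30.0)
    b = simulate_trace(tmpl, cond, imaging, sch, seed=4)
    # first event's right fork runs into the second event's region
    assert "collision" in set(b.truth["right_stop"]) | set(b.truth["left_stop"])
    # unwound intervals never overlap
    for iv in b.unwound_per_line:
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            assert b0 <= a1 + 1e-9


def test_template_end_truncation_flagged():
    tmpl = TemplateSpec(6_400, (6_000,))
    cond = SimCondition(
        velocity_mean=200.0, velocity_sd=0.0,
        initiation_force_quantiles=((30.0, 1.0),),
        initiation_wait_mean_s=1e-9, uni_direction="right",
    )
    imaging = ImagingParams(duration_s=20.0, noiseless=True)
    sch = ForceSchedule.constant(30.0, 20.0)
    b = simulate_trace(tmpl, cond, imaging, sch, seed=4)
    assert b.truth["stop_cause"].iloc[0] == "template_end"
    assert b.truth["bp_total"].iloc[0] == pytest.approx(400.0)


class TestChannelSwitch:
    def test_continue_probability_one_changes_nothing(self):
        cond = condition("switch_rewind")
        imaging = ImagingParams(duration_s=40.0, noiseless=True)
        sch = ForceSchedule.constant(30.0, 40.0)
        plain = simulate_trace(LAMBDA, cond, imaging, sch, seed=6, n_events=2)
        switched = simulate_channel_switch(
            LAMBDA, cond, imaging, sch, t_switch_s=20.0, p_continue=1.0,
            seed=6, n_events=2,
        )
        assert np.array_equal(
            plain.kymo.channels["sytox"], switched.kymo.channels["sytox"]
        )
        pd.testing.assert_frame_equal(plain.series, switched.series)

    def test_full_rewind_restores_baseline(self):
        cond = condition("switch_rewind")
        imaging = ImagingParams(duration_s=120.0, noiseless=True)
        sch = ForceSchedule.constant(30.0, 120.0)
        b = simulate_channel_switch(
            LAMBDA, cond, imaging, sch, t_switch_s=40.0, p_continue=0.0,
            seed=8, n_events=2,
        )
        assert bool(b.truth["rewound"].all())
        assert b.truth["bp_total"].max() == pytest.approx(0.0, abs=1e-6)
        assert b.series["length_um"].iloc[-1] == pytest.approx(
            b.baseline_length_um, abs=1e-6
        )
        assert b.unwound_per_line[-1] == []

    def test_continuation_fraction_matches_binomial(self):
        """p_continue = 0.75 over ≥53 forks: observed continuation within the
        95% binomial interval."""
        cond = condition("switch_rewind")
        imaging = ImagingParams(duration_s=60.0, noiseless=True)
        sch = ForceSchedule.constant(30.0, 60.0)
        continued = 0
        total = 0
        rng_seeds = np.random.default_rng(123).integers(0, 2**31 - 1, 30)
        for s in rng_seeds:
            b = simulate_channel_switch(
                LAMBDA, cond, imaging, sch, t_switch_s=20.0, p_continue=0.75,
                seed=int(s), n_events=2,
            )
            for _, row in b.truth.iterrows():
                if row["class"] == "none" or row["t_init_s"] > 20.0:
                    continue
                total += 1
                continued += not row["rewound"]
        assert total >= 53
        lo, hi = stats.binom.interval(0.95, total, 0.75)
        assert lo <= continued <= hi

    def test_switch_outside_trace_rejected(self):
        cond = condition("switch_rewind")
        imaging = ImagingParams(duration_s=40.0)
        sch = ForceSchedule.constant(30.0, 40.0)
        with pytest.raises(ValueError):
            simulate_channel_switch(
                LAMBDA, cond, imaging, sch, t_switch_s=50.0, p_continue=0.5, seed=1
            )


class TestInitiationProtocol:
    def test_thresholds_follow_configured_quantiles(self):
        """Sampled initiation thresholds reproduce the configured CDF (force
        titration with an N.U. tail) within per-bin binomial intervals."""
        cond = condition("force_titration")
        sch = ForceSchedule.step_protocol(10.0, 10.0, 40.0, 30.0)
        imaging = ImagingParams(duration_s=120.0, noiseless=True)
        counts: dict = {}
        n = 0
        for s in range(300):
            b = simulate_trace(
                template_preset("lambda_48502"), cond, imaging, sch,
                seed=10_000 + s, n_events=1,
            )
            thr = b.truth["threshold_force_pN"].iloc[0]
            key = "N.U." if np.isnan(thr) else thr
            counts[key] = counts.get(key, 0) + 1
            n += 1
        probs = {10.0: 0.10, 20.0: 0.20, 30.0: 0.30, 40.0: 0.20, "N.U.": 0.20}
        for key, p in probs.items():
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= counts.get(key, 0) <= hi, (key, counts)

    def test_step_protocol_shape(self):
        sch = ForceSchedule.step_protocol(10.0, 10.0, 40.0, 60.0)
        assert [f for f, _ in sch.plateaus] == [10.0, 20.0, 30.0, 40.0]
        assert sch.force_at(125.0) == 30.0
        assert sch.total_duration_s == 240.0


def test_imaging_param_validation():
    with pytest.raises(ValueError):
        ImagingParams(pixel_size_um=0.0)
    with pytest.warns(UserWarning, match="undersampled"):
        ImagingParams(psf_sigma_um=0.01)
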