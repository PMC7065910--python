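"""End-to-end analysis of one trace: image → tracks → events table.

Ties the stages together: segment the duplex channel, link dark regions into
events, detect/assign spots, classify each event, fit rates, convert both
estimators (dark span → nt, tether ΔL → bp) and flag their disagreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .elasticity import (
    DEFAULT_DSDNA,
    DEFAULT_SSDNA,
    PolymerModelParams,
    conversion_factor,
    extension_per_bp_ds,
    extension_per_nt_ss,
)
from .inference import (
    RewindResult,
    UnwindingEvent,
    classify_event,
    detect_rewinding,
    diverging_edge_spot_pair,
    estimate_rate,
    fit_linear_region,
    growth_phase_end,
)
from .simulate import ForceSchedule, TraceBundle
from .tracking import (
    EventTrack,
    Kymograph,
    SpotTrack,
    assign_spots_to_events,
    detect_spots,
    link_events,
    segment_dark_regions,
)

__all__ = ["AnalysisConfig", "TraceAnalysis", "analyze_trace", "events_to_frame"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the tracking/inference stages (documented defaults).

    ``threshold_mode`` is ``"median_frac"`` (robust to lamp drift; fraction of
    the brighter-half median) or ``"absolute"`` (counts; for noiseless
    oracles). The minimum-event filter (≥ ``min_lines`` lines, ≥
    ``min_width_px`` pixels at the widest) suppresses shot-noise artifacts.
    """

    threshold_mode: str = "median_frac"
    threshold_value: float = 0.5
    bead_margin_px: int = 5
    max_gap_lines: int = 2
    max_jump_px: float = 5.0
    min_lines: int = 5
    min_width_px: float = 3.0
    motion_threshold_um: float = 0.3
    r2_min: float = 0.9
    min_frac: float = 0.5
    min_snr: float = 3.0
    use_spots: bool = True
    # detection-onset transient: while the blurred dip is still deepening
    # through the threshold, the measured width races ahead of the true
    # width; widths below this floor (duplex frame) are excluded from rate
    # fits and classification (≈ 4·psf_sigma in raw-frame terms)
    min_fit_width_um: float = 0.4

    @property
    def threshold_spec(self) -> tuple[str, float]:
        return (self.threshold_mode, self.threshold_value)

    @classmethod
    def noiseless(cls, imaging) -> "AnalysisConfig":
        """Absolute half-amplitude threshold for noise-free rasters."""
        tau = imaging.background_counts + imaging.dsdna_counts_per_pixel / 2.0
        return cls(threshold_mode="absolute", threshold_value=tau)


@dataclass
class TraceAnalysis:
    events: list[UnwindingEvent]
    tracks: list[EventTrack]
    spots: list[SpotTrack]
    rewinds: dict[int, RewindResult]
    warnings: list[str]

    @property
    def frame(self) -> pd.DataFrame:
        return events_to_frame(self.events)


def to_duplex_frame(
    tracks: list[EventTrack],
    intervals_per_line: list[list[tuple[float, float]]],
    line_time_s: float,
    series: pd.DataFrame,
    ss_params: PolymerModelParams,
    ds_params: PolymerModelParams,
) -> list[EventTrack]:
    """Map edge tracks from the lab frame into the duplex frame.

    In the lab frame every unwound base pair left of a point pushes it toward
    larger x by ``x_ss − x_ds`` (tensioned ssDNA is longer per monomer than
    duplex above the crossover force), so even the static nick-side edge of a
    growing dark region translates — by the event's *own* width growth as
    well as its upstream neighbours'. Subtracting ``(1 − x_ds/x_ss) ×`` (dark
    length left of each edge, summed per scan line straight from the
    segmented intervals, partial overlap included) yields coordinates equal
    to ``bp position × x_ds``: nick edges become static and every fork edge
    moves at ``v·x_ds``. All downstream µm→bp conversions in this frame use
    the duplex extension x_ds.
    """
    if not tracks:
        return tracks
    t_ser = series["time_s"].to_numpy()
    f_ser = series["force_pN"].to_numpy()
    ratio_by_force = {
        f: 1.0
        - extension_per_bp_ds(ds_params, f) / extension_per_nt_ss(ss_params, f)
        for f in np.unique(f_ser)
    }
    n_lines = len(intervals_per_line)

    def dark_left_of(k: int, x: float) -> float:
        return sum(
            max(0.0, min(r, x) - l) for l, r in intervals_per_line[k]
        )

    corrected = []
    for ev in tracks:
        lines = np.clip(
            np.rint(ev.times_s / line_time_s).astype(int), 0, n_lines - 1
        )
        idx = np.clip(np.searchsorted(t_ser, ev.times_s), 0, len(t_ser) - 1)
        r = np.array([ratio_by_force[f_ser[i]] for i in idx])
        up_l = np.array(
            [dark_left_of(k, ev.left_um[i]) for i, k in enumerate(lines)]
        )
        up_r = np.array(
            [dark_left_of(k, ev.right_um[i]) for i, k in enumerate(lines)]
        )
        corrected.append(
            EventTrack(
                ev.event_id,
                ev.times_s,
                ev.left_um - r * up_l,
                ev.right_um - r * up_r,
            )
        )
    return corrected


def _series_level(series: pd.DataFrame, t: float, half_window_s: float = 0.5) -> float:
    ts = series["time_s"].to_numpy()
    ls = series["length_um"].to_numpy()
    sel = np.abs(ts - t) <= half_window_s
    if not sel.any():
        idx = int(np.clip(np.searchsorted(ts, t), 0, len(ts) - 1))
        return float(ls[idx])
    return float(np.median(ls[sel]))


def analyze_trace(
    kymo: Kymograph,
    series: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
    t_switch_s: float | None = None,
    trace_id: int = 0,
    ss_params: PolymerModelParams = DEFAULT_SSDNA,
    ds_params: PolymerModelParams = DEFAULT_DSDNA,
) -> TraceAnalysis:
    """Full single-trace analysis; see module docstring.

    The per-event ΔL estimate is referenced to the event's extrapolated
    initiation time (the zero-width intercept of the dark-width fit), so the
    base pairs unwound before the region first clears the detection threshold
    are counted by both estimators. Events whose time window overlaps another
    event's are flagged ``dL_confounded`` (the length change is shared).
    """
    if kymo.n_lines == 0:
        raise ValueError("kymograph has zero scan lines")
    intervals = segment_dark_regions(
        kymo, config.threshold_spec, bead_margin_px=config.bead_margin_px
    )
    tracks = link_events(
        intervals,
        kymo.pixel_size_um,
        kymo.line_time_s,
        max_gap_lines=config.max_gap_lines,
        max_jump_px=config.max_jump_px,
        min_lines=config.min_lines,
        min_width_px=config.min_width_px,
    )
    spots: list[SpotTrack] = []
    if config.use_spots:
        spots = detect_spots(
            kymo,
            min_snr=config.min_snr,
            max_gap_lines=config.max_gap_lines,
            max_jump_px=config.max_jump_px,
            min_lines=config.min_lines,
        )
        # spots live in the lab frame: assign before the duplex-frame map
        assign_spots_to_events(spots, tracks)
    lab_tracks = tracks
    # two-edge diverging spot pairs evaluated in the lab frame
    spot_pair_bi = {
        t.event_id: bool(spots) and diverging_edge_spot_pair(t, spots)
        for t in lab_tracks
    }
    tracks = to_duplex_frame(
        tracks, intervals, kymo.line_time_s, series, ss_params, ds_params
    )

    warnings: list[str] = []
    events: list[UnwindingEvent] = []
    rewinds: dict[int, RewindResult] = {}
    for ev in tracks:
        sel = (series["time_s"] >= ev.t_start) & (series["time_s"] <= ev.t_end)
        force = float(np.median(series.loc[sel, "force_pN"])) if sel.any() else float(
            series["force_pN"].iloc[0]
        )
        x_ds = extension_per_bp_ds(ds_params, force)
        # duplex-frame width = bp span × x_ds
        width = ev.width_um
        bp_dark = float(np.max(width)) * 1000.0 / x_ds

        # clean-phase sub-track: drop the detection-onset transient
        clean = np.flatnonzero(width >= config.min_fit_width_um)
        ev_fit = None
        if len(clean) >= config.min_lines:
            s = int(clean[0])
            ev_fit = EventTrack(
                ev.event_id, ev.times_s[s:], ev.left_um[s:], ev.right_um[s:]
            )

        if ev_fit is not None:
            rate = estimate_rate(
                ev_fit,
                force,
                ds_params=ds_params,
                motion_threshold_um=config.motion_threshold_um,
                r2_min=config.r2_min,
                min_frac=config.min_frac,
            )
            klass = classify_event(
                ev_fit,
                spots,
                motion_threshold_um=config.motion_threshold_um,
                spot_pair_bi=spot_pair_bi[ev.event_id],
            )
        else:
            rate = estimate_rate(
                EventTrack(ev.event_id, ev.times_s[:2], ev.left_um[:2], ev.right_um[:2]),
                force,
                ds_params=ds_params,
            )  # < min samples: unratable by construction
            klass = "ambiguous"

        # extrapolate initiation: zero-width intercept of the clean growth fit
        wfit = None
        if ev_fit is not None:
            g = growth_phase_end(ev_fit.width_um)
            wfit = fit_linear_region(
                ev_fit.times_s[:g], ev_fit.width_um[:g], r2_min=config.r2_min,
                min_frac=config.min_frac, anchored=True,
            ) or fit_linear_region(
                ev_fit.times_s[:g], ev_fit.width_um[:g], r2_min=config.r2_min,
                min_frac=config.min_frac,
            )
        if wfit is not None and wfit.slope > 1e-6:
            t_init = float(wfit.intercept / -wfit.slope) if wfit.intercept < 0 else ev.t_start
            t_init = min(max(t_init, 0.0), ev.t_start)
        else:
            t_init = ev.t_start

        try:
            conv = conversion_factor(ss_params, ds_params, force)
        except ValueError:
            conv = 0.0
        if abs(conv) > 1e-3:
            dL = _series_level(series, ev.t_end) - _series_level(series, t_init)
            bp_dL = dL * 1000.0 / conv
        else:
            bp_dL = float("nan")
            warnings.append(
                f"event {ev.event_id}: ill-conditioned ΔL conversion at "
                f"{force:.1f} pN; dark-region estimator used"
            )

        confounded = any(
            other is not ev
            and min(other.t_end, ev.t_end) > max(other.t_start, t_init)
            for other in tracks
        )

        ev_spots = [s for s in spots if s.event_id == ev.event_id]
        n_spots = _max_simultaneous(ev_spots)

        ue = UnwindingEvent(
            event_id=ev.event_id,
            klass=klass,
            rate_total_bps=rate.rate_total_bps,
            rate_left_bps=rate.rate_left_bps,
            rate_right_bps=rate.rate_right_bps,
            r2=rate.r2,
            n_spots=n_spots,
            force_pN=force,
            bp_dark=bp_dark,
            bp_dL=bp_dL,
            t_init_s=t_init,
            ratable=rate.ratable,
            dL_confounded=confounded,
            trace_id=trace_id,
        )
        if not rate.ratable:
            warnings.append(f"event {ev.event_id}: unratable (no linear region)")
        if ue.qc_disagreement():
            warnings.append(
                f"event {ev.event_id}: dark vs ΔL estimators disagree > 10%"
            )
        events.append(ue)

        if t_switch_s is not None:
            rewinds[ev.event_id] = detect_rewinding(
                ev, series, t_switch_s, force, ss_params, ds_params
            )

    return TraceAnalysis(events, tracks, spots, rewinds, warnings)


def _max_simultaneous(spots: Sequence[SpotTrack]) -> int:
    if not spots:
        return 0
    edges = []
    for s in spots:
        edges.append((s.times_s[0], 1))
        edges.append((s.times_s[-1], -1))
    best = cur = 0
    for _, d in sorted(edges):
        cur += d
        best = max(best, cur)
    return best


EVENT_COLUMNS = [
    "event_id", "class", "rate_total_bps", "rate_left_bps", "rate_right_bps",
    "r2", "n_spots", "force_pN", "bp_dark", "bp_dL", "t_init_s", "ratable",
    "dL_confounded", "trace_id",
]


def events_to_frame(events: Sequence[UnwindingEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_id": e.event_id,
            "class": e.klass,
            "rate_total_bps": e.rate_total_bps,
            "rate_left_bps": e.rate_left_bps,
            "rate_right_bps": e.rate_right_bps,
            "r2": e.r2,
            "n_spots": e.n_spots,
            "force_pN": e.force_pN,
            "bp_dark": e.bp_dark,
            "bp_dL": e.bp_dL,
            "t_init_s": e.t_init_s,
            "ratable": e.ratable,
            "dL_confounded": e.dL_confounded,
            "trace_id": e.trace_id,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
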