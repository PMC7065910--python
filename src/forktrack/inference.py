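"""From tracks to biophysical quantities.

Classifies each dark-region event as unidirectional or bidirectional (edge
motion and, when available, diverging fluorescent-protein spots), estimates
unwinding rates in bp/s by fitting the linear region of edge position versus
time and converting through the ssDNA extension at the applied force, assigns
each molecule its required initiation force under a force-step protocol
("N.U." when no event appears up to the schedule maximum), detects
post-switch rewinding, and aggregates per-condition statistics (mean ± SD,
bidirectional fraction with Wilson interval, pooled-variance two-sample
Student's t test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .elasticity import (
    DEFAULT_DSDNA,
    DEFAULT_SSDNA,
    PolymerModelParams,
    conversion_factor,
    extension_per_bp_ds,
    extension_per_nt_ss,
)
from .simulate import ForceSchedule
from .tracking import EventTrack, SpotTrack

__all__ = [
    "LinearFit",
    "fit_linear_region",
    "classify_event",
    "estimate_rate",
    "RateEstimate",
    "UnwindingEvent",
    "required_force",
    "NO_UNWINDING",
    "detect_rewinding",
    "RewindResult",
    "ConditionSummary",
    "summarize_condition",
    "wilson_interval",
]

NO_UNWINDING = "N.U."


# ---------------------------------------------------------------------------
# linear-region fitting


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r2: float
    i0: int
    i1: int  # inclusive window [i0, i1]
    slope_se: float

    @property
    def n(self) -> int:
        return self.i1 - self.i0 + 1


def _window_stats(px, py, pxx, pyy, pxy, i: int, j: int):
    """Regression sums over inclusive window [i, j] from prefix sums."""
    n = j - i + 1
    sx = px[j + 1] - px[i]
    sy = py[j + 1] - py[i]
    sxx = pxx[j + 1] - pxx[i]
    syy = pyy[j + 1] - pyy[i]
    sxy = pxy[j + 1] - pxy[i]
    den = n * sxx - sx * sx
    if den <= 0:
        return None
    slope = (n * sxy - sx * sy) / den
    intercept = (sy - slope * sx) / n
    sst = syy - sy * sy / n
    ssr = max(sst - slope * (sxy - sx * sy / n), 0.0)
    scale = max(abs(sy / n), 1.0)
    if sst <= 1e-18 * scale * scale * n:
        r2 = 1.0 if ssr <= 1e-18 * scale * scale * n else 0.0
    else:
        r2 = 1.0 - ssr / sst
    se = math.sqrt(ssr / (n - 2) / (sxx - sx * sx / n)) if n > 2 and sxx > sx * sx / n else 0.0
    return slope, intercept, r2, se


def fit_linear_region(
    t: np.ndarray,
    y: np.ndarray,
    r2_min: float = 0.9,
    min_frac: float = 0.5,
    min_pts: int = 5,
    anchored: bool = False,
) -> LinearFit | None:
    """Longest contiguous window with local-fit R² ≥ ``r2_min``.

    The window must cover at least ``min_frac`` of the samples (and at least
    ``min_pts``); among qualifying windows the longest wins, ties broken
    earliest. With ``anchored=True`` only windows starting at the first
    sample are considered — the *initial* linear region, which is the
    class-consistent rate when a fork later stops (template end, collision)
    and kinks the slope; callers fall back to the unanchored search when no
    anchored window qualifies. Returns None when no window qualifies (event
    unratable).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    if n < min_pts:
        return None
    px = np.concatenate([[0.0], np.cumsum(t)])
    py = np.concatenate([[0.0], np.cumsum(y)])
    pxx = np.concatenate([[0.0], np.cumsum(t * t)])
    pyy = np.concatenate([[0.0], np.cumsum(y * y)])
    pxy = np.concatenate([[0.0], np.cumsum(t * y)])
    min_len = max(min_pts, int(math.ceil(min_frac * n)))
    scale = max(float(np.max(np.abs(y))), 1.0)
    for length in range(n, min_len - 1, -1):
        i = np.arange(0, 1 if anchored else n - length + 1)
        j = i + length - 1
        m = float(length)
        sx = px[j + 1] - px[i]
        sy = py[j + 1] - py[i]
        sxx = pxx[j + 1] - pxx[i]
        syy = pyy[j + 1] - pyy[i]
        sxy = pxy[j + 1] - pxy[i]
        den = m * sxx - sx * sx
        valid = den > 0
        slope = np.where(valid, (m * sxy - sx * sy) / np.where(valid, den, 1.0), np.nan)
        sst = syy - sy * sy / m
        ssr = np.maximum(sst - slope * (sxy - sx * sy / m), 0.0)
        flat = sst <= 1e-18 * scale * scale * m
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(
                flat,
                np.where(ssr <= 1e-18 * scale * scale * m, 1.0, 0.0),
                1.0 - ssr / np.where(flat, 1.0, sst),
            )
        ok = valid & (r2 >= r2_min)
        if ok.any():
            k = int(np.argmax(ok))  # earliest qualifying start
            i0, j0 = int(i[k]), int(j[k])
            res = _window_stats(px, py, pxx, pyy, pxy, i0, j0)
            assert res is not None
            s, b, r, se = res
            return LinearFit(s, b, r, i0, j0, se)
    return None


def growth_phase_end(y: np.ndarray, floor_um: float = 0.05) -> int:
    """Index (exclusive) where a monotone-growth signal first nears its max.

    Forks stop at template ends, collisions, or protein removal, leaving a
    flat (or shrinking) tail that would bias a linear fit; rates are fit on
    the growth phase only. The phase ends at the first sample within
    ``max(2% of max, floor_um)`` of the maximum.
    """
    y = np.asarray(y, float)
    if len(y) == 0:
        return 0
    y_max = float(np.max(y))
    margin = max(0.02 * y_max, floor_um)
    idx = int(np.argmax(y >= y_max - margin))
    return idx + 1


# ---------------------------------------------------------------------------
# classification and rates


def diverging_edge_spot_pair(
    event: EventTrack,
    spots: Sequence[SpotTrack],
    edge_tol_um: float = 0.3,
) -> bool:
    """True if two spots ride the event's two edges and move apart.

    The fluorescent-protein signature of bidirectional unwinding is a spot at
    *each* end of the growing ssDNA, progressing in opposite directions; a
    single coil spot at one moving fork (unidirectional event) or a
    neighbour's spot inside a crowded region must not qualify, so each spot
    of the pair is required to track one edge of this event (median distance
    < ``edge_tol_um`` over the common time span). ``event`` and the spots
    must share a frame (lab-frame tracks straight from linking).
    """
    ev_spots = [s for s in spots if s.event_id == event.event_id]

    def tracks_edge(s: SpotTrack, edge_pos: np.ndarray) -> bool:
        t0 = max(s.times_s[0], event.times_s[0])
        t1 = min(s.times_s[-1], event.times_s[-1])
        sel = (s.times_s >= t0) & (s.times_s <= t1)
        if sel.sum() < 5:
            return False
        edge = np.interp(s.times_s[sel], event.times_s, edge_pos)
        return float(np.median(np.abs(s.positions_um[sel] - edge))) < edge_tol_um

    for i in range(len(ev_spots)):
        for j in range(i + 1, len(ev_spots)):
            a, b = ev_spots[i], ev_spots[j]
            for left_spot, right_spot in ((a, b), (b, a)):
                if not (
                    tracks_edge(left_spot, event.left_um)
                    and tracks_edge(right_spot, event.right_um)
                ):
                    continue
                t0 = max(left_spot.times_s[0], right_spot.times_s[0])
                t1 = min(left_spot.times_s[-1], right_spot.times_s[-1])
                ta = (left_spot.times_s >= t0) & (left_spot.times_s <= t1)
                tb = (right_spot.times_s >= t0) & (right_spot.times_s <= t1)
                if ta.sum() < 5 or tb.sum() < 5:
                    continue
                sep = np.abs(
                    left_spot.positions_um[ta]
                    - np.interp(
                        left_spot.times_s[ta],
                        right_spot.times_s[tb],
                        right_spot.positions_um[tb],
                    )
                )
                k = min(3, len(sep))
                if np.median(sep[-k:]) - np.median(sep[:k]) > 0.2:
                    return True
    return False


def classify_event(
    event: EventTrack,
    spots: Sequence[SpotTrack] = (),
    motion_threshold_um: float = 0.3,
    spot_pair_bi: bool | None = None,
) -> str:
    """Classify fork progression: 'unidirectional' | 'bidirectional' | 'ambiguous'.

    Bidirectional iff both edges move outward beyond the motion threshold, or
    a pair of spots rides the event's two edges diverging; unidirectional iff
    exactly one edge qualifies; ambiguous otherwise. ``spot_pair_bi``
    overrides the spot evaluation when the caller has computed it in a
    different frame (spots are detected in the lab frame).
    """
    disp_left = -event.left.displacement_um  # outward = toward smaller x
    disp_right = event.right.displacement_um
    left_moves = disp_left > motion_threshold_um
    right_moves = disp_right > motion_threshold_um
    if spot_pair_bi is None:
        spot_pair_bi = bool(spots) and diverging_edge_spot_pair(event, spots)
    if spot_pair_bi:
        return "bidirectional"
    if left_moves and right_moves:
        return "bidirectional"
    if left_moves ^ right_moves:
        return "unidirectional"
    return "ambiguous"


@dataclass(frozen=True)
class RateEstimate:
    rate_total_bps: float
    rate_left_bps: float
    rate_right_bps: float
    r2: float
    fit_window_s: tuple[float, float]
    ratable: bool


def estimate_rate(
    event: EventTrack,
    force_pN: float,
    ds_params: PolymerModelParams = DEFAULT_DSDNA,
    motion_threshold_um: float = 0.3,
    r2_min: float = 0.9,
    min_frac: float = 0.5,
) -> RateEstimate:
    """Unwinding rates in bp/s from the linear region of the edge tracks.

    Expects tracks in the duplex frame (see
    :func:`forktrack.pipeline.to_duplex_frame`), where positions equal
    ``bp × x_ds``: width and edge slopes (µm/s) divide by the duplex
    extension per base pair at the applied force. Fits run over the growth
    phase only (forks stop at template ends, collisions, or protein removal,
    and the flat tail would bias the slope). An edge that never clears the
    motion threshold is reported at 0 bp/s; events with no qualifying linear
    window are flagged unratable.
    """
    x_ds = extension_per_bp_ds(ds_params, force_pN)  # nm/bp
    g = growth_phase_end(event.width_um)
    width_fit = fit_linear_region(
        event.times_s[:g], event.width_um[:g], r2_min=r2_min,
        min_frac=min_frac, anchored=True,
    ) or fit_linear_region(
        event.times_s[:g], event.width_um[:g], r2_min=r2_min, min_frac=min_frac
    )
    if width_fit is None:
        return RateEstimate(
            np.nan, np.nan, np.nan, np.nan,
            (event.t_start, event.t_end), False,
        )
    rate_width = width_fit.slope * 1000.0 / x_ds

    def side_rate(outward: np.ndarray, disp: float) -> float:
        if disp <= motion_threshold_um:
            return 0.0
        gs = growth_phase_end(outward)
        fit = fit_linear_region(
            event.times_s[:gs], outward[:gs], r2_min=r2_min,
            min_frac=min_frac, anchored=True,
        ) or fit_linear_region(
            event.times_s[:gs], outward[:gs], r2_min=r2_min, min_frac=min_frac
        )
        if fit is None:
            return np.nan
        return fit.slope * 1000.0 / x_ds

    rate_left = side_rate(
        event.left_um[0] - event.left_um, -event.left.displacement_um
    )
    rate_right = side_rate(
        event.right_um - event.right_um[0], event.right.displacement_um
    )
    # per-side series are single-sloped up to each side's own stop, so their
    # sum is robust to the slope kink the width picks up when one fork stops
    # (template end / collision) mid-observation; the width fit is the
    # fallback when a side is unmeasurable
    if math.isfinite(rate_left) and math.isfinite(rate_right):
        rate_total = rate_left + rate_right
    else:
        rate_total = rate_width
    t_win = (
        float(event.times_s[width_fit.i0]),
        float(event.times_s[width_fit.i1]),
    )
    return RateEstimate(rate_total, rate_left, rate_right, width_fit.r2, t_win, True)


@dataclass
class UnwindingEvent:
    """One analyzed unwinding event, pipeline output row."""

    event_id: int
    klass: str
    rate_total_bps: float
    rate_left_bps: float
    rate_right_bps: float
    r2: float
    n_spots: int
    force_pN: float
    bp_dark: float
    bp_dL: float
    t_init_s: float
    ratable: bool
    dL_confounded: bool = False
    trace_id: int = 0

    def qc_disagreement(self) -> bool:
        """True when dark- and ΔL-based bp totals disagree by > 10%."""
        if self.dL_confounded or not np.isfinite(self.bp_dL):
            return False
        denom = max(abs(self.bp_dark), 1e-9)
        return abs(self.bp_dark - self.bp_dL) / denom > 0.10


# ---------------------------------------------------------------------------
# required force and rewinding


def required_force(
    event_init_times: Sequence[float],
    schedule: ForceSchedule,
) -> float | str:
    """Plateau force of the first event initiation; N.U. when none occurred.

    Initiations are mapped to the force plateau containing them; the molecule
    that never unwinds through the schedule maximum scores the sentinel
    ``"N.U."``.
    """
    times = [t for t in event_init_times if np.isfinite(t)]
    if not times:
        return NO_UNWINDING
    t0 = min(times)
    return schedule.plateaus[schedule.plateau_of(t0)][0]


@dataclass(frozen=True)
class RewindResult:
    rewound: bool
    continued: bool
    rewind_rate_bps: float
    indeterminate: bool = False


def detect_rewinding(
    event: EventTrack,
    series: pd.DataFrame,
    t_switch_s: float,
    force_pN: float,
    ss_params: PolymerModelParams = DEFAULT_SSDNA,
    ds_params: PolymerModelParams = DEFAULT_DSDNA,
    alpha: float = 0.05,
) -> RewindResult:
    """Post-switch rewinding call for one event (duplex-frame track).

    Rewound iff the dark width shrinks significantly after the switch (sign
    test on width increments) and the tether-length trend has the sign
    opposite to unwinding at this force; the rewind rate comes from the same
    linear-region fit applied to the shrinking width. Too few post-switch
    samples → indeterminate.
    """
    post = event.times_s >= t_switch_s
    if post.sum() < 8:
        return RewindResult(False, False, np.nan, indeterminate=True)
    t = event.times_s[post]
    w = event.width_um[post]
    # sign test on increments of time-binned means: per-line increments are
    # noise-dominated for slow reannealing, bin means are not
    n_bins = min(12, len(w) // 4)
    shrinking = False
    if n_bins >= 6:
        bins = np.array_split(w, n_bins)
        dw = np.diff([float(np.mean(b)) for b in bins])
        dw = dw[dw != 0]
        if len(dw) >= 5:
            k_neg = int(np.sum(dw < 0))
            p = stats.binomtest(k_neg, len(dw), 0.5, alternative="greater").pvalue
            shrinking = p < alpha
    sel = (series["time_s"] >= t_switch_s) & (series["time_s"] <= event.t_end)
    sl = series.loc[sel]
    conv = conversion_factor(ss_params, ds_params, force_pN)
    length_opposes = False
    if len(sl) >= 5:
        slope = np.polyfit(sl["time_s"], sl["length_um"], 1)[0]
        length_opposes = np.sign(slope) == -np.sign(conv) and slope != 0
    rewound = shrinking and length_opposes
    rate = np.nan
    if rewound:
        fit = fit_linear_region(t, w, r2_min=0.9, min_frac=0.5)
        if fit is not None and fit.slope < 0:
            # duplex-frame width: µm/s → bp/s through x_ds
            rate = -fit.slope * 1000.0 / extension_per_bp_ds(ds_params, force_pN)
    # continued: width keeps growing after the switch
    grow_fit = fit_linear_region(t, w, r2_min=0.0, min_frac=1.0)
    continued = (
        not rewound
        and grow_fit is not None
        and grow_fit.slope * (t[-1] - t[0]) > 0.15
    )
    return RewindResult(rewound, continued, rate)


# ---------------------------------------------------------------------------
# condition-level statistics


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson 95% score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(center - half, 0.0), min(center + half, 1.0))


@dataclass
class ConditionSummary:
    label: str
    n_events: int
    n_ratable: int
    class_stats: dict  # class -> {n, mean_bps, sd_bps}
    fraction_bidirectional: float
    fraction_bi_ci95: tuple[float, float]
    required_force_histogram: dict  # force (or "N.U.") -> count
    events_per_molecule_mean: float
    t_statistic: float
    p_value: float
    comparison: tuple[str, str] | None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["fraction_bi_ci95"] = list(self.fraction_bi_ci95)
        d["required_force_histogram"] = {
            str(k): v for k, v in self.required_force_histogram.items()
        }
        return d


def summarize_condition(
    events: Sequence[UnwindingEvent],
    label: str = "",
    comparison: tuple[str, str] | None = ("bidirectional", "unidirectional"),
    required_forces: Sequence[float | str] = (),
    n_molecules: int | None = None,
    equal_var: bool = True,
) -> ConditionSummary:
    """Aggregate events into per-condition statistics.

    Rate means are reported as mean ± SD (n−1 denominator) over ratable
    events per class; the bidirectional fraction counts classified events
    only (ambiguous excluded) with a Wilson 95% CI; the named classes are
    compared with a two-sample Student's t test (pooled variance by default;
    ``equal_var=False`` switches to Welch). An empty comparison class yields
    NaN statistics rather than an error.
    """
    events = list(events)
    classes = sorted({e.klass for e in events})
    class_stats: dict[str, dict] = {}
    rates: dict[str, np.ndarray] = {}
    for c in classes:
        r = np.array(
            [e.rate_total_bps for e in events if e.klass == c and e.ratable]
        )
        r = r[np.isfinite(r)]
        rates[c] = r
        class_stats[c] = {
            "n": int(len(r)),
            "mean_bps": float(np.mean(r)) if len(r) else np.nan,
            "sd_bps": float(np.std(r, ddof=1)) if len(r) > 1 else (0.0 if len(r) else np.nan),
        }
    # class tallies count ratable events only: fragments and too-short tracks
    # (no usable linear region) are not classifiable measurements
    n_bi = sum(1 for e in events if e.klass == "bidirectional" and e.ratable)
    n_uni = sum(1 for e in events if e.klass == "unidirectional" and e.ratable)
    n_classified = n_bi + n_uni
    frac_bi = n_bi / n_classified if n_classified else np.nan
    ci = wilson_interval(n_bi, n_classified) if n_classified else (0.0, 1.0)

    hist: dict = {}
    for rf in required_forces:
        hist[rf] = hist.get(rf, 0) + 1

    t_stat = p_val = np.nan
    if comparison is not None:
        a = rates.get(comparison[0], np.array([]))
        b = rates.get(comparison[1], np.array([]))
        if len(a) >= 2 and len(b) >= 2:
            t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
            t_stat, p_val = float(t_stat), float(p_val)

    epm = np.nan
    if n_molecules:
        initiated = sum(1 for e in events)
        epm = initiated / n_molecules

    return ConditionSummary(
        label=label,
        n_events=len(events),
        n_ratable=sum(1 for e in events if e.ratable),
        class_stats=class_stats,
        fraction_bidirectional=frac_bi,
        fraction_bi_ci95=ci,
        required_force_histogram=hist,
        events_per_molecule_mean=epm,
        t_statistic=t_stat,
        p_value=p_val,
        comparison=comparison,
    )
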