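"""Synthetic single-molecule unwinding traces with ground truth.

Emulates a dual-trap constant-force experiment on a nicked duplex template:
forks initiate at nicks once the scheduled force exceeds a per-event sampled
initiation threshold, progress at Gaussian-distributed velocities (one fork
for unidirectional events, two independent forks for bidirectional ones),
stop at template ends, at collisions with neighbouring events, or at the end
of the trace, and optionally rewind after a buffer-channel switch removes
the helicase.

Outputs are a multi-channel kymograph (intercalator/duplex channel, optional
fluorescent-RPA spot channel) with Gaussian PSF blur and per-pixel Poisson
photon noise, a (time, force, length) series consistent with the tether
elasticity model at every scan line, and a ground-truth event table. Given
the same seed and configuration the outputs are bit-identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .elasticity import (
    DEFAULT_DSDNA,
    DEFAULT_SSDNA,
    PolymerModelParams,
    extension_per_bp_ds,
    extension_per_nt_ss,
)
from .tether import TemplateSpec, TetherComposition, tether_length_um
from .tracking import Kymograph

__all__ = [
    "ForceSchedule",
    "SimCondition",
    "ImagingParams",
    "SwitchSpec",
    "TraceBundle",
    "simulate_trace",
    "simulate_channel_switch",
]


@dataclass(frozen=True)
class ForceSchedule:
    """Constant-force plateaus, in order: ((force_pN, duration_s), ...)."""

    plateaus: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.plateaus:
            raise ValueError("schedule needs at least one plateau")
        for f, d in self.plateaus:
            if f <= 0 or d <= 0:
                raise ValueError("plateau forces and durations must be positive")

    @classmethod
    def constant(cls, force_pN: float, duration_s: float) -> "ForceSchedule":
        return cls(((force_pN, duration_s),))

    @classmethod
    def step_protocol(
        cls,
        start_pN: float = 10.0,
        step_pN: float = 10.0,
        max_pN: float = 40.0,
        plateau_s: float = 60.0,
    ) -> "ForceSchedule":
        """Force-step protocol: start low, raise by ``step_pN`` each plateau."""
        forces = np.arange(start_pN, max_pN + 0.5 * step_pN, step_pN)
        return cls(tuple((float(f), plateau_s) for f in forces))

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.plateaus))

    @property
    def boundaries_s(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([d for _, d in self.plateaus])])

    def force_at(self, t: float) -> float:
        edges = self.boundaries_s
        idx = int(np.searchsorted(edges, t, side="right")) - 1
        idx = min(max(idx, 0), len(self.plateaus) - 1)
        return self.plateaus[idx][0]

    def plateau_of(self, t: float) -> int:
        edges = self.boundaries_s
        idx = int(np.searchsorted(edges, t, side="right")) - 1
        return min(max(idx, 0), len(self.plateaus) - 1)

    def first_plateau_reaching(self, force_pN: float) -> int | None:
        for i, (f, _) in enumerate(self.plateaus):
            if f >= force_pN - 1e-9:
                return i
        return None


@dataclass(frozen=True)
class SimCondition:
    """Statistical structure of one experimental condition.

    ``velocity_mean/sd`` calibrate single-fork (unidirectional) velocities;
    ``bi_velocity_mean/sd`` calibrate the *total* expansion rate of
    bidirectional events — each of the two independent forks is drawn from
    N(mean/2, sd/√2) so their sum has the calibrated distribution. Velocity
    draws are truncated at zero. ``initiation_force_quantiles`` maps force
    (pN) to the cumulative probability that an event's initiation threshold
    is ≤ that force; leftover mass never initiates ("N.U.").
    """

    velocity_mean: float = 60.0
    velocity_sd: float = 9.0
    p_bidirectional: float = 0.0
    bi_velocity_mean: float = 117.0
    bi_velocity_sd: float = 25.0
    initiation_force_quantiles: tuple[tuple[float, float], ...] = ((30.0, 1.0),)
    events_per_molecule_mean: float = 2.5
    rewind_rate: float = 50.0
    spot_channel: bool = False
    initiation_wait_mean_s: float = 10.0
    uni_direction: str | None = None  # None → random side; "left"/"right"

    def __post_init__(self) -> None:
        if self.velocity_sd < 0 or self.bi_velocity_sd < 0:
            raise ValueError("velocity SDs must be non-negative")
        if not 0.0 <= self.p_bidirectional <= 1.0:
            raise ValueError("p_bidirectional must be in [0, 1]")
        q = [p for _, p in self.initiation_force_quantiles]
        if any(b < a for a, b in zip(q, q[1:])) or any(not 0 <= p <= 1 for p in q):
            raise ValueError("initiation quantiles must be nondecreasing in [0,1]")
        if self.rewind_rate < 0 or self.events_per_molecule_mean < 0:
            raise ValueError("rates and counts must be non-negative")
        if self.uni_direction not in (None, "left", "right"):
            raise ValueError("uni_direction must be None, 'left' or 'right'")


@dataclass(frozen=True)
class ImagingParams:
    """Confocal line-scan imaging model.

    Typical scanning-confocal values by default; ``noiseless`` replaces
    Poisson draws with expected counts (float image) and zeroes the
    length-series noise, for oracle tests.
    """

    pixel_size_um: float = 0.1
    line_time_s: float = 0.1
    psf_sigma_um: float = 0.15
    dsdna_counts_per_pixel: float = 50.0
    background_counts: float = 5.0
    spot_counts_per_knt: float = 150.0
    egfp_background_counts: float = 2.0
    bead_width_um: float = 1.0  # rendered bead plateau; real beads are µm-scale
    duration_s: float = 80.0
    length_noise_um: float = 0.005
    noiseless: bool = False

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um", "line_time_s", "psf_sigma_um",
            "dsdna_counts_per_pixel", "duration_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.background_counts < 0 or self.length_noise_um < 0:
            raise ValueError("noise levels must be non-negative")
        if self.psf_sigma_um < self.pixel_size_um / 2:
            warnings.warn(
                "psf_sigma_um < pixel_size_um/2: PSF undersampled",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SwitchSpec:
    """Buffer-channel switch: after ``t_switch_s`` each fork with unwound DNA
    continues with probability ``p_continue``, otherwise rewinds (reanneals)
    at ``rewind_rate`` bp/s until its dark region closes."""

    t_switch_s: float
    p_continue: float
    rewind_rate: float | None = None  # None → condition.rewind_rate

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_continue <= 1.0:
            raise ValueError("p_continue must be in [0, 1]")


class _Fork:
    __slots__ = ("v", "mode", "stop_cause")

    def __init__(self, v: float) -> None:
        self.v = v  # bp/s, 0 for the absent side of a uni event
        self.mode = "run" if v > 0 else "idle"  # run|idle|stopped|rewind|closed
        self.stop_cause: str | None = None


class _Event:
    __slots__ = (
        "nick", "t_init", "klass", "left", "right", "a", "b",
        "threshold_force", "initiated",
    )

    def __init__(self, nick, t_init, klass, v_left, v_right, threshold_force):
        self.nick = nick
        self.t_init = t_init
        self.klass = klass
        self.left = _Fork(v_left)
        self.right = _Fork(v_right)
        self.a = float(nick)  # unwound interval [a, b] in bp
        self.b = float(nick)
        self.threshold_force = threshold_force
        self.initiated = t_init is not None

    @property
    def width_bp(self) -> float:
        return self.b - self.a

    def stop_cause(self) -> str:
        causes = [f.stop_cause for f in (self.left, self.right) if f.stop_cause]
        for c in ("rewound", "collision", "template_end", "trace_end"):
            if c in causes:
                return c
        return "trace_end"


@dataclass
class TraceBundle:
    """One simulated molecule: kymograph, series, truth, and provenance."""

    kymo: Kymograph
    series: pd.DataFrame  # time_s, force_pN, length_um
    truth: pd.DataFrame
    unwound_per_line: list[list[tuple[float, float]]]
    template: TemplateSpec
    condition: SimCondition
    imaging: ImagingParams
    schedule: ForceSchedule
    seed: int
    baseline_length_um: float


def _sample_threshold(rng, quantiles: Sequence[tuple[float, float]]) -> float | None:
    """Inverse-CDF draw of the initiation-threshold force; None → never (N.U.)."""
    u = rng.random()
    for force, cum in quantiles:
        if u <= cum:
            return force
    return None


def _truncated_normal(rng, mean: float, sd: float) -> float:
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    return max(mean, 1e-6)


def _plan_events(
    template: TemplateSpec,
    condition: SimCondition,
    schedule: ForceSchedule,
    rng: np.random.Generator,
    n_events: int | None,
) -> list[_Event]:
    if template.nick_positions:
        nicks = list(template.nick_positions)
        if n_events is not None and n_events > len(nicks):
            raise ValueError("template has fewer nicks than events requested")
        if n_events is not None:
            nicks = nicks[:n_events]
    else:
        count = (
            n_events
            if n_events is not None
            else int(rng.poisson(condition.events_per_molecule_mean))
        )
        lo, hi = 0.05 * template.total_bp, 0.95 * template.total_bp
        nicks = sorted(int(round(x)) for x in rng.uniform(lo, hi, size=count))

    events: list[_Event] = []
    for nick in nicks:
        thr = _sample_threshold(rng, condition.initiation_force_quantiles)
        t_init = None
        if thr is not None:
            ip = schedule.first_plateau_reaching(thr)
            if ip is not None:
                t0 = schedule.boundaries_s[ip]
                wait = rng.exponential(condition.initiation_wait_mean_s)
                t_cand = t0 + wait
                if t_cand < schedule.total_duration_s:
                    t_init = float(t_cand)
        if rng.random() < condition.p_bidirectional:
            klass = "bi"
            vl = _truncated_normal(
                rng, condition.bi_velocity_mean / 2.0,
                condition.bi_velocity_sd / math.sqrt(2.0),
            )
            vr = _truncated_normal(
                rng, condition.bi_velocity_mean / 2.0,
                condition.bi_velocity_sd / math.sqrt(2.0),
            )
        else:
            klass = "uni"
            v = _truncated_normal(rng, condition.velocity_mean, condition.velocity_sd)
            direction = condition.uni_direction or (
                "right" if rng.random() < 0.5 else "left"
            )
            vl, vr = (v, 0.0) if direction == "left" else (0.0, v)
        events.append(_Event(nick, t_init, klass, vl, vr, thr))
    return events


def _advance(events: list[_Event], dt: float, total_bp: int) -> None:
    for ev in events:
        if ev.left.mode == "run":
            ev.a -= ev.left.v * dt
        elif ev.left.mode == "rewind":
            ev.a += ev.left.v * dt
            if ev.a >= ev.nick:
                ev.a = float(ev.nick)
                ev.left.mode = "closed"
                ev.left.stop_cause = "rewound"
        if ev.right.mode == "run":
            ev.b += ev.right.v * dt
        elif ev.right.mode == "rewind":
            ev.b -= ev.right.v * dt
            if ev.b <= ev.nick:
                ev.b = float(ev.nick)
                ev.right.mode = "closed"
                ev.right.stop_cause = "rewound"
        if ev.a <= 0.0:
            ev.a = 0.0
            if ev.left.mode == "run":
                ev.left.mode = "stopped"
                ev.left.stop_cause = "template_end"
        if ev.b >= total_bp:
            ev.b = float(total_bp)
            if ev.right.mode == "run":
                ev.right.mode = "stopped"
                ev.right.stop_cause = "template_end"

    live = sorted(
        (ev for ev in events if ev.initiated), key=lambda e: e.nick
    )
    for e1, e2 in zip(live, live[1:]):
        if e1.b >= e2.a and (e1.width_bp > 0 or e2.width_bp > 0):
            mid = 0.5 * (e1.b + e2.a)
            e1.b = e2.a = mid
            if e1.right.mode == "run":
                e1.right.mode = "stopped"
                e1.right.stop_cause = "collision"
            if e2.left.mode == "run":
                e2.left.mode = "stopped"
                e2.left.stop_cause = "collision"


def _apply_switch(
    events: list[_Event], switch: SwitchSpec, condition: SimCondition, rng
) -> None:
    rate = switch.rewind_rate if switch.rewind_rate is not None else condition.rewind_rate
    for ev in events:
        if not ev.initiated:
            continue
        for fork, opened in ((ev.left, ev.a < ev.nick), (ev.right, ev.b > ev.nick)):
            if fork.mode in ("closed",):
                continue
            if not opened and fork.mode != "run":
                continue
            if rng.random() >= switch.p_continue:
                fork.mode = "rewind"
                fork.v = rate


def _bp_to_um_edges(
    boundaries_bp: np.ndarray,
    unwound: list[tuple[float, float]],
    x_ds_nm: float,
    x_ss_nm: float,
) -> np.ndarray:
    out = boundaries_bp * x_ds_nm
    for a, b in unwound:
        inside = np.clip(boundaries_bp, a, b) - a
        out = out + inside * (x_ss_nm - x_ds_nm)
    return out / 1000.0


def _render(
    unwound_per_line: list[list[tuple[float, float]]],
    forces: np.ndarray,
    lengths_um: np.ndarray,
    spot_tracks: list[list[tuple[float, float]]],
    template: TemplateSpec,
    imaging: ImagingParams,
    ss_params: PolymerModelParams,
    ds_params: PolymerModelParams,
    rng: np.random.Generator,
    spot_channel: bool,
) -> Kymograph:
    px = imaging.pixel_size_um
    bead_w = imaging.bead_width_um
    x_max_per_bp = max(
        max(extension_per_nt_ss(ss_params, f), extension_per_bp_ds(ds_params, f))
        for f in sorted(set(forces))
    )
    width_um = template.total_bp * x_max_per_bp / 1000.0 + 2 * bead_w + 1.0
    n_px = int(math.ceil(width_um / px))
    n_lines = len(unwound_per_line)
    coverage = np.zeros((n_lines, n_px))

    def deposit(row: np.ndarray, u0: float, u1: float, weight: float = 1.0) -> None:
        p0, p1 = u0 / px, u1 / px
        if p1 <= p0:
            return
        i0, i1 = int(math.floor(p0)), int(math.floor(p1))
        i0c, i1c = max(i0, 0), min(i1, n_px - 1)
        if i0 == i1:
            row[i0c] += weight * (p1 - p0)
            return
        if 0 <= i0 < n_px:
            row[i0] += weight * (i0 + 1 - p0)
        if 0 <= i1 < n_px:
            row[i1] += weight * (p1 - i1)
        row[max(i0 + 1, 0) : max(min(i1, n_px), 0)] += weight

    x_ss_cache = {f: extension_per_nt_ss(ss_params, f) for f in set(forces)}
    x_ds_cache = {f: extension_per_bp_ds(ds_params, f) for f in set(forces)}

    for k, unwound in enumerate(unwound_per_line):
        row = coverage[k]
        f = forces[k]
        x_ss, x_ds = x_ss_cache[f], x_ds_cache[f]
        # duplex segments = complement of unwound intervals on [0, N]
        bounds = [0.0]
        for a, b in unwound:
            bounds.extend((a, b))
        bounds.append(float(template.total_bp))
        um = _bp_to_um_edges(np.asarray(bounds), unwound, x_ds, x_ss) + bead_w
        for i in range(0, len(bounds) - 1, 2):  # even gaps are duplex
            deposit(row, um[i], um[i + 1])
        # beads: plateaus flanking the tether, duplex-bright
        deposit(row, 0.0, bead_w)
        tether_end = bead_w + lengths_um[k]
        deposit(row, tether_end, tether_end + bead_w)

    sigma_px = imaging.psf_sigma_um / px
    blurred = gaussian_filter1d(coverage, sigma_px, axis=1, mode="constant")
    expected = imaging.background_counts + imaging.dsdna_counts_per_pixel * blurred
    channels: dict[str, np.ndarray] = {}
    if imaging.noiseless:
        channels["sytox"] = expected
    else:
        channels["sytox"] = rng.poisson(expected).astype(np.float64)

    if spot_channel:
        amp = np.zeros((n_lines, n_px))
        for k, spots in enumerate(spot_tracks):
            row = amp[k]
            for pos_um, coil_nt in spots:
                if coil_nt <= 0:
                    continue
                counts = imaging.spot_counts_per_knt * coil_nt / 1000.0
                deposit(row, pos_um - px / 2, pos_um + px / 2, counts)
        amp = gaussian_filter1d(amp, sigma_px, axis=1, mode="constant")
        expected_g = imaging.egfp_background_counts + amp
        if imaging.noiseless:
            channels["egfp"] = expected_g
        else:
            channels["egfp"] = rng.poisson(expected_g).astype(np.float64)

    return Kymograph(channels, px, imaging.line_time_s)


def simulate_trace(
    template: TemplateSpec,
    condition: SimCondition,
    imaging: ImagingParams,
    schedule: ForceSchedule,
    seed: int,
    switch: SwitchSpec | None = None,
    n_events: int | None = None,
    ss_params: PolymerModelParams = DEFAULT_SSDNA,
    ds_params: PolymerModelParams = DEFAULT_DSDNA,
) -> TraceBundle:
    """Simulate one molecule under a force schedule; see module docstring.

    ``n_events`` overrides the Poisson event count (templates with explicit
    nicks host exactly one event per nick). Randomness is split into named
    substreams (event plan, photon noise, length noise, switch decisions) off
    a single :class:`numpy.random.SeedSequence`, so identical (seed, config)
    give bit-identical outputs.
    """
    ss = np.random.SeedSequence(seed)
    rng_events, rng_photon, rng_series, rng_switch = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    duration = min(imaging.duration_s, schedule.total_duration_s)
    n_lines = int(round(duration / imaging.line_time_s))
    dt = imaging.line_time_s

    events = _plan_events(template, condition, schedule, rng_events, n_events)
    switched = False

    unwound_per_line: list[list[tuple[float, float]]] = []
    spot_tracks: list[list[tuple[float, float]]] = []
    lengths = np.empty(n_lines)
    forces = np.empty(n_lines)
    x_ss_cache: dict[float, float] = {}
    x_ds_cache: dict[float, float] = {}

    started: set[int] = set()
    for k in range(n_lines):
        t = k * dt
        if switch is not None and not switched and t >= switch.t_switch_s:
            _apply_switch(events, switch, condition, rng_switch)
            switched = True
        for idx, ev in enumerate(events):
            if ev.initiated and idx not in started and t >= ev.t_init:
                started.add(idx)
        active = [events[i] for i in sorted(started)]
        if active:
            _advance(active, dt, template.total_bp)

        f = schedule.force_at(t)
        forces[k] = f
        if f not in x_ss_cache:
            x_ss_cache[f] = extension_per_nt_ss(ss_params, f)
            x_ds_cache[f] = extension_per_bp_ds(ds_params, f)
        unwound = sorted(
            (ev.a, ev.b) for ev in active if ev.width_bp > 1e-9
        )
        unwound_per_line.append(unwound)
        n_ss = sum(b - a for a, b in unwound)
        comp = TetherComposition(template.total_bp - n_ss, n_ss, n_ss, f)
        lengths[k] = tether_length_um(comp, ss_params, ds_params)

        spots: list[tuple[float, float]] = []
        if condition.spot_channel:
            for ev in active:
                for edge_bp, coil in (
                    (ev.a, ev.nick - ev.a),
                    (ev.b, ev.b - ev.nick),
                ):
                    if coil > 1e-9:
                        pos = _bp_to_um_edges(
                            np.asarray([edge_bp]), unwound,
                            x_ds_cache[f], x_ss_cache[f],
                        )[0] + imaging.bead_width_um
                        spots.append((float(pos), float(coil)))
        spot_tracks.append(spots)

    # outstanding forks at trace end
    for ev in events:
        for fork in (ev.left, ev.right):
            if fork.mode == "run" and fork.stop_cause is None:
                fork.stop_cause = "trace_end"

    kymo = _render(
        unwound_per_line, forces, lengths, spot_tracks, template, imaging,
        ss_params, ds_params, rng_photon, condition.spot_channel,
    )
    times = np.arange(n_lines) * dt
    noise = (
        0.0
        if imaging.noiseless or imaging.length_noise_um == 0
        else rng_series.normal(0.0, imaging.length_noise_um, size=n_lines)
    )
    series = pd.DataFrame(
        {"time_s": times, "force_pN": forces, "length_um": lengths + noise}
    )

    rows = []
    for i, ev in enumerate(events):
        rows.append(
            {
                "event_id": i,
                "nick_bp": ev.nick,
                "t_init_s": ev.t_init if ev.initiated else np.nan,
                "class": ev.klass if ev.initiated else "none",
                "v_left_bps": ev.left.v if ev.left.mode != "idle" else 0.0,
                "v_right_bps": ev.right.v if ev.right.mode != "idle" else 0.0,
                "threshold_force_pN": (
                    ev.threshold_force if ev.threshold_force is not None else np.nan
                ),
                "bp_left": ev.nick - ev.a,
                "bp_right": ev.b - ev.nick,
                "bp_total": ev.width_bp,
                "stop_cause": ev.stop_cause() if ev.initiated else "not_initiated",
                "left_stop": ev.left.stop_cause or "",
                "right_stop": ev.right.stop_cause or "",
                "rewound": bool(
                    ev.initiated
                    and ("rewound" in (ev.left.stop_cause, ev.right.stop_cause))
                ),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "event_id", "nick_bp", "t_init_s", "class", "v_left_bps",
            "v_right_bps", "threshold_force_pN", "bp_left", "bp_right",
            "bp_total", "stop_cause", "left_stop", "right_stop", "rewound",
        ],
    )

    all_ds = TetherComposition(template.total_bp, 0, 0, forces[0])
    return TraceBundle(
        kymo=kymo,
        series=series,
        truth=truth,
        unwound_per_line=unwound_per_line,
        template=template,
        condition=condition,
        imaging=imaging,
        schedule=schedule,
        seed=seed,
        baseline_length_um=tether_length_um(all_ds, ss_params, ds_params),
    )


def simulate_channel_switch(
    template: TemplateSpec,
    condition: SimCondition,
    imaging: ImagingParams,
    schedule: ForceSchedule,
    t_switch_s: float,
    p_continue: float,
    seed: int,
    rewind_rate: float | None = None,
    **kwargs,
) -> TraceBundle:
    """Trace with a buffer-channel switch at ``t_switch_s``.

    After the switch each fork with unwound DNA independently continues with
    probability ``p_continue`` or rewinds at ``rewind_rate`` (default: the
    condition's) until its dark region closes and the tether length returns
    to its pre-event value.
    """
    if not 0.0 <= t_switch_s <= min(imaging.duration_s, schedule.total_duration_s):
        raise ValueError("t_switch_s must fall within the trace duration")
    switch = SwitchSpec(t_switch_s, p_continue, rewind_rate)
    return simulate_trace(
        template, condition, imaging, schedule, seed, switch=switch, **kwargs
    )
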