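"""Kymograph image analysis: dark-region segmentation, linking, spots.

A confocal line scan across a tethered DNA yields a time × position raster.
Duplex DNA is bright in the intercalator (Sytox) channel; unwound stretches
appear as dark regions that grow as forks progress. This module segments the
dark intervals per scan line, links them through time into candidate
unwinding events with left/right edge tracks (subpixel, by linear
interpolation of the threshold crossing), and detects/links fluorescent
protein spots in an optional second channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Kymograph",
    "EdgeTrack",
    "EventTrack",
    "SpotTrack",
    "segment_dark_regions",
    "link_events",
    "detect_spots",
    "assign_spots_to_events",
]


@dataclass
class Kymograph:
    """Per-channel time × position intensity rasters.

    Rows are scan lines in time order, columns positions; all channels share
    one shape and pixel grid.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    line_time_s: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("kymograph needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        if self.pixel_size_um <= 0 or self.line_time_s <= 0:
            raise ValueError("pixel_size_um and line_time_s must be positive")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} must be 2-D")
            if np.any(ch < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def n_lines(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def n_px(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_lines) * self.line_time_s


@dataclass
class EdgeTrack:
    """One edge (left or right) of a dark region through time."""

    event_id: int
    side: str  # "left" | "right"
    times_s: np.ndarray
    positions_um: np.ndarray
    subpixel: bool = True

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("edge sample times must be strictly increasing")

    @property
    def displacement_um(self) -> float:
        """Net signed displacement over the track (robust ends, median of 3)."""
        k = min(3, len(self.positions_um))
        return float(
            np.median(self.positions_um[-k:]) - np.median(self.positions_um[:k])
        )


@dataclass
class EventTrack:
    """A linked dark-region event: per-line (t, left, right) in µm."""

    event_id: int
    times_s: np.ndarray
    left_um: np.ndarray
    right_um: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.right_um < self.left_um):
            raise ValueError("right edge must not precede left edge")

    @property
    def width_um(self) -> np.ndarray:
        return self.right_um - self.left_um

    @property
    def left(self) -> EdgeTrack:
        return EdgeTrack(self.event_id, "left", self.times_s, self.left_um)

    @property
    def right(self) -> EdgeTrack:
        return EdgeTrack(self.event_id, "right", self.times_s, self.right_um)

    @property
    def t_start(self) -> float:
        return float(self.times_s[0])

    @property
    def t_end(self) -> float:
        return float(self.times_s[-1])


@dataclass
class SpotTrack:
    """A linked fluorescent spot: (t, position µm, peak intensity counts)."""

    spot_id: int
    times_s: np.ndarray
    positions_um: np.ndarray
    intensities: np.ndarray
    event_id: int | None = None


def _line_threshold(v: np.ndarray, threshold_spec: tuple[str, float]) -> float:
    mode, value = threshold_spec
    if mode == "absolute":
        return float(value)
    if mode == "median_frac":
        # reference = median of the duplex-bright pixels: pixels within a
        # factor 2 of the line maximum (bead glow keeps the bright mode
        # present even when unwinding has darkened most of the tether)
        vmax = float(np.max(v))
        bright = v[v >= 0.5 * vmax]
        return float(value * np.median(bright))
    raise ValueError(f"unknown threshold mode {mode!r}")


def segment_dark_regions(
    kymo: Kymograph,
    threshold_spec: tuple[str, float] = ("median_frac", 0.5),
    channel: str = "sytox",
    bead_margin_px: int = 5,
) -> list[list[tuple[float, float]]]:
    """Per scan line, maximal sub-threshold runs as (left, right) edges in µm.

    Edges are refined to subpixel precision by linear interpolation of the
    threshold crossing between the bracketing pixels. A ``bead_margin_px``
    band at both raster ends is excluded, and runs touching the trimmed
    boundary (background beyond the beads) are dropped.
    """
    if channel not in kymo.channels:
        raise KeyError(f"channel {channel!r} not present")
    img = kymo.channels[channel]
    if img.size == 0 or np.ptp(img) == 0:
        raise ValueError("no signal: empty or constant raster")
    n_px = img.shape[1]
    m = int(bead_margin_px)
    if n_px - 2 * m < 3:
        raise ValueError("bead margin leaves too few pixels")

    out: list[list[tuple[float, float]]] = []
    px = kymo.pixel_size_um
    for v in img:
        tau = _line_threshold(v.astype(float), threshold_spec)
        mask = v[m : n_px - m] < tau
        intervals: list[tuple[float, float]] = []
        if mask.any():
            dm = np.diff(mask.astype(np.int8))
            starts = np.flatnonzero(dm == 1) + 1
            ends = np.flatnonzero(dm == -1)
            if mask[0]:
                starts = np.r_[0, starts]
            if mask[-1]:
                ends = np.r_[ends, mask.size - 1]
            for s, e in zip(starts, ends):
                if s == 0 or e == mask.size - 1:
                    continue  # touches trimmed boundary: outside the tether
                i0, i1 = s + m, e + m
                # left crossing between i0-1 (>= tau) and i0 (< tau)
                d = v[i0 - 1] - v[i0]
                xl = (i0 - 1) + ((v[i0 - 1] - tau) / d if d > 0 else 0.5)
                d = v[i1 + 1] - v[i1]
                xr = i1 + ((tau - v[i1]) / d if d > 0 else 0.5)
                intervals.append((xl * px, xr * px))
        out.append(intervals)
    return out


class _Track:
    __slots__ = ("samples", "last_line", "tid", "kind")

    def __init__(
        self, tid: int, line: int, iv: tuple[float, float], kind: str = "interval"
    ) -> None:
        self.tid = tid
        self.samples: list[tuple[int, float, float]] = [(line, *iv)]
        self.last_line = line
        self.kind = kind

    @property
    def center(self) -> float:
        _, a, b = self.samples[-1]
        # interval samples are (left, right); spot samples are (pos, intensity)
        return 0.5 * (a + b) if self.kind == "interval" else a


def link_events(
    intervals_per_line: Sequence[Sequence[tuple[float, float]]],
    pixel_size_um: float,
    line_time_s: float,
    max_gap_lines: int = 2,
    max_jump_px: float = 5.0,
    min_lines: int = 5,
    min_width_px: float = 3.0,
) -> list[EventTrack]:
    """Greedy nearest-neighbour linking of dark intervals into events.

    Intervals are matched to open tracks by center distance (≤ ``max_jump_px``
    pixels), tolerating up to ``max_gap_lines`` missing lines; a match is
    also refused when the interval's width jumps by more than the same gate —
    two regions merging (forks colliding) must start a new candidate track
    rather than silently extending a parent, which would blend the
    neighbour's fork motion into the parent's edge. Unmatched intervals open
    new candidate tracks. Tracks shorter than ``min_lines`` lines or thinner
    than ``min_width_px`` pixels at their widest are discarded as shot-noise
    artifacts.
    """
    max_jump_um = max_jump_px * pixel_size_um
    open_tracks: list[_Track] = []
    closed: list[_Track] = []
    next_id = 0
    for line, intervals in enumerate(intervals_per_line):
        # expire tracks that exceeded the gap tolerance
        still_open = []
        for tr in open_tracks:
            if line - tr.last_line > max_gap_lines + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        unmatched = list(range(len(intervals)))
        # greedy: smallest center distance first
        pairs = sorted(
            (
                (abs(0.5 * (iv[0] + iv[1]) - tr.center), i, j)
                for j, tr in enumerate(open_tracks)
                for i, iv in enumerate(intervals)
            ),
        )
        used_tracks: set[int] = set()
        used_ivs: set[int] = set()
        for dist, i, j in pairs:
            if dist > max_jump_um or i in used_ivs or j in used_tracks:
                continue
            if open_tracks[j].last_line == line:
                continue
            _, tl, tr_r = open_tracks[j].samples[-1]
            dw = abs((intervals[i][1] - intervals[i][0]) - (tr_r - tl))
            if dw > max_jump_um:
                continue  # merge/split: do not extend across a width jump
            open_tracks[j].samples.append((line, *intervals[i]))
            open_tracks[j].last_line = line
            used_ivs.add(i)
            used_tracks.add(j)
        for i in unmatched:
            if i not in used_ivs:
                open_tracks.append(_Track(next_id, line, intervals[i]))
                next_id += 1
    closed.extend(open_tracks)

    events: list[EventTrack] = []
    for tr in closed:
        if len(tr.samples) < min_lines:
            continue
        arr = np.asarray(tr.samples, dtype=float)
        widths = arr[:, 2] - arr[:, 1]
        if widths.max() < min_width_px * pixel_size_um:
            continue
        events.append(
            EventTrack(
                event_id=len(events),
                times_s=arr[:, 0] * line_time_s,
                left_um=arr[:, 1],
                right_um=arr[:, 2],
            )
        )
    events.sort(key=lambda e: e.t_start)
    for k, e in enumerate(events):
        e.event_id = k
    return events


def detect_spots(
    kymo: Kymograph,
    channel: str = "egfp",
    min_snr: float = 3.0,
    max_gap_lines: int = 2,
    max_jump_px: float = 5.0,
    min_lines: int = 5,
) -> list[SpotTrack]:
    """Detect and link bright spots in a fluorescent-protein channel.

    Per line, local maxima exceeding ``background + min_snr·sqrt(background)``
    (shot-noise scale) are kept, refined to subpixel by parabolic
    interpolation, then linked greedily like dark-region events. Returns an
    empty list when the channel is absent (feature disabled, not an error).
    """
    if channel not in kymo.channels:
        return []
    img = kymo.channels[channel].astype(float)
    px = kymo.pixel_size_um

    open_tracks: list[_Track] = []
    closed: list[_Track] = []
    next_id = 0
    for line, v in enumerate(img):
        bg = float(np.median(v))
        floor = bg + min_snr * np.sqrt(max(bg, 1.0))
        cand: list[tuple[float, float]] = []  # (pos_um, intensity)
        core = v[1:-1]
        peaks = np.flatnonzero(
            (core > v[:-2]) & (core >= v[2:]) & (core > floor)
        ) + 1
        for i in peaks:
            denom = v[i - 1] - 2 * v[i] + v[i + 1]
            delta = 0.5 * (v[i - 1] - v[i + 1]) / denom if denom < 0 else 0.0
            cand.append(((i + float(np.clip(delta, -0.5, 0.5))) * px, float(v[i])))

        still_open = []
        for tr in open_tracks:
            if line - tr.last_line > max_gap_lines + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        pairs = sorted(
            (abs(c[0] - tr.center), i, j)
            for j, tr in enumerate(open_tracks)
            for i, c in enumerate(cand)
        )
        used_t: set[int] = set()
        used_c: set[int] = set()
        for dist, i, j in pairs:
            if dist > max_jump_px * px or i in used_c or j in used_t:
                continue
            if open_tracks[j].last_line == line:
                continue
            pos, inten = cand[i]
            open_tracks[j].samples.append((line, pos, inten))
            open_tracks[j].last_line = line
            used_c.add(i)
            used_t.add(j)
        for i, c in enumerate(cand):
            if i not in used_c:
                tr = _Track(next_id, line, (c[0], c[1]), kind="spot")
                next_id += 1
                open_tracks.append(tr)
    closed.extend(open_tracks)

    spots: list[SpotTrack] = []
    for tr in closed:
        if len(tr.samples) < min_lines:
            continue
        arr = np.asarray(tr.samples, dtype=float)
        spots.append(
            SpotTrack(
                spot_id=len(spots),
                times_s=arr[:, 0] * kymo.line_time_s,
                positions_um=arr[:, 1],
                intensities=arr[:, 2],
            )
        )
    return spots


def assign_spots_to_events(
    spots: list[SpotTrack],
    events: list[EventTrack],
    slack_um: float = 0.3,
) -> None:
    """Attach each spot to the event whose dark interval it rides (in place).

    A spot belongs to an event if, over their common time span, its median
    position lies within the event's [left − slack, right + slack] interval.
    """
    for sp in spots:
        best: tuple[float, int] | None = None
        for ev in events:
            t0 = max(sp.times_s[0], ev.t_start)
            t1 = min(sp.times_s[-1], ev.t_end)
            if t1 <= t0:
                continue
            sel_s = (sp.times_s >= t0) & (sp.times_s <= t1)
            sel_e = (ev.times_s >= t0) & (ev.times_s <= t1)
            if sel_s.sum() < 2 or sel_e.sum() < 2:
                continue
            pos = float(np.median(sp.positions_um[sel_s]))
            lo = float(np.median(ev.left_um[sel_e])) - slack_um
            hi = float(np.median(ev.right_um[sel_e])) + slack_um
            if lo <= pos <= hi:
                center = 0.5 * (lo + hi)
                score = abs(pos - center)
                if best is None or score < best[0]:
                    best = (score, ev.event_id)
        sp.event_id = best[1] if best else None
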