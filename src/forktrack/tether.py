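"""Geometry of a nicked dsDNA tether held at constant force.

An unwinding fork converts duplex into one tensioned ssDNA strand plus one
relaxed coiled strand; the coil carries zero end-to-end extension, so every
unwound base pair swaps one tensioned duplex bp for one tensioned nucleotide
on the tension path. This module does the bookkeeping (base-pair
conservation), the forward length model, the two inverse estimators
(ΔL → bp and dark span → nt), and the reachable extents from a nick.

Coordinates: base-pair positions are 0-based from the left trap attachment;
spatial kymograph positions are µm from the left bead edge; the bp→µm map
uses cumulative per-segment extensions at the current force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .elasticity import (
    DEFAULT_DSDNA,
    DEFAULT_SSDNA,
    PolymerModelParams,
    conversion_factor,
    extension_per_bp_ds,
    extension_per_nt_ss,
)

__all__ = [
    "TemplateSpec",
    "TetherComposition",
    "TEMPLATE_PRESETS",
    "template_preset",
    "tether_length_um",
    "bp_unwound_from_dL",
    "dark_length_to_nt",
    "reachable_extent",
    "bp_to_um",
]

CONVERSION_FLOOR_NM = 1e-3  # |x_ss - x_ds| below this is ill-conditioned


@dataclass(frozen=True)
class TemplateSpec:
    """A linear duplex template with nick entry points.

    ``nick_positions`` are 0-based bp offsets from the left attachment;
    position ``k`` puts the nick between bp ``k`` and ``k+1``.
    """

    total_bp: int
    nick_positions: tuple[int, ...] = ()
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.total_bp < 1000:
            raise ValueError("total_bp must be ≥ 1,000")
        pos = tuple(self.nick_positions)
        if any(not 0 < p < self.total_bp for p in pos):
            raise ValueError("nick positions must lie strictly inside the template")
        if list(pos) != sorted(set(pos)):
            raise ValueError("nick positions must be strictly increasing")
        object.__setattr__(self, "nick_positions", pos)


def _lambda_preset() -> TemplateSpec:
    return TemplateSpec(48_502, (), "lambda_48502")


def _nicked_6p4_preset() -> TemplateSpec:
    # single nick 2,200 bp from one end, 4,200 bp from the other
    return TemplateSpec(6_400, (2_200,), "nicked_6p4kbp")


TEMPLATE_PRESETS = {
    "lambda_48502": _lambda_preset,
    "nicked_6p4kbp": _nicked_6p4_preset,
    "nicked_6p4": _nicked_6p4_preset,
}


def template_preset(name: str) -> TemplateSpec:
    try:
        return TEMPLATE_PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown template preset {name!r}; available: "
            f"{sorted(set(TEMPLATE_PRESETS))}"
        ) from None


@dataclass
class TetherComposition:
    """Counts along the tension path at one instant.

    ``n_ds`` bp of tensioned duplex, ``n_ss`` nt of tensioned ssDNA,
    ``n_coil`` nt in zero-extension relaxed coils. For purely nick-initiated
    unwinding ``n_coil == n_ss``.
    """

    n_ds: float
    n_ss: float
    n_coil: float
    force: float

    def __post_init__(self) -> None:
        if min(self.n_ds, self.n_ss, self.n_coil) < 0:
            raise ValueError("composition counts must be non-negative")

    @property
    def total_bp(self) -> float:
        return self.n_ds + self.n_ss

    def unwind(self, bp: float) -> "TetherComposition":
        """Move *bp* base pairs from duplex to tensioned ssDNA (+coil)."""
        if bp > self.n_ds:
            raise ValueError("cannot unwind more duplex than remains")
        return TetherComposition(
            self.n_ds - bp, self.n_ss + bp, self.n_coil + bp, self.force
        )


def tether_length_um(
    comp: TetherComposition,
    ss_params: PolymerModelParams = DEFAULT_SSDNA,
    ds_params: PolymerModelParams = DEFAULT_DSDNA,
) -> float:
    """End-to-end tether length in µm; relaxed coils contribute zero."""
    x_ds = extension_per_bp_ds(ds_params, comp.force)
    x_ss = extension_per_nt_ss(ss_params, comp.force)
    return (comp.n_ds * x_ds + comp.n_ss * x_ss) / 1000.0


def bp_unwound_from_dL(
    delta_L_um: float,
    force: float,
    ss_params: PolymerModelParams = DEFAULT_SSDNA,
    ds_params: PolymerModelParams = DEFAULT_DSDNA,
) -> float:
    """Base pairs unwound from a tether-length change at constant force.

    Ill-conditioned near the ss/ds crossover force (the divisor
    ``x_ss − x_ds`` vanishes); raises there with a pointer to the
    fluorescence-based estimator, which stays valid at all forces.
    """
    factor = conversion_factor(ss_params, ds_params, force)
    if abs(factor) <= CONVERSION_FLOOR_NM:
        raise ValueError(
            f"ill-conditioned conversion at {force} pN (|x_ss - x_ds| = "
            f"{abs(factor):.2g} nm/bp ≤ {CONVERSION_FLOOR_NM}); use the "
            "dark-region (fluorescence) estimator instead"
        )
    return delta_L_um * 1000.0 / factor


def dark_length_to_nt(
    dark_span_um: float,
    force: float,
    ss_params: PolymerModelParams = DEFAULT_SSDNA,
) -> float:
    """Nucleotides of tensioned ssDNA spanning a dark region of given width.

    Primary estimator of bp unwound (1 nt tensioned ssDNA per unwound bp for
    nick-initiated forks); valid at every force including near and below the
    ΔL crossover.
    """
    if dark_span_um < 0:
        raise ValueError("dark span must be non-negative")
    return dark_span_um * 1000.0 / extension_per_nt_ss(ss_params, force)


def reachable_extent(
    template: TemplateSpec, nick_index: int, direction: Literal["left", "right"]
) -> int:
    """Base pairs between a nick and the template end in one direction."""
    try:
        pos = template.nick_positions[nick_index]
    except IndexError:
        raise IndexError(
            f"nick_index {nick_index} out of range for "
            f"{len(template.nick_positions)} nick(s)"
        ) from None
    if direction == "left":
        return pos
    if direction == "right":
        return template.total_bp - pos
    raise ValueError("direction must be 'left' or 'right'")


def bp_to_um(
    bp_grid: np.ndarray,
    unwound_intervals: Sequence[tuple[float, float]],
    force: float,
    ss_params: PolymerModelParams = DEFAULT_SSDNA,
    ds_params: PolymerModelParams = DEFAULT_DSDNA,
) -> np.ndarray:
    """Map template bp positions to µm from the left attachment.

    ``unwound_intervals`` are disjoint, sorted (start_bp, end_bp) spans that
    are currently single-stranded on the tension path; each bp inside extends
    at x_ss, each duplex bp at x_ds. Nonuniform when ss and ds mix.
    """
    x_ds = extension_per_bp_ds(ds_params, force)
    x_ss = extension_per_nt_ss(ss_params, force)
    bp_grid = np.asarray(bp_grid, dtype=float)
    out = bp_grid * x_ds
    for a, b in unwound_intervals:
        if b < a:
            raise ValueError("unwound interval end before start")
        # bp beyond the interval shift by the full differential; bp inside
        # shift proportionally
        inside = np.clip(bp_grid, a, b) - a
        out += inside * (x_ss - x_ds)
    return out / 1000.0
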