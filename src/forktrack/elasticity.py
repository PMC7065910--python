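"""Force–extension models for tensioned DNA strands.

Two closed-form polymer models cover the 0–60 pN range of a dual-trap
experiment:

* ssDNA — extensible freely-jointed chain (eFJC):
  ``x(F) = L_c [coth(bF/kT) - kT/(bF)] (1 + F/S)``
  with contour length per nucleotide ``L_c``, Kuhn length ``b`` and stretch
  modulus ``S``.
* dsDNA — extensible worm-like chain in the Odijk high-force form:
  ``x(F) = L_c [1 - (1/2)·sqrt(kT/(F·P)) + F/S]``
  with persistence length ``P``.

Everything downstream (base pairs unwound from a tether-length change, dark
ssDNA span to nucleotides) is a ratio of these two extensions, so this module
also provides the per-base-pair conversion factor ``x_ss(F) - x_ds(F)`` and
its crossover root, numerical inversion extension→force, and least-squares
fitting of model parameters to measured force–extension points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "KB_PN_NM_PER_K",
    "PolymerModelParams",
    "DEFAULT_SSDNA",
    "DEFAULT_DSDNA",
    "extension_per_nt_ss",
    "extension_per_bp_ds",
    "extension_per_monomer",
    "conversion_factor",
    "crossover_force",
    "invert_extension",
    "fit_force_extension",
    "FitResult",
]

#: Boltzmann constant in pN·nm/K.
KB_PN_NM_PER_K = 0.0138064852

FORCE_MAX_PN = 60.0  # above this dsDNA overstretches; models not valid

StrandKind = Literal["dsDNA", "ssDNA"]


@dataclass(frozen=True)
class PolymerModelParams:
    """Elasticity constants for one strand type.

    Parameters
    ----------
    strand_kind
        ``"ssDNA"`` (eFJC) or ``"dsDNA"`` (extensible WLC).
    contour_per_monomer
        Contour length per nt or bp, nm.
    persistence_or_kuhn
        Kuhn length ``b`` (ssDNA) or persistence length ``P`` (dsDNA), nm.
    stretch_modulus
        Enthalpic stretch modulus ``S``, pN.
    temperature
        Absolute temperature, K.
    """

    strand_kind: StrandKind
    contour_per_monomer: float
    persistence_or_kuhn: float
    stretch_modulus: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.strand_kind not in ("dsDNA", "ssDNA"):
            raise ValueError(f"unknown strand_kind {self.strand_kind!r}")
        for name in ("contour_per_monomer", "persistence_or_kuhn", "stretch_modulus"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 273.0 <= self.temperature <= 320.0:
            raise ValueError("temperature must be within [273, 320] K")

    @property
    def kT(self) -> float:
        """Thermal energy, pN·nm."""
        return KB_PN_NM_PER_K * self.temperature


# Canonical literature defaults; experiments run at 25 °C (kT = 4.11 pN·nm).
DEFAULT_SSDNA = PolymerModelParams("ssDNA", 0.56, 1.5, 800.0)
DEFAULT_DSDNA = PolymerModelParams("dsDNA", 0.34, 50.0, 1200.0)


def _check_force(force: float, upper: float = FORCE_MAX_PN) -> None:
    if not force > 0:
        raise ValueError(f"force must be > 0 pN, got {force}")
    if force > upper:
        raise ValueError(
            f"force {force} pN outside the validity window (0, {upper}] pN "
            "(dsDNA overstretching)"
        )


def extension_per_nt_ss(params: PolymerModelParams, force: float) -> float:
    """Mean eFJC extension per nucleotide at *force*, nm/nt.

    Strictly increasing in force; ``force == 0`` returns the analytic limit 0.
    """
    if params.strand_kind != "ssDNA":
        raise ValueError("extension_per_nt_ss requires ssDNA parameters")
    if force == 0:
        return 0.0
    _check_force(force)
    u = params.persistence_or_kuhn * force / params.kT
    # Langevin function; stable for small u via expm1-free series is not
    # needed at experimental forces, but guard anyway.
    if u < 1e-4:
        langevin = u / 3.0 - u**3 / 45.0
    else:
        langevin = 1.0 / math.tanh(u) - 1.0 / u
    return params.contour_per_monomer * langevin * (1.0 + force / params.stretch_modulus)


def extension_per_bp_ds(params: PolymerModelParams, force: float) -> float:
    """Odijk extensible-WLC extension per base pair at *force*, nm/bp.

    Valid where the Odijk expansion holds, i.e. ``(1/2)·sqrt(kT/(F·P)) < 1``
    and ``force ≤ 60 pN`` (below overstretching).
    """
    if params.strand_kind != "dsDNA":
        raise ValueError("extension_per_bp_ds requires dsDNA parameters")
    if force == 0:
        return 0.0
    _check_force(force)
    wlc_term = 0.5 * math.sqrt(params.kT / (force * params.persistence_or_kuhn))
    if wlc_term >= 1.0:
        fmin = params.kT / (4.0 * params.persistence_or_kuhn)
        raise ValueError(
            f"force {force} pN below the Odijk validity bound (> {fmin:.4g} pN "
            f"required for these parameters; window ({fmin:.4g}, {FORCE_MAX_PN}] pN)"
        )
    return params.contour_per_monomer * (1.0 - wlc_term + force / params.stretch_modulus)


def extension_per_monomer(params: PolymerModelParams, force: float) -> float:
    """Dispatch to the model matching ``params.strand_kind``."""
    if params.strand_kind == "ssDNA":
        return extension_per_nt_ss(params, force)
    return extension_per_bp_ds(params, force)


def conversion_factor(
    ss_params: PolymerModelParams = DEFAULT_SSDNA,
    ds_params: PolymerModelParams = DEFAULT_DSDNA,
    force: float = 30.0,
) -> float:
    """Tether-length change per unwound base pair, nm/bp: x_ss(F) − x_ds(F).

    Each unwound bp replaces one tensioned duplex bp with one tensioned
    nucleotide; the complementary nucleotide joins a zero-extension coil.
    Positive above the ss/ds crossover force (≈6 pN at defaults), negative
    below it.
    """
    return extension_per_nt_ss(ss_params, force) - extension_per_bp_ds(ds_params, force)


def crossover_force(
    ss_params: PolymerModelParams = DEFAULT_SSDNA,
    ds_params: PolymerModelParams = DEFAULT_DSDNA,
) -> float:
    """Force at which ssDNA and dsDNA extensions per monomer are equal, pN.

    The Odijk dsDNA form degenerates toward its low-force validity bound, so
    the physical crossover is located as the uppermost sign change of the
    conversion factor on a grid over the validity window.
    """
    fmin = ds_params.kT / (4.0 * ds_params.persistence_or_kuhn) * (1 + 1e-6)
    grid = np.geomspace(max(fmin, 1e-3), FORCE_MAX_PN, 400)
    f = lambda F: conversion_factor(ss_params, ds_params, F)
    vals = np.array([f(F) for F in grid])
    sign_changes = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if len(sign_changes) == 0:
        raise ValueError("no ss/ds extension crossover in the validity window")
    k = sign_changes[-1]
    return optimize.brentq(f, grid[k], grid[k + 1], xtol=1e-12)


def invert_extension(params: PolymerModelParams, target_extension: float) -> float:
    """Force (pN) at which the model extension per monomer equals the target.

    Monotone bisection/Brent root find on the validity window; accurate to
    1e-6 pN. ``target_extension == 0`` returns 0 (zero-force limit).
    """
    if target_extension < 0:
        raise ValueError("target extension must be non-negative")
    if target_extension == 0:
        return 0.0
    if params.strand_kind == "dsDNA":
        fmin = params.kT / (4.0 * params.persistence_or_kuhn) * (1 + 1e-9)
    else:
        fmin = 1e-9
    x_max = extension_per_monomer(params, FORCE_MAX_PN)
    x_min = extension_per_monomer(params, fmin)
    if target_extension > x_max or target_extension < x_min * (1 - 1e-12):
        raise ValueError(
            f"extension {target_extension} nm/monomer unattainable on "
            f"({fmin:.4g}, {FORCE_MAX_PN}] pN (range [{x_min:.4g}, {x_max:.4g}])"
        )
    g = lambda F: extension_per_monomer(params, F) - target_extension
    return optimize.brentq(g, fmin, FORCE_MAX_PN, xtol=1e-9)


@dataclass(frozen=True)
class FitResult:
    params: PolymerModelParams
    residuals_nm: np.ndarray
    rmse_nm: float


def fit_force_extension(
    points: Sequence[tuple[float, float]],
    strand_kind: StrandKind,
    temperature: float = 298.0,
) -> FitResult:
    """Least-squares fit of (L_c, b or P, S) to (force pN, extension nm) points.

    Extensions are per monomer (nm/nt or nm/bp). Requires at least 5 points
    spanning at least 10 pN of force.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 (force, extension) points")
    forces, exts = pts[:, 0], pts[:, 1]
    if forces.max() - forces.min() < 10.0:
        raise ValueError("force range must span at least 10 pN")
    template = DEFAULT_SSDNA if strand_kind == "ssDNA" else DEFAULT_DSDNA
    template = replace(template, temperature=temperature)

    def model(F, lc, pb, s):
        p = replace(
            template,
            contour_per_monomer=lc,
            persistence_or_kuhn=pb,
            stretch_modulus=s,
        )
        return np.array([extension_per_monomer(p, f) for f in F])

    p0 = (
        template.contour_per_monomer,
        template.persistence_or_kuhn,
        template.stretch_modulus,
    )
    try:
        popt, _ = optimize.curve_fit(
            model, forces, exts, p0=p0,
            bounds=([1e-3, 1e-3, 1.0], [5.0, 500.0, 1e5]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"force-extension fit did not converge: {exc}") from exc
    fitted = replace(
        template,
        contour_per_monomer=float(popt[0]),
        persistence_or_kuhn=float(popt[1]),
        stretch_modulus=float(popt[2]),
    )
    resid = exts - model(forces, *popt)
    return FitResult(fitted, resid, float(np.sqrt(np.mean(resid**2))))
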