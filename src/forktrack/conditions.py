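"""Calibrated experimental-condition fixtures.

Each fixture encodes one measured condition of the underlying experiments as
the statistical ground truth the simulator draws from: mean ± SD fork
velocities, the unidirectional/bidirectional mixture, events per molecule,
and the initiation-force distribution. Benchmarks then ask whether the full
image-synthesis → tracking → conversion → fitting pipeline recovers these
numbers.

Velocities are Gaussian truncated at zero. The bidirectional calibration is
the *total* dark-region expansion rate (the two independent forks each draw
N(mean/2, sd/√2), so their sum matches the calibration).
"""

from __future__ import annotations

from .simulate import SimCondition

__all__ = ["CONDITIONS", "condition"]

#: Named condition fixtures.
CONDITIONS: dict[str, SimCondition] = {
    # Full-length helicase alone, λ template, 30 pN: unidirectional only,
    # 60 ± 9 bp/s; a couple of nick-initiated events per molecule.
    "blm_alone_30pN": SimCondition(
        velocity_mean=60.0,
        velocity_sd=9.0,
        p_bidirectional=0.0,
        initiation_force_quantiles=((10.0, 0.15), (20.0, 0.45), (30.0, 1.0)),
        events_per_molecule_mean=2.5,
        spot_channel=False,
    ),
    # Helicase + ssDNA-binding protein, λ, 30 pN: 53% bidirectional;
    # uni 72 ± 24 bp/s, bi total 117 ± 25 bp/s; 3.4 events per molecule;
    # labeled RPA gives a spot channel.
    "blm_rpa_30pN": SimCondition(
        velocity_mean=72.0,
        velocity_sd=24.0,
        p_bidirectional=0.53,
        bi_velocity_mean=117.0,
        bi_velocity_sd=25.0,
        initiation_force_quantiles=((10.0, 0.35), (20.0, 0.70), (30.0, 1.0)),
        events_per_molecule_mean=3.4,
        spot_channel=True,
    ),
    # Truncated (core) helicase + RPA: slower, 42% bidirectional, and the
    # bi/uni rate ratio calibrated at 1.7. Absolute core rates are a package
    # calibration choice (slower than the full-length enzyme).
    "corebm_rpa_30pN": SimCondition(
        velocity_mean=50.0,
        velocity_sd=17.0,
        p_bidirectional=0.42,
        bi_velocity_mean=85.0,
        bi_velocity_sd=20.0,
        initiation_force_quantiles=((10.0, 0.25), (20.0, 0.60), (30.0, 1.0)),
        events_per_molecule_mean=3.0,
        spot_channel=True,
    ),
    # Single-nick 6.4 kbp template: one fork on the tensioned strand (runs
    # toward the 4.2 kbp side), quick initiation at 30 pN.
    "nicked_6p4": SimCondition(
        velocity_mean=60.0,
        velocity_sd=9.0,
        p_bidirectional=0.0,
        initiation_force_quantiles=((30.0, 1.0),),
        events_per_molecule_mean=1.0,
        initiation_wait_mean_s=2.0,
        uni_direction="right",
        spot_channel=False,
    ),
    # Force-step titration with a no-unwinding tail: 20% of molecules never
    # initiate through the 40 pN maximum ("N.U.").
    "force_titration": SimCondition(
        velocity_mean=60.0,
        velocity_sd=9.0,
        p_bidirectional=0.0,
        initiation_force_quantiles=(
            (10.0, 0.10), (20.0, 0.30), (30.0, 0.60), (40.0, 0.80),
        ),
        events_per_molecule_mean=1.0,
        initiation_wait_mean_s=5.0,
        spot_channel=False,
    ),
    # Channel-switch / rewinding assays: unwinding then protein removal;
    # reannealing at 50 bp/s.
    "switch_rewind": SimCondition(
        velocity_mean=60.0,
        velocity_sd=9.0,
        p_bidirectional=0.0,
        initiation_force_quantiles=((30.0, 1.0),),
        events_per_molecule_mean=1.0,
        initiation_wait_mean_s=2.0,
        rewind_rate=50.0,
        spot_channel=False,
    ),
}


def condition(name: str) -> SimCondition:
    try:
        return CONDITIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition fixture {name!r}; available: {sorted(CONDITIONS)}"
        ) from None
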