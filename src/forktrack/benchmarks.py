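"""Benchmark suites: recover fixture calibrations through the full pipeline.

Each suite simulates molecules under a named condition fixture, runs the
image-analysis pipeline end to end (synthesis → segmentation → linking →
classification → elasticity conversion → linear-region fitting), and reports
the recovered quantities next to the fixture's calibration. Suites are the
backbone of the acceptance checks and of the ``benchmark`` CLI command.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Callable

import numpy as np
from scipy import stats

from .conditions import condition
from .inference import (
    NO_UNWINDING,
    UnwindingEvent,
    required_force,
    summarize_condition,
    wilson_interval,
)
from .pipeline import AnalysisConfig, analyze_trace
from .simulate import (
    ForceSchedule,
    ImagingParams,
    SimCondition,
    simulate_channel_switch,
    simulate_trace,
)
from .tether import TemplateSpec, template_preset

__all__ = ["run_condition", "SUITES", "run_suite"]


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _dedupe_fragments(res) -> list[UnwindingEvent]:
    """Keep one classified event per dark region: linking can split a single
    region (gaps, thin slivers) into several ratable tracks; retain the
    longest track and drop others whose span overlaps it."""
    by_id = {t.event_id: t for t in res.tracks}
    cls = [
        e
        for e in res.events
        if e.ratable and e.klass in ("unidirectional", "bidirectional")
    ]
    cls.sort(key=lambda e: -(by_id[e.event_id].t_end - by_id[e.event_id].t_start))
    kept: list[UnwindingEvent] = []
    for e in cls:
        tr = by_id[e.event_id]
        lo = float(np.median(tr.left_um))
        hi = float(np.median(tr.right_um))
        span = max(hi - lo, 1e-6)
        clash = False
        for k in kept:
            kt = by_id[k.event_id]
            klo = float(np.median(kt.left_um))
            khi = float(np.median(kt.right_um))
            overlap = min(hi, khi) - max(lo, klo)
            if overlap > 0.5 * span:
                clash = True
                break
        if not clash:
            kept.append(e)
    return kept



def run_condition(
    cond: SimCondition,
    template: TemplateSpec,
    imaging: ImagingParams,
    schedule: ForceSchedule,
    seed: int,
    min_events: int = 40,
    max_molecules: int = 80,
    config: AnalysisConfig | None = None,
    events_per_molecule: int | None = None,
    count: Callable[[UnwindingEvent], bool] | None = None,
) -> tuple[list[UnwindingEvent], list[float | str], int]:
    """Simulate molecules until ``min_events`` counted events are analyzed.

    Returns (events, per-molecule required forces, n_molecules). ``count``
    decides which analyzed events advance the tally (default: ratable events
    classified uni or bi).
    """
    if config is None:
        config = (
            AnalysisConfig.noiseless(imaging)
            if imaging.noiseless
            else AnalysisConfig()
        )
    if count is None:
        count = lambda e: e.ratable and e.klass in (
            "unidirectional",
            "bidirectional",
        )
    seeds = _child_seeds(seed, max_molecules)
    events: list[UnwindingEvent] = []
    req_forces: list[float | str] = []
    n_mol = 0
    for mol_seed in seeds:
        bundle = simulate_trace(
            template, cond, imaging, schedule, mol_seed,
            n_events=events_per_molecule,
        )
        res = analyze_trace(bundle.kymo, bundle.series, config, trace_id=n_mol)
        for e in res.events:
            e.trace_id = n_mol
        # one event per dark region: linking splits/merges produce fragment
        # tracks that would double-count a region
        events.extend(_dedupe_fragments(res))
        req_forces.append(
            required_force([e.t_init_s for e in res.events], schedule)
        )
        n_mol += 1
        if sum(1 for e in events if count(e)) >= min_events:
            break
    return events, req_forces, n_mol


# ---------------------------------------------------------------------------
# suites


def helicase_alone_rate(seed: int, min_events: int = 40) -> dict:
    """Helicase-alone 30 pN: recover the mean unidirectional rate (bp/s)."""
    cond = condition("blm_alone_30pN")
    template = template_preset("lambda_48502")
    imaging = ImagingParams(duration_s=160.0)
    schedule = ForceSchedule.constant(30.0, 160.0)
    events, _, n_mol = run_condition(
        cond, template, imaging, schedule, seed, min_events=min_events
    )
    rates = np.array(
        [
            e.rate_total_bps
            for e in events
            if e.ratable and e.klass == "unidirectional"
        ]
    )
    return {
        "mean_rate_bps": float(np.mean(rates)),
        "sd_rate_bps": float(np.std(rates, ddof=1)),
        "expected_bps": cond.velocity_mean,
        "n_events": int(len(rates)),
        "n_molecules": n_mol,
    }


def rpa_mixed_rates(seed: int, min_events: int = 60) -> dict:
    """Helicase+RPA 30 pN: recover uni and bi (total-expansion) mean rates."""
    cond = condition("blm_rpa_30pN")
    template = template_preset("lambda_48502")
    imaging = ImagingParams(duration_s=160.0)
    schedule = ForceSchedule.constant(30.0, 160.0)
    events, _, n_mol = run_condition(
        cond, template, imaging, schedule, seed, min_events=min_events
    )
    summary = summarize_condition(events, label="blm_rpa_30pN")
    uni = summary.class_stats.get("unidirectional", {})
    bi = summary.class_stats.get("bidirectional", {})
    ratio = (
        bi.get("mean_bps", np.nan) / uni.get("mean_bps", np.nan)
        if uni.get("n", 0)
        else np.nan
    )
    return {
        "uni_mean_bps": uni.get("mean_bps", np.nan),
        "uni_n": uni.get("n", 0),
        "bi_mean_bps": bi.get("mean_bps", np.nan),
        "bi_n": bi.get("n", 0),
        "ratio_bi_over_uni": float(ratio),
        "fraction_bidirectional": summary.fraction_bidirectional,
        "t_statistic": summary.t_statistic,
        "p_value": summary.p_value,
        "expected_uni_bps": cond.velocity_mean,
        "expected_bi_bps": cond.bi_velocity_mean,
        "n_molecules": n_mol,
    }


def rpa_bidirectional_fraction(seed: int, n_events: int = 40) -> dict:
    """Exactly ``n_events`` helicase+RPA events: bidirectional percentage."""
    cond = condition("blm_rpa_30pN")
    template = template_preset("lambda_48502")
    imaging = ImagingParams(duration_s=160.0)
    schedule = ForceSchedule.constant(30.0, 160.0)
    seeds = _child_seeds(seed, 64)
    events: list[UnwindingEvent] = []
    remaining = n_events
    per_mol = 3
    i = 0
    while remaining > 0 and i < len(seeds):
        k = min(per_mol, remaining)
        bundle = simulate_trace(
            template, cond, imaging, schedule, seeds[i], n_events=k
        )
        res = analyze_trace(bundle.kymo, bundle.series, trace_id=i)
        events.extend(_dedupe_fragments(res))
        remaining -= k
        i += 1
    n_bi = sum(1 for e in events if e.klass == "bidirectional" and e.ratable)
    n_uni = sum(1 for e in events if e.klass == "unidirectional" and e.ratable)
    n_cls = n_bi + n_uni
    frac = n_bi / n_cls if n_cls else float("nan")
    lo, hi = wilson_interval(n_bi, n_cls)
    return {
        "fraction_bidirectional_pct": 100.0 * frac,
        "n_classified": n_cls,
        "n_bidirectional": n_bi,
        "mixture_p": cond.p_bidirectional,
        "wilson_ci_pct": [100.0 * lo, 100.0 * hi],
        "n_requested": n_events,
    }


def class_ttest_power(seed: int, n_replicates: int = 200) -> dict:
    """Fraction of replicate event sets where bi > uni at p < 0.01.

    Statistical-power companion to the rate suite: each replicate draws a
    fresh 40-event sample from the fixture's calibrated velocity mixture and
    applies the pooled-variance Student's t test between classes.
    """
    cond = condition("blm_rpa_30pN")
    rng = np.random.default_rng(seed)
    hits = 0
    used = 0
    for _ in range(n_replicates):
        n = 40
        is_bi = rng.random(n) < cond.p_bidirectional
        uni = np.abs(rng.normal(cond.velocity_mean, cond.velocity_sd, (~is_bi).sum()))
        bi = np.abs(
            rng.normal(cond.bi_velocity_mean / 2, cond.bi_velocity_sd / math.sqrt(2), (is_bi.sum(), 2)).sum(axis=1)
        )
        if len(uni) < 2 or len(bi) < 2:
            continue
        used += 1
        _, p = stats.ttest_ind(bi, uni, equal_var=True)
        if p < 0.01:
            hits += 1
    return {
        "power_p_lt_0p01": hits / used if used else float("nan"),
        "n_replicates": used,
    }


def core_helicase_ratio_suite(seed: int, min_events: int = 40) -> dict:
    """Core-helicase + RPA: recover the bi/uni rate ratio (calibrated 1.7)."""
    cond = condition("corebm_rpa_30pN")
    template = template_preset("lambda_48502")
    imaging = ImagingParams(duration_s=160.0)
    schedule = ForceSchedule.constant(30.0, 160.0)
    events, _, n_mol = run_condition(
        cond, template, imaging, schedule, seed, min_events=min_events
    )
    summary = summarize_condition(events, label="corebm_rpa_30pN")
    uni = summary.class_stats.get("unidirectional", {})
    bi = summary.class_stats.get("bidirectional", {})
    ratio = bi.get("mean_bps", np.nan) / uni.get("mean_bps", np.nan)
    return {
        "ratio_bi_over_uni": float(ratio),
        "expected_ratio": cond.bi_velocity_mean / cond.velocity_mean,
        "uni_mean_bps": uni.get("mean_bps", np.nan),
        "bi_mean_bps": bi.get("mean_bps", np.nan),
        "uni_n": uni.get("n", 0),
        "bi_n": bi.get("n", 0),
        "n_molecules": n_mol,
    }


def nick_polarity_extent(seed: int) -> dict:
    """Nicked 6.4 kbp template, tensioned-strand fork run to completion.

    Noiseless single-fork trace at 30 pN; the fork initiated at the nick
    (2,200 bp from one end) unwinds toward the far end. Reports the unwound
    extent in kbp from both estimators (dark span and tether ΔL).
    """
    cond = replace(condition("nicked_6p4"), velocity_sd=9.0)
    template = template_preset("nicked_6p4kbp")
    imaging = ImagingParams(duration_s=160.0, noiseless=True)
    schedule = ForceSchedule.constant(30.0, 160.0)
    bundle = simulate_trace(template, cond, imaging, schedule, seed)
    res = analyze_trace(
        bundle.kymo, bundle.series, AnalysisConfig.noiseless(imaging)
    )
    ratable = [e for e in res.events if e.ratable]
    ev = max(ratable or res.events, key=lambda e: e.bp_dark)
    truth_bp = float(bundle.truth["bp_total"].iloc[0])
    return {
        "extent_dark_kbp": ev.bp_dark / 1000.0,
        "extent_dL_kbp": ev.bp_dL / 1000.0,
        "truth_kbp": truth_bp / 1000.0,
        "expected_kbp": 4.2,
        "class": ev.klass,
    }


def rewinding_switch_suite(seed: int, n_molecules: int = 12) -> dict:
    """Protein removal: every fork rewinds; recover the rewind rate.

    Molecules unwind for 60 s at 30 pN, then the buffer switch (p_continue=0)
    triggers reannealing at the fixture's 50 bp/s until dark regions close.
    """
    cond = condition("switch_rewind")
    template = template_preset("lambda_48502")
    imaging = ImagingParams(duration_s=140.0)
    schedule = ForceSchedule.constant(30.0, 140.0)
    t_switch = 60.0
    seeds = _child_seeds(seed, n_molecules)
    calls = []
    rates = []
    for s in seeds:
        bundle = simulate_channel_switch(
            template, cond, imaging, schedule, t_switch, p_continue=0.0,
            seed=s, n_events=1,
        )
        res = analyze_trace(bundle.kymo, bundle.series, t_switch_s=t_switch)
        for ev in res.events:
            rw = res.rewinds.get(ev.event_id)
            if rw is None or rw.indeterminate:
                continue
            if not ev.ratable:
                continue  # fragments / unmeasurable tracks
            calls.append(rw.rewound)
            if rw.rewound and np.isfinite(rw.rewind_rate_bps):
                rates.append(rw.rewind_rate_bps)
    frac = float(np.mean(calls)) if calls else float("nan")
    return {
        "fraction_rewound": frac,
        "mean_rewind_rate_bps": float(np.mean(rates)) if rates else float("nan"),
        "expected_rate_bps": cond.rewind_rate,
        "n_events": len(calls),
    }


SUITES: dict[str, Callable[..., dict]] = {
    "helicase_alone": helicase_alone_rate,
    "rpa_mixed": rpa_mixed_rates,
    "rpa_bidirectional_fraction": rpa_bidirectional_fraction,
    "ttest_power": class_ttest_power,
    "core_ratio": core_helicase_ratio_suite,
    "nick_polarity_extent": nick_polarity_extent,
    "rewinding": rewinding_switch_suite,
}


def run_suite(name: str, seeds: list[int]) -> dict:
    """Run a registered suite once per seed; report per-seed results."""
    if name not in SUITES:
        raise KeyError(f"unknown suite {name!r}; available: {sorted(SUITES)}")
    if not seeds:
        raise ValueError("at least one seed is required")
    fn = SUITES[name]
    return {"suite": name, "runs": {str(s): fn(s) for s in seeds}}
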