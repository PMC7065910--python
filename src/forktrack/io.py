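"""On-disk formats and run configuration.

A simulated trace is persisted as a *bundle* directory:

* ``kymo.tiff`` — one TIFF page per channel (float32);
* ``sidecar.json`` — pixel size, line time, channel order, force schedule,
  seed, package version, and metadata flags;
* ``series.csv`` — ``time_s,force_pN,length_um``;
* ``truth.tsv`` — ground-truth event table;
* ``config.yaml`` — the resolved run configuration;
* ``run.log`` — human-readable log lines.

``RunConfig`` round-trips losslessly through YAML and rejects unknown keys.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .conditions import CONDITIONS
from .pipeline import AnalysisConfig
from .simulate import ForceSchedule, ImagingParams, SimCondition, TraceBundle
from .tether import TEMPLATE_PRESETS, TemplateSpec, template_preset
from .tracking import Kymograph

__all__ = [
    "RunConfig",
    "FormatError",
    "write_bundle",
    "read_bundle",
    "write_events_tsv",
    "read_events_tsv",
]

log = logging.getLogger("forktrack")


class FormatError(RuntimeError):
    """A bundle on disk is incomplete or malformed."""


# ---------------------------------------------------------------------------
# config


def _known_fields(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def _build(cls, section: dict, name: str):
    unknown = set(section) - _known_fields(cls)
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
    return cls(**section)


def _condition_from_dict(d: dict) -> SimCondition:
    d = dict(d)
    if "fixture" in d:
        base = CONDITIONS[d.pop("fixture")]
        merged = dataclasses.asdict(base)
        merged.update(d)
        d = merged
    if "initiation_force_quantiles" in d:
        q = d["initiation_force_quantiles"]
        if isinstance(q, dict):
            q = sorted(q.items())
        d["initiation_force_quantiles"] = tuple(
            (float(f), float(p)) for f, p in q
        )
    return _build(SimCondition, d, "condition")


def _schedule_from_dict(d: dict) -> ForceSchedule:
    if "plateaus" in d:
        return ForceSchedule(tuple((float(f), float(t)) for f, t in d["plateaus"]))
    if "constant" in d:
        c = d["constant"]
        return ForceSchedule.constant(float(c["force_pN"]), float(c["duration_s"]))
    if "step" in d:
        return ForceSchedule.step_protocol(**d["step"])
    raise ValueError("protocol needs 'plateaus', 'constant' or 'step'")


def _schedule_to_dict(s: ForceSchedule) -> dict:
    return {"plateaus": [[f, t] for f, t in s.plateaus]}


def _template_from_spec(spec) -> TemplateSpec:
    if isinstance(spec, str):
        return template_preset(spec)
    d = dict(spec)
    return TemplateSpec(
        int(d["total_bp"]),
        tuple(int(p) for p in d.get("nicks", ())),
        d.get("label", "custom"),
    )


@dataclass
class RunConfig:
    """One resolved simulation/analysis run."""

    template: TemplateSpec
    condition: SimCondition
    imaging: ImagingParams
    schedule: ForceSchedule
    analysis: AnalysisConfig
    seed: int
    out_dir: str
    switch: dict | None = None  # {"t_switch_s":..., "p_continue":..., ...}

    TOP_KEYS = {
        "template", "condition", "imaging", "protocol", "analysis",
        "seed", "out", "switch",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls.TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            template=_template_from_spec(d.get("template", "lambda_48502")),
            condition=_condition_from_dict(d.get("condition", {})),
            imaging=_build(ImagingParams, d.get("imaging", {}), "imaging"),
            schedule=_schedule_from_dict(
                d.get("protocol", {"constant": {"force_pN": 30.0, "duration_s": 80.0}})
            ),
            analysis=_build(AnalysisConfig, d.get("analysis", {}), "analysis"),
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out", "out")),
            switch=d.get("switch"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        cond = dataclasses.asdict(self.condition)
        cond["initiation_force_quantiles"] = [
            [f, p] for f, p in self.condition.initiation_force_quantiles
        ]
        d = {
            "template": {
                "total_bp": self.template.total_bp,
                "nicks": list(self.template.nick_positions),
                "label": self.template.label,
            },
            "condition": cond,
            "imaging": dataclasses.asdict(self.imaging),
            "protocol": _schedule_to_dict(self.schedule),
            "analysis": dataclasses.asdict(self.analysis),
            "seed": self.seed,
            "out": self.out_dir,
        }
        if self.switch is not None:
            d["switch"] = self.switch
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# bundles


def write_bundle(
    out_dir: str | Path, bundle: TraceBundle, config: RunConfig | None = None
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(bundle.kymo.channels)
    stack = np.stack(
        [bundle.kymo.channels[n].astype(np.float32) for n in names]
    )
    tifffile.imwrite(out / "kymo.tiff", stack, metadata={"axes": "CYX"})
    sidecar = {
        "pixel_size_um": bundle.kymo.pixel_size_um,
        "line_time_s": bundle.kymo.line_time_s,
        "channels": names,
        "force_schedule": _schedule_to_dict(bundle.schedule),
        "seed": bundle.seed,
        "template": {
            "total_bp": bundle.template.total_bp,
            "nicks": list(bundle.template.nick_positions),
            "label": bundle.template.label,
        },
        "baseline_length_um": bundle.baseline_length_um,
        "version": __version__,
        # literature-default elasticity constants stand in for per-experiment
        # force-extension fits; downstream reports carry this flag
        "elasticity_defaults_are_standins": True,
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    bundle.series.to_csv(out / "series.csv", index=False)
    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    if config is not None:
        config.to_yaml(out / "config.yaml")
    with open(out / "run.log", "a") as fh:
        fh.write(
            f"forktrack {__version__}: wrote bundle seed={bundle.seed} "
            f"lines={bundle.kymo.n_lines} channels={names}\n"
        )
    return out


def read_bundle(bundle_dir: str | Path):
    """Load a bundle directory → (Kymograph, series, truth, sidecar dict)."""
    d = Path(bundle_dir)
    sc_path = d / "sidecar.json"
    if not sc_path.exists():
        raise FormatError(f"missing sidecar.json in {d}")
    sidecar = json.loads(sc_path.read_text())
    try:
        stack = tifffile.imread(d / "kymo.tiff")
    except (FileNotFoundError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"unreadable kymo.tiff in {d}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    names = sidecar["channels"]
    if len(names) != stack.shape[0]:
        raise FormatError("channel count mismatch between TIFF and sidecar")
    kymo = Kymograph(
        {n: stack[i].astype(np.float64) for i, n in enumerate(names)},
        float(sidecar["pixel_size_um"]),
        float(sidecar["line_time_s"]),
    )
    series = pd.read_csv(d / "series.csv")
    truth_path = d / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None
    return kymo, series, truth, sidecar


def write_events_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    cols = [
        "event_id", "class", "rate_total_bps", "rate_left_bps",
        "rate_right_bps", "r2", "n_spots", "force_pN", "bp_dark", "bp_dL",
    ]
    extra = [c for c in frame.columns if c not in cols]
    frame[cols + extra].to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
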