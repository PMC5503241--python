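"""Configuration documents, validation, and the file output surfaces.

A scenario is described by a nested YAML or JSON document with sections
``network``, ``controller``, ``heart``, ``direct_parasym``, ``plasticity``,
``pathology``, ``schedule`` and ``run``.  Every field has a default: an empty
document is the canonical low-diversity stratified unstable-angina scenario.
Unknown keys are rejected, and each default's provenance — whether the value
is fixed by the modelled study design or is a calibration/design choice of
this package — is recorded in :data:`PROVENANCE`.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import network as _network
from . import control as _control
from . import dynamics as _dynamics
from . import pathology as _pathology
from .scenario import (
    PreludeAftermathSummary,
    ScenarioConfig,
    SimulationRecord,
)

__all__ = [
    "ConfigError",
    "load_config",
    "parse_config",
    "default_config",
    "config_to_dict",
    "write_outputs",
    "write_timeseries",
    "read_timeseries",
    "check_summary",
    "PROVENANCE",
    "example_config_path",
]


class ConfigError(ValueError):
    """A configuration document failed validation."""


def _section(dataclass_type, exclude: tuple[str, ...] = ()):
    """Build a strict pydantic model mirroring a parameter dataclass."""
    import typing

    hints = typing.get_type_hints(dataclass_type)
    fields, annotations = {}, {}
    for f in dataclasses.fields(dataclass_type):
        if f.name in exclude:
            continue
        default = (f.default if f.default is not dataclasses.MISSING
                   else f.default_factory())
        fields[f.name] = default
        annotations[f.name] = hints[f.name]
    ns = {"model_config": ConfigDict(extra="forbid"),
          "__annotations__": annotations}
    ns.update(fields)
    return type(f"{dataclass_type.__name__}Doc", (BaseModel,), ns)


_NetworkDoc = _section(_network.NetworkConfig)
_ControllerDoc = _section(_control.ControllerParams)
_HeartDoc = _section(_control.HeartParams)
_DirectParasymDoc = _section(_control.DirectParasymParams)
_PlasticityDoc = _section(_dynamics.PlasticityParams)
_PathologyDoc = _section(_pathology.PathologyConfig)
_ScheduleDoc = _section(_pathology.EpisodeSchedule)


class _RunDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str = "fig04"
    description: str = ScenarioConfig.description
    setpoint_init: float = 0.25
    setpoint_steady: float = 0.3
    setpoint_challenge: float = 0.35
    init_end: float = 500.0
    tau_a: float = 2.0
    init_heart_rate: float = 0.25
    init_p_dir: float = 0.1
    record_stride: int = 1
    master_seed: int = 0
    prelude_window: tuple[float, float] = (500.0, 2500.0)
    aftermath_window: tuple[float, float] = (16000.0, 18000.0)


class ConfigDocument(BaseModel):
    """The validated top-level document; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    network: _NetworkDoc = _NetworkDoc()
    controller: _ControllerDoc = _ControllerDoc()
    heart: _HeartDoc = _HeartDoc()
    direct_parasym: _DirectParasymDoc = _DirectParasymDoc()
    plasticity: _PlasticityDoc = _PlasticityDoc()
    pathology: _PathologyDoc = _PathologyDoc()
    schedule: _ScheduleDoc = _ScheduleDoc()
    run: _RunDoc = _RunDoc()

    def to_scenario(self) -> ScenarioConfig:
        run = self.run.model_dump()
        sched = self.schedule.model_dump()
        for key in ("onsets", "recoveries", "demands"):
            sched[key] = tuple(sched[key])
        cfg = ScenarioConfig(
            network=_network.NetworkConfig(**self.network.model_dump()),
            controller=_control.ControllerParams(**self.controller.model_dump()),
            heart=_control.HeartParams(**self.heart.model_dump()),
            direct_parasym=_control.DirectParasymParams(
                **self.direct_parasym.model_dump()),
            plasticity=_dynamics.PlasticityParams(**self.plasticity.model_dump()),
            pathology=_pathology.PathologyConfig(**self.pathology.model_dump()),
            schedule=_pathology.EpisodeSchedule(**sched),
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in run.items()},
        )
        try:
            cfg.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        return cfg


#: provenance of every configurable default: values fixed by the modelled
#: study design ("paper") vs calibration and design choices of this package
#: ("decision")
PROVENANCE: dict[str, str] = {
    "network.lcn_per_level": "paper",
    "network.connectedness": "paper",
    "network.diversity": "paper",
    "network.peer_to_adjacent_ratio": "paper",
    "network.transducer_fraction": "paper",
    "network.layer_composition": "decision",
    "network.out_degree": "decision",
    "network.parasym_pool_size": "decision",
    "network.weight_init_max": "decision",
    "network.demand_sensitivity_scale": "decision",
    "network.feedback_sensitivity_scale": "decision",
    "network.sensitivity_spread": "decision",
    "network.bias_lcn": "decision",
    "network.bias_demand": "decision",
    "network.bias_heartrate": "decision",
    "network.bias_parasym": "decision",
    "network.seed": "decision",
    "controller.k_pi": "decision",
    "controller.ti_pi": "decision",
    "controller.delay_steps": "decision",
    "controller.dt": "decision",
    "controller.demand_min": "decision",
    "controller.demand_max": "decision",
    "heart.tau_h": "decision",
    "heart.h_0": "decision",
    "heart.c_s": "decision",
    "heart.c_p": "decision",
    "heart.alpha": "decision",
    "direct_parasym.tau_p": "decision",
    "direct_parasym.overshoot_gain": "decision",
    "direct_parasym.baseline_bias": "decision",
    "plasticity.hebb_rate": "decision",
    "plasticity.weight_max": "decision",
    "plasticity.homeo_rate": "decision",
    "plasticity.scaling_rate": "decision",
    "plasticity.activity_target": "decision",
    "plasticity.activity_avg_tau": "decision",
    "plasticity.gain_min": "decision",
    "plasticity.gain_max": "decision",
    "pathology.enabled": "paper",
    "pathology.mode": "paper",
    "pathology.affected_fraction_by_level": "paper",
    "pathology.lcn_affected": "paper",
    "pathology.lcn_fate": "paper",
    "pathology.transducer_fate": "paper",
    "pathology.transducers_affected": "paper",
    "pathology.derangement": "paper",
    "pathology.derangement_hr_factor": "paper",
    "pathology.derangement_demand_factor": "paper",
    "pathology.derangement_ramp": "decision",
    "pathology.derangement_affected_only": "decision",
    "pathology.ischemic_drive_amplitude": "decision",
    "pathology.selection_seed": "decision",
    "schedule.onsets": "paper",
    "schedule.recoveries": "paper",
    "schedule.demands": "paper",
    "schedule.demand_duration": "paper",
    "schedule.aftermath_start": "paper",
    "schedule.t_end": "paper",
    "run.label": "decision",
    "run.description": "decision",
    "run.setpoint_init": "paper",
    "run.setpoint_steady": "paper",
    "run.setpoint_challenge": "paper",
    "run.init_end": "paper",
    "run.tau_a": "decision",
    "run.init_heart_rate": "decision",
    "run.init_p_dir": "decision",
    "run.record_stride": "decision",
    "run.master_seed": "decision",
    "run.prelude_window": "paper",
    "run.aftermath_window": "decision",
}


def parse_config(document: dict | None) -> ScenarioConfig:
    """Validate a nested mapping and return the scenario configuration."""
    try:
        doc = ConfigDocument(**(document or {}))
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    return doc.to_scenario()


def load_config(path: str | os.PathLike) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario document."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(data)


def default_config() -> ScenarioConfig:
    """The full-default scenario (stratified, low diversity, angina)."""
    return parse_config({})


def config_to_dict(config: ScenarioConfig) -> dict:
    """Serialize a scenario configuration back to a plain nested mapping."""
    out = {}
    for section, obj in (("network", config.network),
                         ("controller", config.controller),
                         ("heart", config.heart),
                         ("direct_parasym", config.direct_parasym),
                         ("plasticity", config.plasticity),
                         ("pathology", config.pathology),
                         ("schedule", config.schedule)):
        out[section] = dataclasses.asdict(obj)
    out["run"] = {f: getattr(config, f) for f in _RunDoc.model_fields}
    return _jsonable(out)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _no_nan(obj):
    """JSON numbers must be finite: non-finite floats become null + flag."""
    if isinstance(obj, dict):
        return {k: _no_nan(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_no_nan(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


class SummarySchema(BaseModel):
    """Shipped schema for summary.json documents."""

    model_config = ConfigDict(extra="forbid")
    label: str
    seed: int
    software_version: str
    config: dict
    flags: dict[str, str]
    prelude: dict
    aftermath: dict
    deltas: dict[str, float | None]


def check_summary(document: dict) -> None:
    """Raise ``ConfigError`` if a summary document violates the schema."""
    try:
        SummarySchema(**document)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def write_outputs(record: SimulationRecord, summary: PreludeAftermathSummary,
                  out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write timeseries.csv, summary.json and events.jsonl into ``out_dir``.

    The CSV uses '.' decimals and full-precision floats, so a write → read →
    write cycle is byte-identical at the recorded stride.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    csv_path = out / "timeseries.csv"
    write_timeseries(record.to_dataframe(), csv_path)

    summary_doc = {
        "label": summary.label,
        "seed": int(record.config.master_seed),
        "software_version": __version__,
        "config": config_to_dict(record.config),
        "flags": summary.flags,
        "prelude": summary.prelude.as_dict(),
        "aftermath": summary.aftermath.as_dict(),
        "deltas": summary.deltas,
    }
    summary_doc = _no_nan(_jsonable(summary_doc))
    check_summary(summary_doc)
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(summary_doc, indent=2) + "\n")

    events_path = out / "events.jsonl"
    with events_path.open("w") as fh:
        for ev in record.events:
            fh.write(json.dumps(_no_nan(_jsonable(ev))) + "\n")
    return {"timeseries": csv_path, "summary": json_path, "events": events_path}


def write_timeseries(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a timeseries frame with locale-free '.' decimals.

    Floats are printed with 17 significant digits so that a write -> read ->
    write cycle is byte-identical.
    """
    df.to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path: str | os.PathLike) -> pd.DataFrame:
    """Read a timeseries.csv back into a data frame (round-trip companion).

    Floats are parsed with the round-trip converter so the values are exactly
    those that were written.
    """
    return pd.read_csv(path, float_precision="round_trip")


def example_config_path(name: str) -> Path:
    """Path of a shipped example configuration (e.g. ``'fig05'`` or ``'toy'``)."""
    p = Path(__file__).parent / "examples" / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no shipped example named {name!r}")
    return p
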