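"""Flat key-value experiment configuration files.

A config file is a flat YAML mapping (``key: value``, no nesting). Keys are
split between the pipeline (:class:`slidemil.pipeline.PrepConfig`) and the
training protocol (:class:`slidemil.training.ExperimentConfig`); unknown
keys are rejected so typos fail loudly. Every threshold the pipeline or
trainer uses is exposed here with its default.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import yaml

from .pipeline import PrepConfig
from .training import ExperimentConfig


def load_config_file(path: str | Path) -> dict:
    """Read a flat YAML mapping; nested values are a configuration error."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must be a flat key-value mapping")
    for k, v in data.items():
        if isinstance(v, (dict, list)):
            raise ValueError(f"config key {k!r} is nested; flat values only")
    return data


def _build(cls, overrides: dict, used: set[str]):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in overrides.items():
        if k in names:
            kwargs[k] = tuple(v) if isinstance(v, tuple) else v
            used.add(k)
    return cls(**kwargs)


def resolve_configs(
    overrides: dict | None = None,
) -> tuple[PrepConfig, ExperimentConfig]:
    """Split flat overrides into pipeline and training configs."""
    overrides = dict(overrides or {})
    used: set[str] = set()
    prep = _build(PrepConfig, overrides, used)
    train = _build(ExperimentConfig, overrides, used)
    unknown = set(overrides) - used
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return prep, train


def run_manifest(
    config: dict, seeds: dict, inputs: dict, outputs: dict
) -> dict:
    """Provenance record written next to every produced artifact."""
    from . import __version__

    return {
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds,
        "inputs": inputs,
        "outputs": outputs,
    }


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
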