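"""Serialization helpers: config round-trips, CSV and JSON writers.

CSV output uses 12 significant digits so that re-runs diff meaningfully;
JSON sidecars echo the configuration and stimulus that produced a result.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .model import InputParams, ModelConfig, Pathways, PopulationParams

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "write_csv",
    "write_json",
]

_FLOAT_FMT = "%.12g"


def config_to_dict(config: ModelConfig) -> dict:
    return {
        "variant": config.variant,
        "population": asdict(config.population),
        "inputs": asdict(config.inputs),
        "pathways": asdict(config.pathways),
    }


def _strict(cls, payload: dict, section: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(payload) - allowed
    if unknown:
        raise KeyError(f"unknown key(s) in {section!r} section: {sorted(unknown)}")
    return cls(**payload)


def config_from_dict(payload: dict) -> ModelConfig:
    """Inverse of :func:`config_to_dict`; unknown keys raise KeyError."""
    allowed = {"variant", "population", "inputs", "pathways"}
    unknown = set(payload) - allowed
    if unknown:
        raise KeyError(f"unknown top-level key(s): {sorted(unknown)}")
    return ModelConfig(
        population=_strict(PopulationParams, payload.get("population", {}), "population"),
        inputs=_strict(InputParams, payload.get("inputs", {}), "inputs"),
        pathways=_strict(Pathways, payload.get("pathways", {}), "pathways"),
        variant=payload.get("variant", "custom"),
    )


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_json(payload: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
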