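"""YAML configuration for the pipeline stages.

One file drives all stages; command-line flags override config values.  Every
stage echoes the effective configuration (including the seed) next to its
outputs, so a run can be reproduced from its artefacts alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Type, TypeVar

import yaml

from .quantify import CompartmentParams
from .segmentation import SegmentationParams
from .synthetic import SyntheticSpec

T = TypeVar("T")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dataclass_from_dict(cls: Type[T], data: dict[str, Any]) -> T:
    """Build a params dataclass, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            # YAML lists for tuple-typed fields (shapes, ranges, distractors)
            val = coerced[f.name]
            coerced[f.name] = (
                [tuple(v) if isinstance(v, list) else v for v in val]
                if any(isinstance(v, list) for v in val)
                else tuple(val)
            )
    return cls(**coerced)


class PipelineConfig:
    """Validated configuration of a full simulate->segment->quantify->stats run."""

    def __init__(self, data: dict[str, Any]):
        self.raw = dict(data)
        if "pixel_size_um" not in data and "synthetic" not in data:
            raise ValueError("config must set pixel_size_um (or a synthetic block)")
        self.seed = int(data.get("seed", 0))
        synth = dict(data.get("synthetic", {}))
        synth.setdefault("seed", self.seed)
        self.synthetic = dataclass_from_dict(SyntheticSpec, synth)
        self.segmentation = dataclass_from_dict(
            SegmentationParams, data.get("segmentation", {})
        )
        self.compartments = dataclass_from_dict(
            CompartmentParams, data.get("compartments", {})
        )
        self.pixel_size_um = float(
            data.get("pixel_size_um", self.synthetic.pixel_size_um)
        )
        self.legacy_n = int(data.get("legacy_n", 40))
        self.bins = int(data.get("bins", 64))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls(load_yaml(path))

    def echo(self, out_dir: str | Path) -> Path:
        out = Path(out_dir) / "config_echo.json"
        payload = {
            "seed": self.seed,
            "pixel_size_um": self.pixel_size_um,
            "synthetic": self.synthetic.to_dict(),
            "segmentation": dataclasses.asdict(self.segmentation),
            "compartments": dataclasses.asdict(self.compartments),
            "legacy_n": self.legacy_n,
            "bins": self.bins,
        }
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return out
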