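"""Nested run configuration with JSON round-trip and strict key checking."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .io import Calibration
from .morphometry import MorphometryConfig
from .regions import RegionConfig
from .segmentation import SegmentationConfig

__all__ = ["RunConfig", "load_config"]

CONFIG_SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """Effective configuration for a full quantification run.

    Nested blocks: ``calibration``, ``collagen``/``tissue``/``portal``
    (segmentation), ``regions`` and ``morphometry``.  Unknown keys in a
    config file are rejected rather than ignored.
    """

    calibration: Calibration = field(default_factory=Calibration)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    regions: RegionConfig = field(default_factory=RegionConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    alpha: float = 0.05
    schema_version: str = CONFIG_SCHEMA_VERSION

    def as_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "calibration": dataclasses.asdict(self.calibration),
            "segmentation": dataclasses.asdict(self.segmentation),
            "regions": dataclasses.asdict(self.regions),
            "morphometry": dataclasses.asdict(self.morphometry),
            "alpha": self.alpha,
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


_BLOCKS = {
    "calibration": Calibration,
    "segmentation": SegmentationConfig,
    "regions": RegionConfig,
    "morphometry": MorphometryConfig,
}


def _build_block(cls, payload: dict, block: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown keys in config block {block!r}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
    }
    return cls(**coerced)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a JSON config, filling defaults; None returns all defaults."""
    if path is None:
        return RunConfig()
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError("config must be a JSON object")
    unknown = set(payload) - set(_BLOCKS) - {"alpha", "schema_version"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for block, cls in _BLOCKS.items():
        if block in payload:
            kwargs[block] = _build_block(cls, payload[block], block)
    if "alpha" in payload:
        kwargs["alpha"] = float(payload["alpha"])
    return RunConfig(**kwargs)
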