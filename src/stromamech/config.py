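"""Configuration loading with per-subcommand schema validation.

Configs are flat YAML/JSON mappings whose keys must match the fields of
the target parameter dataclass; unknown keys are rejected by name and the
dataclass's own ``__post_init__`` validation supplies range checks.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .omics_stats import LfqSimParams
from .synth_fibers import FiberFieldParams
from .synth_pillars import ForceEvent, PillarArrayParams

__all__ = ["load_config", "load_params", "CONFIG_SCHEMAS"]

CONFIG_SCHEMAS = {
    "simulate-fibers": FiberFieldParams,
    "simulate-pillars": PillarArrayParams,
    "simulate-lfq": LfqSimParams,
}


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON mapping; an empty file means all defaults."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return raw


def load_params(subcommand: str, raw: dict, seed: int | None = None):
    """Validate a raw config dict into the subcommand's parameter object."""
    cls = CONFIG_SCHEMAS[subcommand]
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(
            f"unknown config key(s) for {subcommand}: {sorted(unknown)}"
        )
    raw = dict(raw)
    if "image_size_px" in raw:
        raw["image_size_px"] = tuple(raw["image_size_px"])
    if "drift_um_per_frame" in raw:
        raw["drift_um_per_frame"] = tuple(raw["drift_um_per_frame"])
    if "force_events" in raw:
        raw["force_events"] = tuple(
            ev if isinstance(ev, ForceEvent)
            else ForceEvent(pillar_id=int(ev["pillar_id"]),
                            force_nN=ev["force_nN"])
            for ev in raw["force_events"]
        )
    if seed is not None:
        raw["seed"] = seed
    return cls(**raw)
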