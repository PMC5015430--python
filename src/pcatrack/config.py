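"""Run configuration: defaults merged with YAML overrides, strictly validated.

The YAML schema mirrors the dataclasses::

    seed: 0
    tracker:
      n_stages: 2
      hidden_units: 64
      motion: {std_x: 15, std_y: 15, std_w: 0.1, std_h: 0.1, n_particles: 1000}
      ...
    scene:
      frame_size: [128, 128]
      occluder: {start_frame: 20, n_frames: 5, coverage: 0.5}
      ...

Unknown keys anywhere are rejected before any computation runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .synthetic import OccluderConfig, SceneConfig
from .tracker import MotionConfig, TrackerConfig

__all__ = ["RunConfig", "load_config", "dump_config"]

_NESTED = {
    "motion": MotionConfig,
    "occluder": OccluderConfig,
    "tracker": TrackerConfig,
    "scene": SceneConfig,
}


def _build(cls, data: dict, context: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{context}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, f"{context}.{key}")
        elif key in ("frame_size", "velocity") and isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs: master seed, tracker, and scene."""

    seed: int = 0
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            data = loaded
    if overrides:
        data = _merge(data, overrides)
    return _build(RunConfig, data, "config")


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def dump_config(cfg: RunConfig) -> str:
    """Serialize a config back to YAML (round-trips through load_config)."""

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: plain(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        return obj

    return yaml.safe_dump(plain(cfg), sort_keys=False)
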