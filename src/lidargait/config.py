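"""Shared run configuration: one TOML file drives every CLI subcommand.

Sections map directly onto the module configuration types::

    seed = 0                # top level: seed, out_dir, log_level
    [detection]             # DetectionCriteria fields
    link_distance = 100.0
    [tracker]               # TrackerConfig fields
    score_min = 0.002
    [gait]                  # GaitConfig fields
    v_stance_frac = 0.2
    [scene]                 # SceneConfig fields (scan_rate, duration, ...)
    scan_rate = 15.0
    [sensor]
    position = [-4000.0, 0.0]
    heading = 0.0
    [[walkers]]             # WalkerSpec fields, one table per walker
    gait_speed = 1.2

CLI flags override file values, which override the package defaults.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

from .detection import DetectionCriteria
from .gait import GaitConfig
from .scan_io import SensorPose
from .simulate import SceneConfig, WalkerSpec
from .tracking import TrackerConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    detection: DetectionCriteria = DetectionCriteria()
    tracker: TrackerConfig = TrackerConfig()
    gait: GaitConfig = GaitConfig()
    scene: SceneConfig = SceneConfig()
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def with_seed(self, seed: int | None) -> "RunConfig":
        if seed is None:
            return self
        return replace(self, seed=seed, scene=replace(self.scene, seed=seed))


def _build(cls, table: dict, **extra):
    known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
    unknown = set(table) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(table)
    # TOML arrays come back as lists; dataclasses here want tuples
    for key, value in kwargs.items():
        if isinstance(value, list):
            kwargs[key] = tuple(value)
    kwargs.update(extra)
    return cls(**kwargs)


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a RunConfig from TOML; missing sections fall back to defaults."""
    if path is None:
        return RunConfig().with_seed(seed)
    with open(path, "rb") as fh:
        data = tomllib.load(fh)

    detection = _build(DetectionCriteria, data.get("detection", {}))
    tracker = _build(TrackerConfig, data.get("tracker", {}))
    gait = _build(GaitConfig, data.get("gait", {}))

    sensor_tbl = data.get("sensor", {})
    sensor = SensorPose(
        tuple(sensor_tbl.get("position", (-4000.0, 0.0))),
        sensor_tbl.get("heading", 0.0),
    )
    walkers = tuple(_build(WalkerSpec, w) for w in data.get("walkers", []))
    scene_tbl = dict(data.get("scene", {}))
    scene_kwargs = {"sensor": sensor}
    if walkers:
        scene_kwargs["walkers"] = walkers
    scene = _build(SceneConfig, scene_tbl, **scene_kwargs)

    cfg = RunConfig(
        detection=detection,
        tracker=tracker,
        gait=gait,
        scene=scene,
        seed=data.get("seed", 0),
        out_dir=data.get("out_dir", "."),
        log_level=data.get("log_level", "INFO"),
    )
    return cfg.with_seed(seed)


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the full effective configuration."""
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
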