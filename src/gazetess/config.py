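"""Experiment configuration: one human-editable YAML file per experiment.

The file declares the screen geometry, the gaze-log dialect, detection and
clustering parameters, input logs, stimulus conditions, and the manual
cell-label maps.  Loading and dumping round-trip unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .clustering import ClusterConfig
from .events import DetectionConfig
from .geometry import ScreenGeometry
from .io import LogDialect

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, resolvable from one YAML file."""

    geometry: ScreenGeometry
    dialect: LogDialect = field(default_factory=LogDialect)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    inputs: list = field(default_factory=list)  # gaze-log paths
    conditions: dict = field(default_factory=dict)  # stimulus -> static|dynamic
    windows: dict = field(default_factory=dict)  # stimulus -> [start_ms, end_ms]
    labels: dict = field(default_factory=dict)  # stimulus -> {cell index: label}
    output_dir: str = "gazetess_out"
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "geometry": asdict(self.geometry),
            "dialect": asdict(self.dialect),
            "detection": asdict(self.detection),
            "clustering": asdict(self.clustering),
            "inputs": list(self.inputs),
            "conditions": dict(self.conditions),
            "windows": {str(k): [float(a), float(b)] for k, (a, b) in self.windows.items()},
            "labels": {str(k): {int(i): str(v) for i, v in m.items()}
                       for k, m in self.labels.items()},
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        return d


def _from_dict(d: dict) -> PipelineConfig:
    return PipelineConfig(
        geometry=ScreenGeometry(**d["geometry"]),
        dialect=LogDialect(**d.get("dialect", {})),
        detection=DetectionConfig(**d.get("detection", {})),
        clustering=ClusterConfig(**d.get("clustering", {})),
        inputs=list(d.get("inputs", [])),
        conditions=dict(d.get("conditions", {})),
        windows={str(k): (float(v[0]), float(v[1]))
                 for k, v in d.get("windows", {}).items()},
        labels={str(k): {int(i): str(v) for i, v in m.items()}
                for k, m in d.get("labels", {}).items()},
        output_dir=d.get("output_dir", "gazetess_out"),
        seed=int(d.get("seed", 0)),
    )


def load_config(path) -> PipelineConfig:
    with Path(path).open() as fh:
        return _from_dict(yaml.safe_load(fh))


def dump_config(config: PipelineConfig, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
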