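"""Pipeline configuration: one flat, fully-seeded parameter record.

Every tunable of the pipeline lives here with its default; configs round-trip
losslessly through YAML and unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # stroke candidate generation
    boundary_samples: int = 128
    stroke_keypoints: int = 7
    stroke_sigma: float = 1.0
    stroke_m: float = 4.0
    pool_size: int = 200
    regions_k: int = 12
    min_area_frac: float = 0.001
    dup_iou: float = 0.95
    # stroke features / detection
    appearance_band: float = 4.0
    appearance_stride: int = 1
    nms_overlap: float = 0.2
    nms_tol: float = 2.0
    f_tolerance_frac: float = 0.0075
    detection_threshold: float = 0.5
    regressor_trees: int = 500
    # biometric encoding
    fin_samples: int = 1024
    fin_keypoints: int = 50
    fin_sigma: float = 2.0
    fin_m: float = 8.0
    subsection_samples: int = 256
    scales: tuple = (1.0, 2.0, 4.0, 8.0)
    dogn_m: float = 2.0
    normal_variant: str = "unit-normals"
    # fin space
    partitions_per_edge: int = 5
    scale_bins: int = 5
    match_trees: int = 500
    neg_ratio: float = 5.0
    # synthetic data
    n_individuals: int = 20
    sightings_per_individual: int = 6
    preset: str = "standard"
    canvas: tuple = (256, 256)
    # global
    seed: int = 0

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["scales"] = list(self.scales)
        payload["canvas"] = list(self.canvas)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scales" in payload:
            payload = dict(payload, scales=tuple(payload["scales"]))
        if "canvas" in payload:
            payload = dict(payload, canvas=tuple(payload["canvas"]))
        return cls(**payload)
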