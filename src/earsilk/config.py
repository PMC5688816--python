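"""Pipeline configuration: every tunable constant of the five analysis stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .plant_segmentation import DEFAULT_HSV_BOUNDS
from .silk_segmentation import EAR_HSV_BOUNDS


@dataclass
class PipelineConfig:
    # side-view segmentation
    ratio_threshold: float = 0.5
    hsv_bounds: tuple = DEFAULT_HSV_BOUNDS
    min_component: int = 30
    # view selection
    view_tol: float = 25.0
    robust_iters: int = 3
    inlier_fraction: float = 0.9
    max_views: int = 6
    # ear detection
    r2_cutoff: float = 0.82          # stem straightness filter
    reference_percentile: float = 0.15
    w1: float = 1.0                  # long-peak criterion weight
    w2: float = 2.0                  # thinner-internodes-above criterion weight
    peak_ratio: float = 1.3      # junction-peak flagging vs local baseline
    above_ratio: float = 1.1     # ear-run threshold vs reference width
    min_run: int = 3
    ratio_drop: float = 0.75
    height_tol_frac: float = 0.05    # consensus tolerance, fraction of plant height
    # silk segmentation
    ear_hsv_bounds: tuple = EAR_HSV_BOUNDS
    colour_sigma: float = 5.0
    tensor_sigma: float = 1.6
    deriv_sigma: float = 1.0
    n_trees: int = 100
    # growth fitting
    n_breakpoints: int = 1
    noise_floor_frac: float = 0.02
    rate_threshold: float = 0.2
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]
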