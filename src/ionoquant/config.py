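"""Pipeline configuration with lossless YAML round trips."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .segmentation import SegmentationParams

__all__ = ["PipelineConfig"]


@dataclass
class QuantificationParams:
    measurement_tophat_yxz: tuple[int, int, int] = (15, 15, 1)
    rolling_ball_radius: float = 50.0
    brightest_k: int = 1

    def to_dict(self) -> dict:
        return {"measurement_tophat_yxz": list(self.measurement_tophat_yxz),
                "rolling_ball_radius": self.rolling_ball_radius,
                "brightest_k": self.brightest_k}

    @classmethod
    def from_dict(cls, d: dict) -> "QuantificationParams":
        d = dict(d)
        if "measurement_tophat_yxz" in d:
            d["measurement_tophat_yxz"] = tuple(d["measurement_tophat_yxz"])
        return cls(**d)


@dataclass
class CountingParams:
    pair_distance_um: float = 10.0
    kind: str = "mature"

    def to_dict(self) -> dict:
        return {"pair_distance_um": self.pair_distance_um, "kind": self.kind}

    @classmethod
    def from_dict(cls, d: dict) -> "CountingParams":
        return cls(**d)


@dataclass
class StatsParams:
    method_two_group: str = "adaptive"  # normality-gated t / Mann-Whitney
    method_multi_group: str = "anova_dunnett"
    control_condition: Optional[str] = "embryo_medium"
    normalize_to_control: bool = False
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {"method_two_group": self.method_two_group,
                "method_multi_group": self.method_multi_group,
                "control_condition": self.control_condition,
                "normalize_to_control": self.normalize_to_control,
                "alpha": self.alpha}

    @classmethod
    def from_dict(cls, d: dict) -> "StatsParams":
        return cls(**d)


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline end to end, reproducibly."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    quantification: QuantificationParams = field(default_factory=QuantificationParams)
    counting: CountingParams = field(default_factory=CountingParams)
    statistics: StatsParams = field(default_factory=StatsParams)
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"segmentation": self.segmentation.to_dict(),
                "quantification": self.quantification.to_dict(),
                "counting": self.counting.to_dict(),
                "statistics": self.statistics.to_dict(),
                "seed": self.seed,
                "paths": dict(self.paths)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            segmentation=SegmentationParams.from_dict(d.get("segmentation", {})),
            quantification=QuantificationParams.from_dict(d.get("quantification", {})),
            counting=CountingParams.from_dict(d.get("counting", {})),
            statistics=StatsParams.from_dict(d.get("statistics", {})),
            seed=d.get("seed", 0),
            paths=dict(d.get("paths", {})),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable config digest for stamping output artifacts."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
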