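"""Pipeline configuration: one validated, serialisable parameter block.

Defaults equal the workflow's stated processing values: picking
threshold 200,000 counts / prominence 0 / distance 5 points, ceiling
KMD rounding, lipid window KMD 0.10-0.50 and m/z 200-1400, 2 ppm CH2
chaining, 3 ppm alignment.  Every run can snapshot its effective
configuration (stable YAML) and a content hash for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import yaml

from .annotate import RankingPolicy
from .kmd import KMDWindow
from .masses import KendrickParams
from .spectral import PickingParams

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass
class PipelineConfig:
    # acquisition / simulation
    grid_height: int = 64
    grid_width: int = 64
    pixel_size_um: float = 50.0
    seed: int = 0
    # spectral processing
    picking: PickingParams = field(default_factory=PickingParams)
    alignment_tolerance_ppm: float = 3.0
    recalibrate: bool = False
    recalibration_tolerance_ppm: float = 5.0
    # parameters of the external recalibration method cited by the study;
    # recorded for provenance, not interpreted by the simplified model.
    external_recalibration_params: Dict[str, float] = field(
        default_factory=lambda: {"st": 0.0003, "tl": 0.02, "lm": 0.002}
    )
    # Kendrick analysis
    kendrick: KendrickParams = field(default_factory=KendrickParams)
    window: KMDWindow = field(default_factory=KMDWindow)
    kmd_class_tolerance: float = 0.0025
    ch2_ppm: float = 2.0
    ch2_k_max: int = 6
    vertical_ppm: float = 2.0
    vertical_span_steps: int = 3
    collapse_ppm: float = 2.0
    matrix_flag_ppm: float = 3.0
    # annotation
    policy: RankingPolicy = field(default_factory=RankingPolicy)
    lipid_table_path: Optional[str] = None
    # imaging
    image_ppm_window: float = 3.0
    # analyst-drawn cloud rectangles: name -> (mz_min, mz_max, kmd_min, kmd_max)
    clouds: Dict[str, Tuple[float, float, float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["policy"]["class_priority"] = list(d["policy"]["class_priority"])
        d["kendrick"]["base_composition"] = dict(d["kendrick"]["base_composition"])
        d["clouds"] = {k: list(v) for k, v in d["clouds"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "picking" in d:
            d["picking"] = PickingParams(**d["picking"])
        if "kendrick" in d:
            d["kendrick"] = KendrickParams(**d["kendrick"])
        if "window" in d:
            d["window"] = KMDWindow(**d["window"])
        if "policy" in d:
            pol = dict(d["policy"])
            if "class_priority" in pol:
                pol["class_priority"] = tuple(pol["class_priority"])
            d["policy"] = RankingPolicy(**pol)
        if "clouds" in d:
            d["clouds"] = {k: tuple(v) for k, v in d["clouds"].items()}
        return cls(**d)


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str) -> str:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path


def config_hash(config: PipelineConfig) -> str:
    """Stable content hash of the effective configuration."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
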