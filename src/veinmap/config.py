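"""Pipeline configuration: defaults, YAML round-trip, CLI overrides.

The file format is a plain YAML mapping with one section per stage
(``illumination``, ``inpaint``, ``hair``, ``enhance``, ``ssim``,
``phantom``) plus ``log_level``.  Structuring elements are written as
``"cross3"``, ``"square3"`` or an explicit 0/1 matrix.  Precedence is
CLI flag > config file > built-in default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .enhancement import EnhanceParams
from .evaluation import SSIMParams
from .hair_removal import HairParams
from .illumination import IlluminationParams
from .inpainting import InpaintParams
from .morphology import StructuringElement, cross3, square3
from .phantom import PhantomSpec

__all__ = ["PipelineConfig", "se_to_config", "load_config"]


def se_to_config(se: StructuringElement):
    """Inverse of ``StructuringElement.from_config`` for the named shapes."""
    if se.values is None and se.anchor == (se.kernel.shape[0] // 2, se.kernel.shape[1] // 2):
        if np.array_equal(se.kernel, cross3().kernel):
            return "cross3"
        if np.array_equal(se.kernel, square3().kernel):
            return "square3"
    return se.kernel.astype(int).tolist()


@dataclass(frozen=True)
class PipelineConfig:
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    ssim: SSIMParams = field(default_factory=SSIMParams)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    log_level: str = "INFO"

    @property
    def illumination(self) -> IlluminationParams:
        return self.enhance.illumination

    @property
    def hair(self) -> HairParams:
        return self.enhance.hair

    @property
    def inpaint(self) -> InpaintParams:
        return self.enhance.hair.inpaint

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        e, h = self.enhance, self.enhance.hair
        return {
            "illumination": {"blur_size": e.illumination.blur_size},
            "inpaint": {"radius": h.inpaint.radius, "weight_mode": h.inpaint.weight_mode},
            "hair": {
                "se": se_to_config(h.se),
                "mask_growth_iters": h.mask_growth_iters,
                "open_first": h.open_first,
                "otsu_exclude_zero": h.otsu_exclude_zero,
            },
            "enhance": {
                "norm_range": list(e.norm_range),
                "dilate_se": se_to_config(e.dilate_se),
                "dilate_iters": e.dilate_iters,
                "dilate_polarity": e.dilate_polarity,
                "sharpen_amount": e.sharpen_amount,
                "median_size": e.median_size,
            },
            "ssim": dataclasses.asdict(self.ssim),
            "phantom": {**dataclasses.asdict(self.phantom), "size": list(self.phantom.size)},
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict | None) -> "PipelineConfig":
        data = dict(data or {})
        illum = IlluminationParams(**data.get("illumination", {}))
        inpaint = InpaintParams(**data.get("inpaint", {}))
        hair_cfg = dict(data.get("hair", {}))
        if "se" in hair_cfg:
            hair_cfg["se"] = StructuringElement.from_config(hair_cfg["se"])
        hair = HairParams(inpaint=inpaint, **hair_cfg)
        enh_cfg = dict(data.get("enhance", {}))
        if "dilate_se" in enh_cfg:
            enh_cfg["dilate_se"] = StructuringElement.from_config(enh_cfg["dilate_se"])
        if "norm_range" in enh_cfg:
            enh_cfg["norm_range"] = tuple(enh_cfg["norm_range"])
        enhance = EnhanceParams(illumination=illum, hair=hair, **enh_cfg)
        phantom_cfg = dict(data.get("phantom", {}))
        phantom_cfg.pop("px_per_cm", None)
        if "size" in phantom_cfg:
            phantom_cfg["size"] = tuple(phantom_cfg["size"])
        return cls(
            enhance=enhance,
            ssim=SSIMParams(**data.get("ssim", {})),
            phantom=PhantomSpec(**phantom_cfg),
            log_level=data.get("log_level", "INFO"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def load_config(path: str | os.PathLike | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` gives the built-in defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))
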