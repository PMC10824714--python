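"""Run configuration: one JSON document per pipeline run, strictly validated.

Unknown keys are rejected (typos must fail loudly, not silently fall
back to defaults), and every stochastic stage receives an explicit
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError
from .morphometry import SegmentationParams
from .polarimetry import MosaicLayout
from .scene import OpticalConfig
from .tracking import TrackParams

__all__ = ["RunConfig"]


def _take(d: dict, allowed: dict, section: str) -> dict:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    out = dict(allowed)
    out.update(d)
    return out


@dataclass
class RunConfig:
    optical: OpticalConfig = field(default_factory=OpticalConfig)
    layout: MosaicLayout = field(default_factory=MosaicLayout)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackParams = field(default_factory=TrackParams)
    erode_px: int = 2
    model_path: str | None = None
    output_dir: str = "holopol_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        top_allowed = {
            "optical": {},
            "layout": "90-45-135-0",
            "segmentation": {},
            "tracking": {},
            "classification": {},
            "output_dir": "holopol_out",
            "seed": 0,
            "log_level": "INFO",
        }
        d = _take(d, top_allowed, "run")
        if "seed" not in top_allowed or d.get("seed") is None:
            raise ConfigError("an explicit integer seed is required")

        opt = _take(
            d["optical"],
            {
                "wavelength": 632.8e-9,
                "physical_pixel_pitch": 3.45e-6,
                "mosaic_shape": [2056, 2464],
                "propagation_distance": 5e-3,
                "magnification": 1.0,
            },
            "optical",
        )
        opt["mosaic_shape"] = tuple(opt["mosaic_shape"])
        seg = _take(
            d["segmentation"],
            {
                "source": "SSD",
                "threshold_method": "otsu",
                "threshold_value": None,
                "polarity": "auto",
                "min_area": 20,
                "closing_radius": 1,
                "smoothing_sigma": 0.0,
            },
            "segmentation",
        )
        trk = _take(
            d["tracking"], {"gate_px": 30.0, "m_confirm": 3, "k_miss": 5}, "tracking"
        )
        cls_blk = _take(
            d["classification"], {"model_path": None, "erode_px": 2}, "classification"
        )
        try:
            return cls(
                optical=OpticalConfig(**opt),
                layout=MosaicLayout.from_code(d["layout"]),
                segmentation=SegmentationParams(**seg),
                tracking=TrackParams(**trk),
                erode_px=int(cls_blk["erode_px"]),
                model_path=cls_blk["model_path"],
                output_dir=str(d["output_dir"]),
                seed=int(d["seed"]),
                log_level=str(d["log_level"]),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_json_file(cls, path) -> "RunConfig":
        from .io import read_json

        return cls.from_dict(read_json(path))
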