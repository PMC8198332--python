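"""Pipeline configuration.

All image-dependent constants live here: the manual per-batch thresholds
(one value per channel, applied to every image of an acquisition batch),
the physical pixel size, and the object-identification constants.  The
segmentation constants default to the published pipeline settings
(lumen diameter 25-800 px, roundness cutoff 0.3, 30-px expansion); the
thresholds default to values calibrated on the synthetic phantoms, since
the original manual batch values were never published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["Thresholds", "PipelineConfig"]


@dataclass
class Thresholds:
    """Manual batch thresholds, in the channels' intensity units."""

    marker: float = 0.75
    cytoplasm: float = 0.35
    nuclei: float = 0.40
    all_tissue: float = 0.12


@dataclass
class PipelineConfig:
    pixel_size_um: float = 0.62
    channel_order: tuple[str, str, str] = ("marker", "cytoplasm", "nuclei")
    thresholds: Thresholds = field(default_factory=Thresholds)
    #: typical lumen diameter range in px (published: 25-800)
    lumen_diameter_range: tuple[float, float] = (25.0, 800.0)
    #: roundness cutoff for the lumen filter (published: 0.3)
    min_form_factor: float = 0.3
    #: maximum outward expansion of a lumen seed in px (published: 30)
    max_expansion_px: float = 30.0
    nuclei_diameter_range: tuple[float, float] = (4.0, 20.0)
    #: standardized upper limit of the lumen-area heat map, µm²
    heatmap_vmax_um2: float = 12000.0
    #: use Otsu instead of the manual thresholds (off by default)
    auto_threshold: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        if "channel_order" in raw:
            raw["channel_order"] = tuple(raw["channel_order"])
        for key in ("lumen_diameter_range", "nuclei_diameter_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(thresholds=thr, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["channel_order"] = list(self.channel_order)
        data["lumen_diameter_range"] = list(self.lumen_diameter_range)
        data["nuclei_diameter_range"] = list(self.nuclei_diameter_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
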