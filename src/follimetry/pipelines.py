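"""End-to-end pipeline drivers.

``run_intensity`` is the compartmentalization pipeline (P1),
``run_morphometry`` the segmentation/morphometry pipeline (P2), and
``run_heatmap`` the lumen-area heat map with intraluminal dead-cell
enumeration (P3).  Each is a thin composition of the module-level
operations, wired with a :class:`follimetry.config.PipelineConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import (ChannelStack, apply_threshold, auto_threshold,
                       build_boundary_image, close_and_skeletonize, invert_mask)
from .config import PipelineConfig
from .intensity import CompartmentIntensity, compartmentalize
from .morphometrics import (FollicleRecord, SectionSummary, follicle_metrics,
                            lumen_heatmap, records_to_frame, section_summary)
from .segmentation import (LabelMap, filter_by_form_factor,
                           identify_primary_objects, mask_intraluminal_nuclei,
                           measure_shape, propagate_follicles, relate_objects,
                           derive_epithelium)

__all__ = ["SegmentationResult", "run_intensity", "run_morphometry", "run_heatmap"]


@dataclass
class SegmentationResult:
    lumina: LabelMap
    follicles: LabelMap
    epithelia: LabelMap
    nuclei: LabelMap
    relations: pd.DataFrame       # nucleus -> follicle
    dead_relations: pd.DataFrame  # intraluminal nucleus -> lumen
    records: list[FollicleRecord]
    summary: SectionSummary

    @property
    def records_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def _threshold(cfg: PipelineConfig, channel: np.ndarray, manual: float,
               source: str):
    value = auto_threshold(channel) if cfg.auto_threshold else manual
    return apply_threshold(channel, value, source=source)


def _identify_nuclei(stack: ChannelStack, cfg: PipelineConfig) -> LabelMap:
    mask = _threshold(cfg, stack.nuclei, cfg.thresholds.nuclei, "nuclei")
    lo, hi = cfg.nuclei_diameter_range
    return identify_primary_objects(mask, lo, hi, kind="nuclei")


def run_intensity(stack: ChannelStack, cfg: PipelineConfig) -> CompartmentIntensity:
    """P1: total vs. epithelium-restricted marker signal, per-cell normalized."""
    epi_mask = _threshold(cfg, stack.cytoplasm, cfg.thresholds.cytoplasm, "cytoplasm")
    nuclei = _identify_nuclei(stack, cfg)
    return compartmentalize(stack.marker, epi_mask, nuclei.n_objects)


def run_morphometry(stack: ChannelStack, cfg: PipelineConfig) -> SegmentationResult:
    """P2: segment lumina, follicles, epithelia and nuclei; measure everything."""
    all_tissue = _threshold(cfg, stack.gray(), cfg.thresholds.all_tissue, "all_tissue")
    green_bin = _threshold(cfg, stack.marker, cfg.thresholds.marker, "marker")
    skeleton = close_and_skeletonize(green_bin)

    lo, hi = cfg.lumen_diameter_range
    candidates = identify_primary_objects(invert_mask(all_tissue), lo, hi,
                                          kind="lumen")
    shapes = measure_shape(candidates, stack.pixel_size)
    lumina = filter_by_form_factor(candidates, shapes, cfg.min_form_factor)

    boundary = build_boundary_image(all_tissue, skeleton)
    follicles = propagate_follicles(lumina, boundary, cfg.max_expansion_px)
    epithelia = derive_epithelium(follicles, lumina)

    nuclei = _identify_nuclei(stack, cfg)
    relations = relate_objects(nuclei, follicles)
    dead_relations = mask_intraluminal_nuclei(nuclei, lumina)

    records = follicle_metrics(follicles, lumina, epithelia, relations,
                               dead_relations, stack.pixel_size)
    summary = section_summary(records, total_nuclei=nuclei.n_objects)
    return SegmentationResult(lumina, follicles, epithelia, nuclei, relations,
                              dead_relations, records, summary)


def run_heatmap(result: SegmentationResult, cfg: PipelineConfig) -> np.ndarray:
    """P3: standardized lumen-area heat map from a segmentation result."""
    return lumen_heatmap(result.lumina, result.records, cfg.heatmap_vmax_um2)
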