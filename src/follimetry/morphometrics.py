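"""Per-follicle morphometry, section summaries, and the lumen-area heat map.

Per follicle, the quantities of interest are the lumen, follicle and
epithelium areas; the *epithelial extension* EExt, a proxy for
epithelial height; the thyrocyte count; the mean thyrocyte area
(epithelium area divided by cell count); and the number of intraluminal
dead-cell remnants.  EExt is computed as the difference of
equivalent-disc radii,

    EExt = sqrt(A_follicle / pi) - sqrt(A_lumen / pi),

which equals the epithelial height exactly for concentric circular
follicles; see docs/methods.md for the rationale behind this definition.
Section-level summaries report unweighted follicle means, the cell
density per 1000 µm² of follicle area, and the dead-cell percentage of
all nuclei in the section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps

from .segmentation import LabelMap

__all__ = [
    "FollicleRecord",
    "SectionSummary",
    "epithelial_extension",
    "follicle_metrics",
    "records_to_frame",
    "section_summary",
    "lumen_heatmap",
]


@dataclass
class FollicleRecord:
    follicle_id: int
    lumen_area_um2: float
    follicle_area_um2: float
    epithelium_area_um2: float
    eext_um: float
    n_cells: int
    thyrocyte_area_um2: float  # NaN when n_cells == 0
    n_dead_cells: int


@dataclass
class SectionSummary:
    n_follicles: int
    mean_lumen_area_um2: float
    mean_follicle_area_um2: float
    mean_thyrocyte_area_um2: float
    mean_eext_um: float
    cells_per_1000um2: float
    dead_cell_pct: float


def epithelial_extension(follicle_area: float, lumen_area: float) -> float:
    """EExt in the units of sqrt(area): equivalent-disc radius difference."""
    return float(np.sqrt(follicle_area / np.pi) - np.sqrt(lumen_area / np.pi))


def follicle_metrics(
    follicles: LabelMap,
    lumina: LabelMap,
    epithelia: LabelMap,
    relations: pd.DataFrame,
    dead_relations: pd.DataFrame,
    pixel_size: float,
) -> list[FollicleRecord]:
    """Assemble one record per follicle from the label maps and relations.

    ``relations`` maps nuclei to follicles, ``dead_relations`` maps
    intraluminal nuclei to lumina (labels correspond across maps).  Areas
    are converted to µm² with ``pixel_size**2``.
    """
    px2 = pixel_size**2
    fol_counts = np.bincount(follicles.data.ravel())
    lum_counts = np.bincount(lumina.data.ravel(), minlength=fol_counts.size)
    epi_counts = np.bincount(epithelia.data.ravel(), minlength=fol_counts.size)
    cells = relations[relations["parent"] > 0]["parent"].value_counts()
    dead = dead_relations[dead_relations["parent"] > 0]["parent"].value_counts()
    records = []
    for k in follicles.labels():
        k = int(k)
        a_fol = fol_counts[k] * px2
        a_lum = (lum_counts[k] if k < lum_counts.size else 0) * px2
        a_epi = (epi_counts[k] if k < epi_counts.size else 0) * px2
        if not np.isclose(a_fol, a_lum + a_epi):
            raise ValueError(f"inconsistent label maps for follicle {k}")
        n_cells = int(cells.get(k, 0))
        n_dead = int(dead.get(k, 0))
        records.append(
            FollicleRecord(
                follicle_id=k,
                lumen_area_um2=a_lum,
                follicle_area_um2=a_fol,
                epithelium_area_um2=a_epi,
                eext_um=epithelial_extension(a_fol, a_lum),
                n_cells=n_cells,
                thyrocyte_area_um2=(a_epi / n_cells) if n_cells > 0 else float("nan"),
                n_dead_cells=n_dead,
            )
        )
    return records


def records_to_frame(records: list[FollicleRecord]) -> pd.DataFrame:
    cols = ["follicle_id", "lumen_area_um2", "follicle_area_um2",
            "epithelium_area_um2", "eext_um", "n_cells", "thyrocyte_area_um2",
            "n_dead_cells"]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records],
                        columns=cols)


def section_summary(records: list[FollicleRecord], total_nuclei: int) -> SectionSummary:
    """Pool follicle records into a per-section summary.

    ``cells_per_1000um2`` is 1000 * (sum of cells) / (sum of follicle
    area); ``dead_cell_pct`` normalizes the intraluminal count to
    ``total_nuclei``, the nucleus count of the whole section.  Means are
    unweighted over follicles.
    """
    n = len(records)
    total_dead = sum(r.n_dead_cells for r in records)
    if total_nuclei < total_dead:
        raise ValueError("total_nuclei cannot be below the summed dead-cell count")
    if n == 0:
        nan = float("nan")
        return SectionSummary(0, nan, nan, nan, nan, nan,
                              0.0 if total_nuclei else nan)
    sum_area = sum(r.follicle_area_um2 for r in records)
    thyro = [r.thyrocyte_area_um2 for r in records if r.n_cells > 0]
    return SectionSummary(
        n_follicles=n,
        mean_lumen_area_um2=float(np.mean([r.lumen_area_um2 for r in records])),
        mean_follicle_area_um2=float(np.mean([r.follicle_area_um2 for r in records])),
        mean_thyrocyte_area_um2=float(np.mean(thyro)) if thyro else float("nan"),
        mean_eext_um=float(np.mean([r.eext_um for r in records])),
        cells_per_1000um2=1000.0 * sum(r.n_cells for r in records) / sum_area,
        dead_cell_pct=100.0 * total_dead / total_nuclei if total_nuclei else float("nan"),
    )


def lumen_heatmap(
    lumina: LabelMap,
    records: list[FollicleRecord] | pd.DataFrame,
    vmax_area: float,
    cmap: str = "viridis",
) -> np.ndarray:
    """Paint each lumen by its area on a standardized linear color scale.

    The colormap position of a lumen is ``min(area / vmax_area, 1)``; the
    fixed upper limit ``vmax_area`` (µm²) standardizes color coding across
    sections and genotypes.  Background is black.  Returns an (H, W, 3)
    uint8 RGB raster; a pure function of the inputs.
    """
    if not vmax_area > 0:
        raise ValueError("vmax_area must be positive")
    if isinstance(records, pd.DataFrame):
        areas = dict(zip(records["follicle_id"].astype(int),
                         records["lumen_area_um2"]))
    else:
        areas = {r.follicle_id: r.lumen_area_um2 for r in records}
    cm = colormaps[cmap]
    out = np.zeros(lumina.shape + (3,), dtype=np.uint8)
    for k in lumina.labels():
        k = int(k)
        if k not in areas:
            continue
        pos = min(areas[k] / vmax_area, 1.0)
        rgb = (np.asarray(cm(pos)[:3]) * 255).astype(np.uint8)
        out[lumina.data == k] = rgb
    return out
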