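"""Channel handling and pixel-level preprocessing shared by the pipelines.

A stained thyroid cryosection is acquired as a three-channel micrograph:
a *marker* channel (green role: cathepsin immunostain or a basal-lamina
stain such as laminin/collagen IV), a *cytoplasm* channel (red role:
whole-cytoplasm stain, CellMask-type) and a *nuclei* channel (blue role:
DNA stain, Draq5-type).  This module splits such images into channels,
binarizes them with batch-wide manual thresholds, and builds the derived
binary images the segmentation stage consumes: the skeletonized
basal-lamina network and the tissue "boundary image" in which lamina
pixels act as barriers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, skeletonize

__all__ = [
    "ChannelStack",
    "BinaryMask",
    "split_channels",
    "apply_threshold",
    "auto_threshold",
    "close_and_skeletonize",
    "invert_mask",
    "build_boundary_image",
]


@dataclass
class ChannelStack:
    """A registered triple of 2-D rasters with a physical pixel size.

    Parameters
    ----------
    marker, cytoplasm, nuclei
        2-D float arrays of identical shape; non-negative finite intensities.
    pixel_size
        Edge length of one pixel in micrometres (µm/px); pixel area is
        ``pixel_size**2`` µm².
    """

    marker: np.ndarray
    cytoplasm: np.ndarray
    nuclei: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.marker = np.asarray(self.marker, dtype=float)
        self.cytoplasm = np.asarray(self.cytoplasm, dtype=float)
        self.nuclei = np.asarray(self.nuclei, dtype=float)
        shapes = {self.marker.shape, self.cytoplasm.shape, self.nuclei.shape}
        if len(shapes) != 1 or self.marker.ndim != 2:
            raise ValueError(f"channels must be 2-D and share one shape, got {shapes}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        for name in ("marker", "cytoplasm", "nuclei"):
            ch = getattr(self, name)
            if not np.all(np.isfinite(ch)) or ch.min() < 0:
                raise ValueError(f"{name} channel must be non-negative and finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.marker.shape

    def gray(self) -> np.ndarray:
        """Unweighted mean of the three channels (the merged 'OrigGray')."""
        return (self.marker + self.cytoplasm + self.nuclei) / 3.0


@dataclass
class BinaryMask:
    """A boolean raster with provenance (source channel and threshold)."""

    data: np.ndarray
    source: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def split_channels(
    image: np.ndarray,
    pixel_size: float,
    channel_order: tuple[str, str, str] = ("marker", "cytoplasm", "nuclei"),
) -> ChannelStack:
    """Split a 3-channel raster into a :class:`ChannelStack`.

    ``image`` may be channel-last ``(H, W, 3)`` or channel-first ``(3, H, W)``.
    ``channel_order`` names the role of each channel index; the conventional
    RGB micrograph maps green->marker, red->cytoplasm, blue->nuclei, i.e.
    ``("cytoplasm", "marker", "nuclei")`` for an RGB-ordered array.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected a 3-channel raster, got {image.ndim}-D array")
    if image.shape[-1] == 3 and image.shape[0] != 3:
        planes = np.moveaxis(image, -1, 0)
    elif image.shape[0] == 3:
        planes = image
    else:
        n = image.shape[-1] if image.shape[-1] < image.shape[0] else image.shape[0]
        raise ValueError(f"expected exactly 3 channels, found {n}")
    if sorted(channel_order) != ["cytoplasm", "marker", "nuclei"]:
        raise ValueError(f"channel_order must name marker/cytoplasm/nuclei, got {channel_order}")
    roles = {role: planes[i].astype(float) for i, role in enumerate(channel_order)}
    return ChannelStack(
        marker=roles["marker"],
        cytoplasm=roles["cytoplasm"],
        nuclei=roles["nuclei"],
        pixel_size=pixel_size,
    )


def apply_threshold(channel: np.ndarray, threshold: float, source: str = "") -> BinaryMask:
    """Binarize a channel: pixel true iff intensity >= ``threshold``.

    The comparison is inclusive so that saturated pixels are kept.  One
    threshold per channel is meant to be applied to every image of an
    acquisition batch; the value is recorded in the mask's provenance.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    channel = np.asarray(channel, dtype=float)
    return BinaryMask(channel >= threshold, source=source, threshold=float(threshold))


def auto_threshold(channel: np.ndarray) -> float:
    """Otsu fallback for when no manual batch threshold is configured."""
    return float(threshold_otsu(np.asarray(channel, dtype=float)))


def close_and_skeletonize(mask: BinaryMask, gap_size: int = 2) -> BinaryMask:
    """Morphologically close small gaps, then skeletonize to 1-px width.

    Applied to the thresholded basal-lamina (marker) channel this turns the
    stained lamina network into closed 1-px curves: a ring interrupted by a
    small staining gap (up to ~``gap_size`` px) becomes a single closed
    curve, which is what makes it usable as a propagation barrier.
    """
    closed = closing(mask.data, disk(gap_size))
    skel = skeletonize(closed)
    return BinaryMask(skel, source=f"skeleton({mask.source})", threshold=mask.threshold)


def invert_mask(mask: BinaryMask) -> BinaryMask:
    """Logical complement (e.g. AllTissue -> candidate lumen pixels)."""
    return BinaryMask(~mask.data, source=f"not({mask.source})", threshold=mask.threshold)


def build_boundary_image(all_tissue: BinaryMask, skeleton: BinaryMask) -> BinaryMask:
    """Subtract the lamina skeleton from the tissue mask.

    The result is the raster through which follicles may grow: true tissue
    pixels minus the skeleton, whose pixels act as barriers for the seeded
    propagation of :func:`follimetry.segmentation.propagate_follicles`.
    """
    if all_tissue.shape != skeleton.shape:
        raise ValueError(
            f"shape mismatch: all_tissue {all_tissue.shape} vs skeleton {skeleton.shape}"
        )
    return BinaryMask(all_tissue.data & ~skeleton.data, source="boundary")
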