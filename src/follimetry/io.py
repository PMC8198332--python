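"""Reading and writing rasters: multi-channel TIFF, PNG triplets, masks, labels."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .channels import BinaryMask, ChannelStack, split_channels

__all__ = [
    "read_stack",
    "read_stack_pngs",
    "write_stack",
    "write_mask",
    "write_labels",
    "read_labels",
]


def read_stack(
    path: str | Path,
    pixel_size: float,
    channel_order: tuple[str, str, str] = ("marker", "cytoplasm", "nuclei"),
) -> ChannelStack:
    """Read a 3-channel TIFF (channel-first or channel-last) into a stack."""
    arr = tifffile.imread(str(path))
    return split_channels(arr, pixel_size, channel_order)


def read_stack_pngs(
    marker: str | Path, cytoplasm: str | Path, nuclei: str | Path, pixel_size: float
) -> ChannelStack:
    """Read one grayscale PNG per channel; 8/16-bit data is scaled to [0, 1]."""

    def _read(p: str | Path) -> np.ndarray:
        a = iio.imread(str(p))
        if a.ndim == 3:  # grayscale saved as RGB
            a = a[..., 0]
        if np.issubdtype(a.dtype, np.integer):
            a = a / float(np.iinfo(a.dtype).max)
        return a.astype(float)

    return ChannelStack(_read(marker), _read(cytoplasm), _read(nuclei), pixel_size)


def write_stack(path: str | Path, stack: ChannelStack) -> None:
    """Write a stack as a float32 multi-channel TIFF (marker, cytoplasm, nuclei)."""
    arr = np.stack([stack.marker, stack.cytoplasm, stack.nuclei]).astype(np.float32)
    tifffile.imwrite(str(path), arr, photometric="minisblack",
                     metadata={"axes": "CYX"})


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a binary mask as single-channel 8-bit TIFF (0/255)."""
    tifffile.imwrite(str(path), (mask.data.astype(np.uint8) * 255))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write an integer label raster as 16-bit single-channel TIFF."""
    arr = np.asarray(labels)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)
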