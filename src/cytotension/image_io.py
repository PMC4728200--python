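"""Loading, normalization and mask extraction for the three fluorescence channels.

Coordinate convention, used everywhere in the package: images are indexed
``intensities[row, col]`` with the origin at the top-left corner and rows
increasing downward.  The physical position of the centre of pixel
``(row, col)`` is ``x = (col + 0.5) * pixel_pitch`` and
``y = (row + 0.5) * pixel_pitch``, both in micrometres.

Gray values are normalized to ``[0, 1]``: 0 is a dark area with no signal,
1 the brightest area (highest local actin density on the actin channel).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.morphology import disk

_RGB_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclasses.dataclass(frozen=True)
class ChannelImage:
    """A single normalized fluorescence channel.

    Parameters
    ----------
    intensities:
        2-D float array of gray values in ``[0, 1]``.
    pixel_pitch:
        Physical size of one pixel in micrometres.
    """

    intensities: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        ints = np.asarray(self.intensities, dtype=float)
        if ints.ndim != 2 or ints.size == 0:
            raise ValueError("intensities must be a non-empty 2-D array")
        if not np.isfinite(ints).all():
            raise ValueError("intensities contain non-finite values")
        if ints.min() < 0.0 or ints.max() > 1.0 + 1e-12:
            raise ValueError("intensities must lie in [0, 1]")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "intensities", ints)

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]


@dataclasses.dataclass(frozen=True)
class CellImageSet:
    """The registered channel set of one cell: normalized actin plus binary masks."""

    actin: ChannelImage
    vinculin_mask: np.ndarray
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        shape = self.actin.intensities.shape
        for name in ("vinculin_mask", "nucleus_mask", "cell_mask"):
            mask = np.asarray(getattr(self, name), dtype=bool)
            if mask.shape != shape:
                raise ValueError(f"{name} shape {mask.shape} does not match actin {shape}")
            object.__setattr__(self, name, mask)
        if np.any(self.nucleus_mask & ~self.cell_mask):
            raise ValueError("nucleus_mask must be contained in cell_mask")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")


def load_channel(path: str | Path, pixel_pitch: float, channel: str | int | None = None) -> ChannelImage:
    """Load one grayscale TIFF channel and scale it to ``[0, 1]``.

    Integer images are divided by the maximum of their bit depth (255 for
    8-bit, 65535 for 16-bit).  For an RGB TIFF, ``channel`` selects the
    color plane (``"R"``/``"G"``/``"B"`` or an index).
    """
    if not pixel_pitch > 0:
        raise ValueError("pixel_pitch must be positive")
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(f"{path}: multi-channel image requires an explicit channel selector")
        idx = _RGB_INDEX[channel.upper()] if isinstance(channel, str) else int(channel)
        if arr.shape[-1] in (3, 4):
            arr = arr[..., idx]
        elif arr.shape[0] in (3, 4):
            arr = arr[idx]
        else:
            raise ValueError(f"{path}: cannot identify color axis of shape {arr.shape}")
    elif arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")

    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        ints = arr.astype(float) / scale
    elif arr.dtype == bool:
        ints = arr.astype(float)
    else:
        ints = arr.astype(float)
        if ints.size and (ints.min() < 0 or ints.max() > 1):
            raise ValueError(f"{path}: float image must already be scaled to [0, 1]")
    return ChannelImage(ints, pixel_pitch)


def normalize_actin(image: ChannelImage, background_percentile: float = 0.01) -> ChannelImage:
    """Normalize the actin channel so background maps to 0 and the peak to 1.

    The background level is estimated as the given percentile (a fraction in
    ``[0, 1)``) of all intensities, subtracted, negatives clipped to zero,
    and the result rescaled to a maximum of exactly 1.  After normalization
    a gray value of 0 means "no actin".
    """
    ints = image.intensities
    if ints.max() == ints.min():
        raise ValueError("constant image: actin normalization undefined")
    if not 0.0 <= background_percentile < 1.0:
        raise ValueError("background_percentile must be a fraction in [0, 1)")
    # "lower" interpolation makes the operation exactly idempotent: after one
    # pass at least this fraction of pixels is 0, so the next background is 0
    background = float(np.quantile(ints, background_percentile, method="lower"))
    shifted = np.clip(ints - background, 0.0, None)
    peak = shifted.max()
    if peak <= 0:
        raise ValueError("background subtraction removed all signal")
    return ChannelImage(shifted / peak, image.pixel_pitch)


def binarize(image: ChannelImage, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Binarize a channel: pixels strictly above the threshold are True.

    ``method`` is ``"otsu"`` (threshold from Otsu's criterion) or
    ``"fixed"`` (explicit ``threshold``).
    """
    ints = image.intensities
    if method == "otsu":
        if ints.max() == ints.min():
            raise ValueError("constant image: Otsu threshold undefined")
        thr = float(threshold_otsu(ints))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return ints > thr


def cell_footprint(actin: ChannelImage, closing_radius_px: int = 2) -> np.ndarray:
    """Binary footprint of the cell body from the normalized actin channel.

    Pixels with ``c > 0`` are morphologically closed (disk radius of one
    node spacing, i.e. 2 px at the default 2x2 binning), hole-filled, and
    the largest connected component is retained.
    """
    mask = actin.intensities > 0
    if not mask.any():
        raise ValueError("empty cell footprint: no actin signal above background")
    mask = ndi.binary_closing(mask, structure=disk(closing_radius_px))
    mask = ndi.binary_fill_holes(mask)
    labels = _cc_label(mask, connectivity=2)
    if labels.max() == 0:
        raise ValueError("empty cell footprint after morphology")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(sizes.argmax())


def build_image_set(
    actin: ChannelImage,
    vinculin: ChannelImage,
    nucleus: ChannelImage,
    background_percentile: float = 0.01,
) -> CellImageSet:
    """Assemble a :class:`CellImageSet` from three raw channels.

    Actin is normalized; vinculin and nucleus are Otsu-binarized; the cell
    mask is the actin footprint united with the nucleus and vinculin masks
    (so anchor and nucleus pixels always belong to the cell).
    """
    norm = normalize_actin(actin, background_percentile)
    vmask = binarize(vinculin, "otsu")
    nmask = binarize(nucleus, "otsu")
    cmask = cell_footprint(norm) | nmask | vmask
    return CellImageSet(norm, vmask, nmask, cmask, norm.pixel_pitch)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit TIFF with values {0, 255}."""
    tifffile.imwrite(str(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_channel(path: str | Path, image: ChannelImage) -> None:
    """Write a normalized channel as a 16-bit grayscale TIFF."""
    data = np.round(image.intensities * 65535.0).astype(np.uint16)
    tifffile.imwrite(str(path), data)
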