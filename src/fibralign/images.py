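"""Loading and preparation of 2D grayscale micrographs.

Images enter the directionality pipeline as :class:`GrayImage`: a 2D grid of
non-negative intensities in ``[0, 1]``, obtained from an 8/16-bit TIFF or PNG
by linear rescaling of the native bit depth and, for RGB inputs, a standard
luminance conversion.  All analyses operate on a centred square crop so every
image in a series shares the same spectral geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.color import rgb2gray

from .errors import ImageInputError, ImageSizeError

# Minimum side so that four 64x64 corner blocks fit around a distinct centre.
MIN_SIDE_PX = 129

DEFAULT_CROP_PX = 825


@dataclass(frozen=True)
class GrayImage:
    """A 2D non-negative intensity grid, the unit of analysis.

    Attributes
    ----------
    pixels : ndarray
        2D float array, finite and ``>= 0`` everywhere (normally in [0, 1]).
    source_id : str
        Free-text label, usually the originating file name.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ImageInputError(f"expected a 2D image, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ImageInputError("image contains non-finite pixel values")
        if np.any(px < 0):
            raise ImageInputError("image contains negative intensities")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def _to_unit_gray(arr: np.ndarray) -> np.ndarray:
    """Convert a decoded image array to float grayscale in [0, 1].

    Integer dtypes are rescaled linearly by their full range so the result
    does not depend on the particular exposure; float inputs are assumed to
    already be on a linear intensity scale and are rescaled only if they
    exceed 1. RGB(A) inputs are reduced with the Rec. 601 luminance weights.
    """
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ImageInputError(f"cannot interpret image of shape {arr.shape}")
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / float(np.iinfo(arr.dtype).max)
        arr = rgb2gray(arr)
    elif arr.ndim == 2:
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / float(np.iinfo(arr.dtype).max)
        else:
            arr = arr.astype(float)
    else:
        raise ImageInputError(f"cannot interpret image of shape {arr.shape}")
    arr = np.asarray(arr, dtype=float)
    if arr.size and arr.max() > 1.0:
        arr = arr / arr.max()
    return np.clip(arr, 0.0, None)


def central_crop(pixels: np.ndarray, crop_px: int) -> np.ndarray:
    """Return the centred ``crop_px`` x ``crop_px`` window of a 2D array."""
    h, w = pixels.shape
    if h < crop_px or w < crop_px:
        raise ImageSizeError(
            f"image is {h}x{w} px but a {crop_px}x{crop_px} central crop "
            f"was requested"
        )
    r0 = (h - crop_px) // 2
    c0 = (w - crop_px) // 2
    return pixels[r0 : r0 + crop_px, c0 : c0 + crop_px]


def load_and_prepare(path, crop_px: int = DEFAULT_CROP_PX) -> GrayImage:
    """Load an image file and return its centred square crop as a GrayImage.

    Parameters
    ----------
    path : path-like
        An 8/16-bit TIFF or PNG, single-channel or RGB.
    crop_px : int
        Side of the centred square window, default 825 px. Odd values give a
        true central pixel for the zero-frequency term after recentring.

    Raises
    ------
    ImageInputError
        If the file cannot be read or decoded.
    ImageSizeError
        If either image dimension is smaller than ``crop_px``.
    """
    if crop_px < 1:
        raise ImageSizeError(f"crop_px must be positive, got {crop_px}")
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises many backend-specific types
        raise ImageInputError(f"cannot read image file {path}: {exc}") from exc
    gray = _to_unit_gray(raw)
    cropped = central_crop(gray, crop_px)
    return GrayImage(pixels=cropped, source_id=path.name)
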