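"""Background illumination correction.

Wide-field HCS images show smooth non-uniform background fluorescence
(plate-bottom imperfections, non-specific dye binding, lamp gradients).
The correction estimates an additive illumination field from the image's
own background and subtracts it: the image is split into small square
blocks, the per-block minimum (a robust background probe as long as each
block contains some background pixels) is taken, a median filter over the
block grid removes outlier blocks (debris, dust), and the smoothed grid is
interpolated back to full resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import block_reduce
from skimage.transform import resize

from .types import ImagePlane

DEFAULT_BLOCK_SIZE = 8
DEFAULT_MEDIAN_FOOTPRINT = 3  # blocks, per side


@dataclass
class IlluminationField:
    """Estimated additive background, same shape as the source image."""

    background: np.ndarray
    block_size: int
    smoothing_radius: int

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if np.any(self.background < 0):
            raise ValueError("background must be non-negative")


def _block_minima(pixels: np.ndarray, block_size: int) -> np.ndarray:
    """Per-block minimum on a ceil(H/B) x ceil(W/B) grid.

    Edge blocks smaller than B x B use their own minima (no padding).
    """
    # cval=inf keeps padded pixels out of edge-block minima
    return block_reduce(pixels, (block_size, block_size), np.min,
                        cval=np.inf).astype(float)


def estimate_background(image: ImagePlane, block_size: int = DEFAULT_BLOCK_SIZE,
                        median_footprint: int = DEFAULT_MEDIAN_FOOTPRINT,
                        ) -> IlluminationField:
    """Estimate the additive illumination field of one frame.

    Parameters
    ----------
    image : frame to analyse (raw intensities).
    block_size : side of the square blocks whose minima probe the
        background; 8 px suits nuclei an order of magnitude larger than
        the block so every block contains background.
    median_footprint : side (in blocks) of the median filter applied to
        the block-minimum grid; 3 rejects isolated outlier blocks such as
        saturated debris.

    Returns
    -------
    IlluminationField with a bilinearly upsampled, median-smoothed
    block-minimum surface.
    """
    h, w = image.shape
    if block_size < 2 or block_size > min(h, w):
        raise ValueError("block_size must be in [2, min(H, W)]")
    grid = _block_minima(np.asarray(image.pixels, dtype=float), block_size)
    if min(grid.shape) < median_footprint:
        raise ValueError(
            f"block grid {grid.shape} smaller than median footprint "
            f"{median_footprint}"
        )
    smooth = ndimage.median_filter(grid, size=median_footprint, mode="nearest")
    background = resize(smooth, (h, w), order=1, mode="edge",
                        anti_aliasing=False)
    background = np.clip(background, 0.0, None)
    return IlluminationField(background=background, block_size=block_size,
                             smoothing_radius=median_footprint // 2)


def correct_illumination(image: ImagePlane, fld: IlluminationField) -> ImagePlane:
    """Subtract the illumination field, clipping at zero.

    Negative residuals (background pixels slightly below the estimated
    field) are clipped: negative intensities are physically meaningless
    and break downstream thresholding.
    """
    if fld.background.shape != image.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs field "
            f"{fld.background.shape}"
        )
    corrected = np.clip(
        np.asarray(image.pixels, dtype=float) - fld.background, 0.0, None)
    return image.with_pixels(corrected)


def correct_frame(image: ImagePlane, block_size: int = DEFAULT_BLOCK_SIZE,
                  median_footprint: int = DEFAULT_MEDIAN_FOOTPRINT) -> ImagePlane:
    """Convenience: estimate and subtract in one call (one field per image)."""
    return correct_illumination(
        image, estimate_background(image, block_size, median_footprint))
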