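"""Static lumen ROI segmentation from magnitude images.

The workflow mirrors manual ROI determination on a PC-MR magnitude series:
normalise a magnitude image to [0, 1], apply an intensity threshold (0.60
for the phantom), pick the bright connected component containing a seed
pixel, and overlay its perimeter on the original magnitude image as a QC
check.  The ROI is static (time-invariant); by default the temporal-mean
magnitude image is segmented, which coincides with any single frame on
noise-free fixtures and is more robust under noise.

Components and perimeters use 4-connectivity: a perimeter pixel is a true
pixel with at least one false 4-neighbour (image borders count as false).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ConfigurationError, EmptyRoiError, InvalidParameterError

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class RoiMask:
    """A single 4-connected set of in-lumen pixels on the acquisition grid.

    ``area`` = pixel_count x pixel_spacing^2 (cm^2); ``perimeter_pixels``
    are (row, col) coordinates of true pixels adjacent to the exterior.
    """

    mask: np.ndarray
    pixel_spacing: float
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if not self.mask.any():
            raise EmptyRoiError("ROI mask contains no pixels")
        _, n_comp = ndimage.label(self.mask, structure=_FOUR_CONNECTED)
        if n_comp != 1:
            raise ConfigurationError(
                f"ROI mask must be a single 4-connected component, found {n_comp}"
            )
        if not (self.pixel_spacing > 0):
            raise InvalidParameterError("pixel_spacing must be > 0")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def area(self) -> float:
        """ROI area N * pixel_spacing^2 in cm^2."""
        return self.pixel_count * self.pixel_spacing**2

    @property
    def perimeter_mask(self) -> np.ndarray:
        """Boolean image of true pixels with >= 1 false 4-neighbour."""
        interior = ndimage.binary_erosion(
            self.mask, structure=_FOUR_CONNECTED, border_value=0
        )
        return self.mask & ~interior

    @property
    def perimeter_pixels(self) -> list[tuple[int, int]]:
        return [tuple(rc) for rc in np.argwhere(self.perimeter_mask)]


def normalize_magnitude(magnitude: np.ndarray) -> np.ndarray:
    """Min-max normalise an image to [0, 1] so thresholds transfer across scans."""
    magnitude = np.asarray(magnitude, dtype=float)
    lo, hi = magnitude.min(), magnitude.max()
    if hi == lo:
        raise InvalidParameterError("magnitude image is constant; cannot normalise")
    return (magnitude - lo) / (hi - lo)


def threshold_image(magnitude: np.ndarray, threshold: float) -> np.ndarray:
    """Binary image: pixel true iff magnitude > threshold."""
    magnitude = np.asarray(magnitude, dtype=float)
    if not np.all(np.isfinite(magnitude)):
        raise InvalidParameterError("magnitude image contains non-finite values")
    return magnitude > threshold


def select_region(
    binary: np.ndarray,
    seed_pixel: tuple[int, int],
    pixel_spacing: float,
    threshold_used: float = float("nan"),
) -> RoiMask:
    """The 4-connected component of a binary image containing the seed pixel.

    Emulates the manual step of clicking the desired bright region.
    """
    binary = np.asarray(binary, dtype=bool)
    row, col = seed_pixel
    if not (0 <= row < binary.shape[0] and 0 <= col < binary.shape[1]):
        raise InvalidParameterError(
            f"seed pixel {seed_pixel} is outside the {binary.shape} grid"
        )
    if not binary[row, col]:
        raise EmptyRoiError(f"seed pixel {seed_pixel} lies on a background pixel")
    labels, _ = ndimage.label(binary, structure=_FOUR_CONNECTED)
    component = labels == labels[row, col]
    return RoiMask(component, pixel_spacing, threshold_used)


def perimeter_overlay(
    mask: RoiMask, magnitude: np.ndarray, sentinel: float | None = None
) -> np.ndarray:
    """QC image: the magnitude image with ROI perimeter pixels marked.

    The sentinel defaults to max(magnitude) + 1 so the perimeter is
    unambiguous in any display windowing.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.shape != mask.mask.shape:
        raise ConfigurationError(
            f"magnitude shape {magnitude.shape} != mask shape {mask.mask.shape}"
        )
    if sentinel is None:
        sentinel = magnitude.max() + 1.0
    overlay = magnitude.copy()
    overlay[mask.perimeter_mask] = sentinel
    return overlay


def segment_series(
    series,
    threshold: float = 0.60,
    seed_pixel: tuple[int, int] | None = None,
    frame: int | str = "mean",
) -> RoiMask:
    """Threshold-and-select segmentation of a gated velocity series.

    ``frame`` chooses the magnitude image: "mean" (temporal mean, default)
    or an integer frame index (the single best-contrast frame of the manual
    workflow).  ``seed_pixel`` defaults to the brightest pixel of that
    image, which for a lumen-in-background phantom is inside the lumen.
    """
    if frame == "mean":
        mag = series.magnitude.mean(axis=0)
    else:
        mag = series.magnitude[int(frame)]
    mag = normalize_magnitude(mag)
    binary = threshold_image(mag, threshold)
    if seed_pixel is None:
        seed_pixel = tuple(np.unravel_index(np.argmax(mag), mag.shape))
    return select_region(
        binary, seed_pixel, series.acquisition.pixel_spacing, threshold
    )
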