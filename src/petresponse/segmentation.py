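"""Intensity normalization and seeded 2-D region growing.

Lesion delineation follows the 40%-of-maximum convention common in PET
quantification: starting from a seed pixel (by default the global intensity
maximum), the region grows through 4-connected pixels whose intensity is at
least ``threshold_fraction`` times the seed intensity.

Conventions frozen here:

* pixel coordinates are 0-based ``(row, column)``;
* connectivity is 4-neighborhood (edge-adjacent pixels only);
* ties for the ``"auto"`` seed are broken by row-major order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DataError, DegenerateImageWarning

#: 4-connectivity structuring element used for region growing.
FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ScanImage:
    """A 2-D grayscale image with intensities normalized to ``[0, 1]``."""

    pixels: np.ndarray
    modality: str = "PET"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DataError(f"ScanImage requires a 2-D grid, got ndim={self.pixels.ndim}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LesionMask:
    """Boolean grid marking the segmented lesion; same shape as its image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise DataError(f"LesionMask requires a 2-D grid, got ndim={self.pixels.ndim}")

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize(raw_image, modality: str = "PET") -> ScanImage:
    """Min–max rescale a raw non-negative image to the ``[0, 1]`` interval.

    A constant raw image is degenerate: the result is all zeros and a
    :class:`~petresponse.errors.DegenerateImageWarning` is emitted.

    Parameters
    ----------
    raw_image : array_like
        2-D grid of arbitrary finite intensities.
    modality : str
        Modality tag carried along on the result.

    Returns
    -------
    ScanImage
        Image with ``min == 0`` and ``max == 1`` (unless degenerate).
    """
    arr = np.asarray(raw_image, dtype=float)
    if arr.ndim != 2:
        raise DataError(f"expected a 2-D image, got ndim={arr.ndim}")
    if arr.size == 0:
        raise DataError("cannot normalize an empty image")
    if not np.isfinite(arr).all():
        raise DataError("image contains non-finite intensities")
    lo = float(arr.min())
    hi = float(arr.max())
    if hi == lo:
        warnings.warn(
            "constant raw image: normalization is degenerate, returning all zeros",
            DegenerateImageWarning,
            stacklevel=2,
        )
        return ScanImage(np.zeros_like(arr), modality=modality)
    return ScanImage((arr - lo) / (hi - lo), modality=modality)


def _resolve_seed(pixels: np.ndarray, seed) -> tuple[int, int]:
    if isinstance(seed, str):
        if seed != "auto":
            raise ConfigurationError(f"unknown seed specifier {seed!r}")
        # np.argmax returns the first maximum in row-major order.
        return tuple(int(v) for v in np.unravel_index(int(np.argmax(pixels)), pixels.shape))
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < pixels.shape[0] and 0 <= c < pixels.shape[1]):
        raise ConfigurationError(
            f"seed {(r, c)} outside image of shape {pixels.shape}"
        )
    return r, c


def region_grow(image, seed="auto", threshold_fraction: float = 0.40) -> LesionMask:
    """Segment the lesion containing *seed* by thresholded region growing.

    The mask is the set of pixels 4-connected to the seed through pixels
    whose intensity is at least ``threshold_fraction * intensity(seed)``.

    Parameters
    ----------
    image : ScanImage or array_like
        Normalized 2-D image.
    seed : (row, col) tuple or ``"auto"``
        Growth origin; ``"auto"`` uses the global maximum (first in
        row-major order on ties).
    threshold_fraction : float
        Relative threshold in ``(0, 1]``; default 0.40.

    Returns
    -------
    LesionMask
        Non-empty mask that always contains the seed.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ConfigurationError(
            f"threshold_fraction must lie in (0, 1], got {threshold_fraction}"
        )
    pixels = image.pixels if isinstance(image, ScanImage) else np.asarray(image, dtype=float)
    if pixels.ndim != 2 or pixels.size == 0:
        raise DataError("region_grow requires a non-empty 2-D image")
    r, c = _resolve_seed(pixels, seed)
    seed_value = pixels[r, c]
    if seed_value <= 0.0:
        raise DataError(f"seed intensity at {(r, c)} is 0: no lesion at seed")
    above = pixels >= threshold_fraction * seed_value
    labels, _ = ndimage.label(above, structure=FOUR_CONNECTED)
    return LesionMask(labels == labels[r, c])
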