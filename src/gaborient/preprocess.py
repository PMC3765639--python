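"""Image ingestion and pre-filtering for cross-polar histology fields.

The analysis operates on single-channel intensity rasters. Colour inputs
(e.g. RGB photomicrographs of picrosirius-stained sections) are reduced to
luminance, and a 3x3 median filter suppresses photon (shot) noise before any
frequency-domain work. Rectangular ROIs support compartment-level analysis,
e.g. separating the papillary from the reticular dermis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "GrayImage",
    "RectROI",
    "REC601_WEIGHTS",
    "read_image",
    "to_grayscale",
    "median3x3",
    "crop",
]

#: Rec. 601 luminance weights (R, G, B); the default colour -> gray reduction.
REC601_WEIGHTS = (0.299, 0.587, 0.114)

MIN_SIDE = 16


@dataclass(frozen=True)
class GrayImage:
    """A 2-D real-valued intensity image with acquisition metadata.

    Attributes
    ----------
    pixels : ndarray, shape (M, Ncols)
        Intensity values as read (no rescaling). The pipeline's later
        spectral stage subtracts the mean itself, so absolute gain is
        irrelevant to the orientation index.
    bit_depth : int
        Bit depth of the source raster (8 or 16 for file input; 0 marks a
        synthetic float image).
    pixel_size_um : float or None
        Physical pixel pitch in micrometres per pixel, if known.
    source : str or None
        Provenance (file path or generator tag).
    """

    pixels: np.ndarray
    bit_depth: int = 0
    pixel_size_um: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValueError(
                f"image too small: {px.shape}, need at least {MIN_SIDE}x{MIN_SIDE}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixel values")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle, 0-based, half-open: rows [row0, row0+height)."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.height < MIN_SIDE or self.width < MIN_SIDE:
            raise ValueError(f"ROI must be at least {MIN_SIDE}x{MIN_SIDE}")


def read_image(path: str | Path) -> GrayImage:
    """Read a TIFF or PNG raster as a :class:`GrayImage`.

    3-channel inputs are reduced with :func:`to_grayscale`; values are kept
    on their native scale (a 16-bit TIFF keeps its 0..65535 range).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {path.name} (need TIFF or PNG)")
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    bit_depth = 16 if arr.dtype.itemsize >= 2 and arr.dtype.kind in "ui" else 8
    if arr.dtype.kind == "f":
        bit_depth = 0
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        return replace(
            to_grayscale(arr), bit_depth=bit_depth, source=str(path)
        )
    if arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality: {arr.shape}")
    return GrayImage(arr.astype(float), bit_depth=bit_depth, source=str(path))


def to_grayscale(
    rgb: np.ndarray, weights: tuple[float, float, float] = REC601_WEIGHTS
) -> GrayImage:
    """Reduce a 3-channel raster to luminance.

    The weighted sum keeps the output inside the input range whenever the
    weights sum to 1 (the Rec. 601 default does).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (M, N, 3) array, got shape {rgb.shape}")
    w = np.asarray(weights, dtype=float)
    gray = rgb @ w
    return GrayImage(gray)


def median3x3(img: GrayImage) -> GrayImage:
    """3x3 median filter with reflect (symmetric) border padding.

    Removes isolated photon-noise impulses while preserving fibre edges;
    dimensions are unchanged.
    """
    filtered = ndimage.median_filter(img.pixels, size=3, mode="reflect")
    return replace(img, pixels=filtered)


def crop(img: GrayImage, roi: RectROI) -> GrayImage:
    """Extract the exact sub-array covered by ``roi``; metadata inherited."""
    m, n = img.shape
    if roi.row0 + roi.height > m or roi.col0 + roi.width > n:
        raise ValueError(
            f"ROI {roi} exceeds image bounds {m}x{n}"
        )
    sub = img.pixels[
        roi.row0 : roi.row0 + roi.height, roi.col0 : roi.col0 + roi.width
    ].copy()
    return replace(img, pixels=sub)
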