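"""Windowed amplitude spectra and their equivalent-ellipse geometry.

The shape of the centred 2-D amplitude spectrum |F(u,v)| encodes the
orientation distribution of image texture: oriented fibre bundles put
spectral energy on a ridge perpendicular to the fibres, while disordered
texture spreads energy isotropically. This module windows an image (to
suppress the axis-aligned leakage cross caused by edge discontinuities),
computes the DFT modulus under the 1/(MN) normalisation

    F(u, v) = 1/(MN) * sum_x sum_y f(x, y) exp(-2 pi j (ux/M + vy/N)),

binarises the dominant spectral blob, and summarises the blob by the ellipse
sharing its second central moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "AmplitudeSpectrum",
    "EllipseMeasure",
    "hann2d",
    "amplitude_spectrum",
    "binarize_spectrum",
    "equivalent_ellipse",
    "DegenerateSpectrumError",
]


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum has no usable supra-threshold blob."""


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """Centred DFT modulus |F(u,v)| with the 1/(MN) convention.

    The zero-frequency bin sits at index (M//2, N//2) after centring (the
    declared convention for even sizes).
    """

    values: np.ndarray
    channel_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("spectrum values must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @property
    def center(self) -> tuple[int, int]:
        return self.values.shape[0] // 2, self.values.shape[1] // 2


@dataclass(frozen=True)
class EllipseMeasure:
    """Axes (in frequency bins) of the moment-equivalent ellipse of a blob."""

    long_axis: float
    short_axis: float
    orientation_deg: float
    blob_pixels: int

    def __post_init__(self) -> None:
        if not self.long_axis >= self.short_axis > 0:
            raise ValueError(
                f"need long >= short > 0, got {self.long_axis}, {self.short_axis}"
            )


def hann2d(img: np.ndarray) -> np.ndarray:
    """Taper an image with the separable 2-D Hann window.

    Hann endpoints are zero, so all four corners map to 0; the centre of an
    odd-sized image is untouched (window peak 1). Suppresses the vertical
    and horizontal leakage lines that edge discontinuities would otherwise
    imprint on the spectrum.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError(f"need a 2-D array of at least 16x16, got {img.shape}")
    wr = np.hanning(img.shape[0])
    wc = np.hanning(img.shape[1])
    return img * np.outer(wr, wc)


def amplitude_spectrum(
    img: np.ndarray, channel_id: str | None = None
) -> AmplitudeSpectrum:
    """Centred DFT modulus of a 2-D array, normalised by 1/(MN).

    Under this convention a constant image c has DC bin exactly c, and
    Parseval reads sum |F|^2 = (1/(MN)) sum f^2.
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("input contains non-finite values")
    m, n = img.shape
    spec = np.abs(np.fft.fftshift(np.fft.fft2(img))) / (m * n)
    return AmplitudeSpectrum(values=spec, channel_id=channel_id)


def binarize_spectrum(
    spec: AmplitudeSpectrum,
    quantile: float = 0.995,
    log_compress: bool = True,
    threshold: float | None = None,
    select: str = "central",
) -> np.ndarray:
    """Threshold the spectrum into a binary blob.

    By default the threshold is the given quantile of log(1 + |F|) of this
    spectrum (log compression tames the DC-dominated dynamic range; the
    quantile form is gain invariant); an absolute ``threshold`` (on the
    same compressed scale) may be supplied instead, e.g. a quantile pooled
    over the four directional channels of one image so that relative
    channel strength is preserved. Bins strictly above the threshold are
    kept (falling back to at-threshold bins only when the threshold sits
    exactly on the maximum).

    ``select="central"`` keeps, of the 8-connected supra-threshold
    components, the one containing the DC bin — or the largest component if
    DC itself falls below threshold (ties broken by lowest label, i.e. scan
    order — deterministic). ``select="all"`` keeps the entire
    supra-threshold scatter pattern.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {quantile}")
    values = np.log1p(spec.values) if log_compress else spec.values
    if threshold is None:
        threshold = np.quantile(values, quantile)
    # Strict comparison: an interpolated quantile of a sparse spectrum can
    # land on the zero floor, and the floor itself is never blob content.
    mask = values > threshold
    if not mask.any():
        mask = values >= threshold  # plateau at the maximum
    if not mask.any():
        raise DegenerateSpectrumError("no spectrum bin reaches the threshold")
    if select == "all":
        return mask
    if select != "central":
        raise ValueError(f"unknown component selection: {select!r}")
    labels = measure.label(mask, connectivity=2)
    center_label = labels[spec.center]
    if center_label == 0:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        center_label = int(np.argmax(counts))
    return labels == center_label


def equivalent_ellipse(mask: np.ndarray) -> EllipseMeasure:
    """Axes of the ellipse with the blob's second central moments.

    Axis length = 4 * sqrt(eigenvalue of the coordinate covariance), the
    standard regionprops convention; axes are floored at 1 bin (the extent
    of a single bin), so a single-bin mask returns long = short = 1.
    Orientation is the major-axis angle in degrees, CCW from the +x
    (column) axis, in (-90, 90].
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    # x = column, y = row; covariance of bin coordinates.
    xy = coords[:, ::-1].astype(float)
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    short = max(4.0 * float(np.sqrt(max(eigvals[0], 0.0))), 1.0)
    long = max(4.0 * float(np.sqrt(max(eigvals[1], 0.0))), 1.0)
    vx, vy = eigvecs[:, 1]
    angle = np.degrees(np.arctan2(vy, vx))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return EllipseMeasure(
        long_axis=long,
        short_axis=short,
        orientation_deg=float(angle),
        blob_pixels=int(coords.shape[0]),
    )
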