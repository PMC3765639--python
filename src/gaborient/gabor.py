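"""Directional Gabor filter bank.

A Gabor filter is a Gaussian-windowed sinusoid: an orientation- and
frequency-tuned band-pass filter. The real (cosine-carrier) impulse response
at orientation 0 is

    g(x, y) = 1/(2 pi sx sy) * exp(-(x^2/sx^2 + y^2/sy^2)/2) * cos(2 pi w x)

with spreads sx, sy in pixels and carrier frequency w in cycles/pixel; other
orientations rotate the sampling grid into the filter frame. Because the
cosine kernel is even, the responses at theta and theta+180 coincide, so the
eight directions used for basketweave analysis collapse to four channels
(0, 45, 90, 135 degrees) of paired opposite angles.

Angles are measured counter-clockwise from the +x (column) axis in array
coordinates (rows increasing downward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .preprocess import GrayImage

__all__ = [
    "GaborParams",
    "DirectionalChannel",
    "BANK_THETAS",
    "gabor_kernel",
    "apply_bank",
]

#: The four channel orientations; each stands for the pair {theta, theta+180}.
BANK_THETAS = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one real Gabor kernel.

    sigma_x, sigma_y : Gaussian spreads (pixels) along / across the carrier.
    freq : carrier frequency (cycles/pixel), strictly below Nyquist (0.5).
    theta : orientation (degrees CCW from the image x-axis).
    support_radius : half-size of the sampled kernel (pixels); the kernel is
        (2r+1) x (2r+1). Must cover at least 3 sigma.
    """

    sigma_x: float = 4.0
    sigma_y: float = 4.0
    freq: float = 0.08
    theta: float = 0.0
    support_radius: int = 15

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be positive")
        if not 0.0 < self.freq < 0.5:
            raise ValueError("freq must lie in (0, 0.5) cycles/pixel")
        min_r = math.ceil(3.0 * max(self.sigma_x, self.sigma_y))
        if self.support_radius < min_r:
            raise ValueError(
                f"support_radius {self.support_radius} < 3*max(sigma) = {min_r}"
            )


@dataclass(frozen=True)
class DirectionalChannel:
    """One filtered output of the bank; same shape as the source image."""

    filtered: np.ndarray
    channel_id: str  # e.g. "45/225"
    params: GaborParams


def gabor_kernel(params: GaborParams, response: str = "real") -> np.ndarray:
    """Sample the Gabor impulse response on an odd square integer grid.

    ``response="real"`` gives the cosine-carrier kernel (even-symmetric);
    ``"imag"`` the sine-carrier counterpart; ``"complex"`` both.
    """
    r = params.support_radius
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    th = math.radians(params.theta)
    # Rotate offsets into the filter frame: x' along the carrier.
    xp = dx * math.cos(th) + dy * math.sin(th)
    yp = -dx * math.sin(th) + dy * math.cos(th)
    envelope = (
        1.0 / (2.0 * math.pi * params.sigma_x * params.sigma_y)
    ) * np.exp(
        -0.5 * (xp**2 / params.sigma_x**2 + yp**2 / params.sigma_y**2)
    )
    phase = 2.0 * math.pi * params.freq * xp
    if response == "real":
        return envelope * np.cos(phase)
    if response == "imag":
        return envelope * np.sin(phase)
    if response == "complex":
        return envelope * np.exp(1j * phase)
    raise ValueError(f"unknown response type: {response!r}")


def _convolve_reflect(pixels: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True convolution with symmetric (reflect) padding, output same shape."""
    r = kernel.shape[0] // 2
    if min(pixels.shape) < kernel.shape[0]:
        raise ValueError(
            f"image {pixels.shape} smaller than kernel support {kernel.shape}"
        )
    padded = np.pad(pixels, r, mode="symmetric")
    return fftconvolve(padded, kernel, mode="valid")


def apply_bank(
    img: GrayImage, base: GaborParams | None = None, response: str = "real"
) -> list[DirectionalChannel]:
    """Apply the 4-channel (8-direction) bank to a mean-subtracted image.

    The image mean is removed first so channel energy reflects oriented
    structure rather than overall brightness (the cosine kernel has a
    non-zero DC gain). Channels come back in fixed order
    [0, 45, 90, 135] degrees.

    With ``response="magnitude"`` the modulus of the complex (quadrature)
    response is returned instead of the real part.
    """
    if base is None:
        base = GaborParams()
    pixels = img.pixels - img.pixels.mean()
    channels: list[DirectionalChannel] = []
    for theta in BANK_THETAS:
        params = replace(base, theta=theta)
        if response == "magnitude":
            kernel = gabor_kernel(params, response="complex")
            out = np.abs(_convolve_reflect(pixels, kernel))
        elif response == "real":
            out = _convolve_reflect(pixels, gabor_kernel(params, "real"))
        else:
            raise ValueError(f"unknown bank response: {response!r}")
        channels.append(
            DirectionalChannel(
                filtered=out,
                channel_id=f"{int(theta)}/{int(theta) + 180}",
                params=params,
            )
        )
    return channels
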