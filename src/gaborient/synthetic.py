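"""Basketweave phantoms with a controllable degradation knob.

Healthy dermal collagen forms a basketweave: two families of roughly
parallel fibre bundles crossing at about 90 degrees, which appear as bright
bands on a dark background under cross-polar optics. The phantom renders
exactly that — two families of anti-aliased straight fibres (default
orientations 45 and 135 degrees in the image frame) — and degrades it by
jittering each fibre's orientation with a zero-mean normal perturbation.
The jitter SD stands in for the age- and disease-related relaxation of the
basketweave; isotropic Gaussian noise images are the fully disordered
control.

Ground truth is analytic: the spectral energy of a fibre family
concentrates in a wedge perpendicular to the fibre orientation, so wedge
energy scans recover the configured angles and provide a method-independent
ordering of degradation levels.

Angles are degrees CCW from the +x (column) axis in array coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import transform

from .preprocess import GrayImage
from .spectrum import amplitude_spectrum, hann2d

__all__ = [
    "PhantomSpec",
    "generate_basketweave",
    "generate_isotropic",
    "rotate_crop",
    "wedge_energy_fraction",
    "dominant_orientations",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one basketweave phantom.

    Fibres are finite straight segments (collagen bundles have finite
    length; infinitely long lines would give unrealistically sharp spectral
    ridges). fiber_spacing is the mean centre-to-centre spacing (pixels)
    and must exceed fiber_width; fiber_length is the (min, max) of the
    uniform segment-length distribution; angular_jitter_sd (degrees) is the
    degradation knob; n_fibers_per_family of None lays down enough segments
    to cover the field at the given spacing. fiber_fraction < 1 randomly
    drops fibres (density-loss knob, unused by the standard degradation
    series).
    """

    height: int = 256
    width: int = 256
    fiber_width: float = 4.0
    fiber_spacing: float = 12.0
    family_angles: tuple[float, float] = (45.0, 135.0)
    angular_jitter_sd: float = 0.0
    n_fibers_per_family: int | None = None
    fiber_length: tuple[float, float] = (60.0, 100.0)
    fiber_intensity: float = 0.7
    intensity_jitter: float = 0.25
    fiber_fraction: float = 1.0
    noise_sd: float = 0.02
    background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fiber_width < 1:
            raise ValueError("fiber_width must be >= 1 pixel")
        if self.fiber_spacing <= self.fiber_width:
            raise ValueError("fiber_spacing must exceed fiber_width")
        if self.angular_jitter_sd < 0:
            raise ValueError("angular_jitter_sd must be >= 0")
        if not 0.0 <= self.fiber_fraction <= 1.0:
            raise ValueError("fiber_fraction must lie in [0, 1]")
        if not 0 < self.fiber_length[0] <= self.fiber_length[1]:
            raise ValueError("fiber_length must be an increasing positive pair")


def _render_segment(img, cx, cy, theta_rad, half_len, width, amplitude):
    """Add one anti-aliased segment (round caps, 1-px edge ramp) in place."""
    h, w = img.shape
    ux, uy = math.cos(theta_rad), math.sin(theta_rad)
    nx, ny = -uy, ux
    reach = width / 2.0 + 1.0
    x0, x1 = cx - abs(ux) * half_len - reach, cx + abs(ux) * half_len + reach
    y0, y1 = cy - abs(uy) * half_len - reach, cy + abs(uy) * half_len + reach
    c0, c1 = max(int(x0), 0), min(int(x1) + 2, w)
    r0, r1 = max(int(y0), 0), min(int(y1) + 2, h)
    if c0 >= c1 or r0 >= r1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)
    t = (xx - cx) * ux + (yy - cy) * uy
    d_perp = (xx - cx) * nx + (yy - cy) * ny
    dist = np.hypot(d_perp, np.maximum(np.abs(t) - half_len, 0.0))
    img[r0:r1, c0:c1] += amplitude * np.clip(
        width / 2.0 + 0.5 - dist, 0.0, 1.0
    )


def generate_basketweave(spec: PhantomSpec) -> GrayImage:
    """Render a basketweave phantom; identical spec + seed gives identical
    pixels.

    Segment centres are uniform over a margin-extended field; each
    segment's orientation is its family angle plus an independent draw from
    N(0, angular_jitter_sd), its length uniform over fiber_length, its
    brightness perturbed by intensity_jitter (relative SD). Overlapping
    fibres add (bright birefringent bundles on a dark cross-polar
    background), then Gaussian intensity noise is added and the result
    clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    diag = math.hypot(h, w)
    mean_len = 0.5 * (spec.fiber_length[0] + spec.fiber_length[1])
    img = np.full((h, w), float(spec.background))

    for angle in spec.family_angles:
        if spec.n_fibers_per_family is None:
            # Total fibre length per family ~ diag^2 / spacing, as a stack
            # of full-diagonal fibres at the given spacing would lay down.
            n_fibers = int(round(diag * diag / (spec.fiber_spacing * mean_len)))
        else:
            n_fibers = spec.n_fibers_per_family
        for _ in range(n_fibers):
            cx = rng.uniform(-0.1 * w, 1.1 * w)
            cy = rng.uniform(-0.1 * h, 1.1 * h)
            theta = math.radians(angle + rng.normal(0.0, spec.angular_jitter_sd))
            half_len = rng.uniform(*spec.fiber_length) / 2.0
            amp = spec.fiber_intensity * float(
                np.clip(rng.normal(1.0, spec.intensity_jitter), 0.2, 2.0)
            )
            if spec.fiber_fraction < 1.0 and rng.random() >= spec.fiber_fraction:
                continue
            _render_segment(img, cx, cy, theta, half_len, spec.fiber_width, amp)

    img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    np.clip(img, 0.0, 1.0, out=img)
    return GrayImage(img, bit_depth=0, source=f"basketweave(seed={spec.seed})")


def generate_isotropic(
    height: int, width: int, seed: int, mean: float = 0.5, sd: float = 0.15
) -> GrayImage:
    """Gaussian white-noise control image, clipped to [0, 1]."""
    if height < 64 or width < 64:
        raise ValueError("isotropic control must be at least 64x64")
    rng = np.random.default_rng(seed)
    img = np.clip(rng.normal(mean, sd, size=(height, width)), 0.0, 1.0)
    return GrayImage(img, bit_depth=0, source=f"isotropic(seed={seed})")


def _max_inscribed_rect(w: int, h: int, angle_deg: float) -> tuple[int, int]:
    """Largest axis-aligned rectangle inside a w x h rectangle rotated by
    ``angle_deg``, same aspect handling as the classic rotated-rect formula."""
    a = abs(math.radians(angle_deg))
    if w <= 0 or h <= 0:
        return 0, 0
    width_longer = w >= h
    side_long, side_short = (w, h) if width_longer else (h, w)
    sin_a, cos_a = abs(math.sin(a)), abs(math.cos(a))
    if side_short <= 2.0 * sin_a * cos_a * side_long or abs(sin_a - cos_a) < 1e-10:
        x = 0.5 * side_short
        wr, hr = (x / sin_a, x / cos_a) if width_longer else (x / cos_a, x / sin_a)
    else:
        cos_2a = cos_a * cos_a - sin_a * sin_a
        wr = (w * cos_a - h * sin_a) / cos_2a
        hr = (h * cos_a - w * sin_a) / cos_2a
    return int(math.floor(wr)), int(math.floor(hr))


def rotate_crop(img: GrayImage, angle: float) -> GrayImage:
    """Rotate about the centre and crop away interpolation padding.

    Multiples of 90 degrees are exact array quarter-turns (no interpolation,
    no crop); other angles must lie in [-45, 45] and use bilinear
    interpolation followed by a central crop to the largest axis-aligned
    rectangle free of padded pixels.
    """
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        out = np.rot90(img.pixels, k).copy()
        return GrayImage(out, bit_depth=img.bit_depth,
                         pixel_size_um=img.pixel_size_um, source=img.source)
    if not -45.0 <= angle <= 45.0:
        raise ValueError("interpolated rotation supports angles in [-45, 45]")
    rotated = transform.rotate(
        img.pixels, angle, resize=False, order=1, mode="constant",
        cval=0.0, preserve_range=True,
    )
    h, w = img.shape
    cw, ch = _max_inscribed_rect(w, h, angle)
    if ch < 64 or cw < 64:
        raise ValueError(f"cropped result {ch}x{cw} smaller than 64x64")
    r0 = (h - ch) // 2
    c0 = (w - cw) // 2
    out = rotated[r0 : r0 + ch, c0 : c0 + cw].copy()
    return GrayImage(out, bit_depth=img.bit_depth,
                     pixel_size_um=img.pixel_size_um, source=img.source)


def _spectral_energy_and_angles(img: GrayImage, exclude_radius: float = 3.0):
    """Windowed spectral energy |F|^2 per bin with each bin's orientation
    angle (degrees mod 180); bins within ``exclude_radius`` of DC are
    dropped so low-frequency background does not dominate."""
    pixels = img.pixels - img.pixels.mean()
    spec = amplitude_spectrum(hann2d(pixels)).values
    h, w = spec.shape
    vy, vx = np.mgrid[0:h, 0:w].astype(float)
    vy -= h // 2
    vx -= w // 2
    radius = np.hypot(vx, vy)
    keep = radius > exclude_radius
    angles = np.degrees(np.arctan2(vy, vx)) % 180.0
    return (spec[keep] ** 2), angles[keep]


def wedge_energy_fraction(
    img: GrayImage, fiber_angles, half_width_deg: float = 10.0
) -> float:
    """Fraction of non-DC spectral energy within angular wedges
    perpendicular to the given fibre orientations.

    A fibre family at angle phi modulates intensity along phi + 90, so its
    spectral ridge lies in the wedge centred on (phi + 90) mod 180.
    """
    energy, angles = _spectral_energy_and_angles(img)
    total = energy.sum()
    if total == 0:
        return 0.0
    in_wedge = np.zeros(angles.shape, dtype=bool)
    for phi in np.atleast_1d(np.asarray(fiber_angles, dtype=float)):
        wedge_center = (phi + 90.0) % 180.0
        delta = np.abs((angles - wedge_center + 90.0) % 180.0 - 90.0)
        in_wedge |= delta <= half_width_deg
    return float(energy[in_wedge].sum() / total)


def dominant_orientations(
    img: GrayImage, n_peaks: int = 2, half_width_deg: float = 5.0,
    min_separation_deg: float = 20.0,
) -> list[float]:
    """Recover dominant fibre orientations by an exhaustive wedge-energy
    scan over 1-degree wedge centres; returns fibre angles (wedge - 90,
    mod 180), strongest first."""
    energy, angles = _spectral_energy_and_angles(img)
    centers = np.arange(0.0, 180.0, 1.0)
    scores = np.empty_like(centers)
    for i, c in enumerate(centers):
        delta = np.abs((angles - c + 90.0) % 180.0 - 90.0)
        scores[i] = energy[delta <= half_width_deg].sum()
    order = np.argsort(scores)[::-1]
    picked: list[float] = []
    for idx in order:
        c = centers[idx]
        if all(
            min(abs(c - p), 180.0 - abs(c - p)) >= min_separation_deg
            for p in picked
        ):
            picked.append(float(c))
        if len(picked) == n_peaks:
            break
    return [(c - 90.0) % 180.0 for c in picked]
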