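"""The collagen orientation index.

Each Gabor channel's binarised spectrum blob is scored by its elongation

    N_wn = 1 - short_axis / long_axis            (per direction, in [0, 1))

and the per-image orientation index is the spread of those scores across
the four directions,

    N = max(N_wn) / min(N_wn)                    (>= 1).

An intact basketweave (two fibre families crossing at ~90 degrees, e.g.
45/135) loads the diagonal channels disproportionately, giving unequal
elongations and a large N; as orientation order degrades the four channel
spectra approach equality and N falls toward 1.

An FFT-only baseline scores the single unfiltered spectrum by its
elongation alone (one blob, so the max/min ratio is undefined); it is less
sensitive to incipient degradation but provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .gabor import apply_bank
from .preprocess import GrayImage, median3x3
from .spectrum import (
    EllipseMeasure,
    amplitude_spectrum,
    binarize_spectrum,
    equivalent_ellipse,
    hann2d,
)

__all__ = [
    "OrientationResult",
    "DegenerateIsotropyError",
    "n_omega",
    "orientation_index",
    "analyze_image_gabor",
    "analyze_image_fft_only",
    "aggregate",
]


class DegenerateIsotropyError(ValueError):
    """A channel's spectrum blob is (numerically) circular: N undefined."""


@dataclass(frozen=True)
class OrientationResult:
    """Per-image outcome of one analysis method.

    n_omega maps channel id (e.g. "45/225") to the per-direction elongation
    score; for the FFT-only method it holds the single spectrum's score
    under the key "fft". index_N is max/min across channels for the Gabor
    method and the lone elongation for the baseline.
    """

    n_omega: dict[str, float]
    index_N: float
    method: str  # "gabor_fft" | "fft_only"
    image_id: str | None = None
    compartment: str | None = None
    config_hash: str = ""
    ellipses: dict[str, EllipseMeasure] = field(default_factory=dict, repr=False)


def n_omega(e: EllipseMeasure) -> float:
    """Per-direction elongation score 1 - short/long, in [0, 1)."""
    if not e.long_axis >= e.short_axis > 0:
        raise ValueError(f"invalid axes: long={e.long_axis}, short={e.short_axis}")
    return 1.0 - e.short_axis / e.long_axis


def orientation_index(
    n_values, epsilon_floor: float = 1e-3
) -> float:
    """Max/min ratio of the per-direction scores; >= 1 by construction.

    A score at or below ``epsilon_floor`` means one channel's blob is
    essentially circular; that is reported as
    :class:`DegenerateIsotropyError` rather than silently clamped, so
    isotropic-channel pathologies surface in QC output.
    """
    vals = np.asarray(list(n_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no channel scores given")
    if np.any(vals <= epsilon_floor):
        raise DegenerateIsotropyError(
            f"channel elongation at/below floor {epsilon_floor}: {vals.tolist()}"
        )
    return float(vals.max() / vals.min())


def _channel_spectrum(
    arr: np.ndarray, channel_id: str, config: AnalysisConfig
):
    windowed = hann2d(arr) if config.window == "hann" else np.asarray(arr, float)
    # The taper reintroduces a small DC term even on mean-subtracted input;
    # null it so the blob selection tracks oriented energy, not residual DC.
    windowed = windowed - windowed.mean()
    return amplitude_spectrum(windowed, channel_id=channel_id)


def _check_size(img: GrayImage, config: AnalysisConfig) -> None:
    if min(img.shape) < config.min_side:
        raise ValueError(
            f"image {img.shape} below configured minimum side {config.min_side}"
        )


def analyze_image_gabor(
    img: GrayImage,
    config: AnalysisConfig | None = None,
    *,
    image_id: str | None = None,
    compartment: str | None = None,
) -> OrientationResult:
    """Full chain: median filter -> Gabor bank -> window -> FFT -> blob ->
    per-channel elongation -> max/min index.

    Deterministic for fixed input and configuration.
    """
    config = config or AnalysisConfig()
    _check_size(img, config)
    smoothed = median3x3(img)
    channels = apply_bank(smoothed, config.gabor, response=config.gabor_response)
    specs = [
        _channel_spectrum(ch.filtered, ch.channel_id, config) for ch in channels
    ]
    # One threshold for all four channels: the binarisation quantile is
    # taken over the pooled channel spectra so that a direction holding a
    # disproportionate share of the image's oriented energy yields a larger,
    # more elongated blob. A per-channel quantile would self-normalise each
    # channel and erase exactly that disproportion.
    pooled = np.concatenate([
        (np.log1p(s.values) if config.log_compress else s.values).ravel()
        for s in specs
    ])
    threshold = float(np.quantile(pooled, config.quantile))
    scores: dict[str, float] = {}
    ellipses: dict[str, EllipseMeasure] = {}
    for spec in specs:
        mask = binarize_spectrum(
            spec, quantile=config.quantile, log_compress=config.log_compress,
            threshold=threshold, select="all",
        )
        ellipse = equivalent_ellipse(mask)
        ellipses[spec.channel_id] = ellipse
        scores[spec.channel_id] = n_omega(ellipse)
    index = orientation_index(scores.values(), config.epsilon_floor)
    return OrientationResult(
        n_omega=scores,
        index_N=index,
        method="gabor_fft",
        image_id=image_id or img.source,
        compartment=compartment,
        config_hash=config.fingerprint,
        ellipses=ellipses,
    )


def analyze_image_fft_only(
    img: GrayImage,
    config: AnalysisConfig | None = None,
    *,
    image_id: str | None = None,
    compartment: str | None = None,
) -> OrientationResult:
    """Baseline: median filter -> window -> FFT -> blob -> elongation.

    The single spectrum's elongation score (in [0, 1)) is itself the
    reported index — with one spectrum there is no max/min ratio to take.
    """
    config = config or AnalysisConfig()
    _check_size(img, config)
    smoothed = median3x3(img)
    centered = smoothed.pixels - smoothed.pixels.mean()
    spec = _channel_spectrum(centered, "fft", config)
    # As for the Gabor channels, the whole supra-threshold scatter pattern
    # is measured: white noise then yields a near-square (round) pattern and
    # a score near 0, oriented texture an elongated one.
    mask = binarize_spectrum(
        spec, quantile=config.quantile, log_compress=config.log_compress,
        select="all",
    )
    ellipse = equivalent_ellipse(mask)
    score = n_omega(ellipse)
    return OrientationResult(
        n_omega={"fft": score},
        index_N=score,
        method="fft_only",
        image_id=image_id or img.source,
        compartment=compartment,
        config_hash=config.fingerprint,
        ellipses={"fft": ellipse},
    )


def aggregate(
    results: list[OrientationResult], animal_of: dict[str, str]
) -> pd.DataFrame:
    """Per-animal mean index, as in averaging >= 3 fields per animal.

    Groups by (animal, method, compartment) and reports arithmetic mean,
    SD and count of index_N. Warns for animals represented by fewer than
    three fields. Raises KeyError for an image id with no animal mapping.
    """
    rows = []
    for res in results:
        if res.image_id not in animal_of:
            raise KeyError(f"no animal mapping for image id {res.image_id!r}")
        rows.append(
            {
                "animal": animal_of[res.image_id],
                "method": res.method,
                "compartment": res.compartment or "",
                "index_N": res.index_N,
            }
        )
    frame = pd.DataFrame(rows)
    summary = (
        frame.groupby(["animal", "method", "compartment"], as_index=False)
        .agg(mean_index=("index_N", "mean"), sd_index=("index_N", "std"),
             count=("index_N", "size"))
    )
    for _, row in summary.iterrows():
        if row["count"] < 3:
            warnings.warn(
                f"animal {row['animal']!r} ({row['method']}) has only "
                f"{row['count']} field(s); means are based on >= 3 in practice",
                stacklevel=2,
            )
    return summary
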