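"""Analysis configuration and its canonical fingerprint.

Index values are only comparable within one configuration, so every result
carries a short hash of the canonical serialisation of the parameters that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .gabor import GaborParams

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable parameters of the orientation-index pipeline.

    gabor : kernel spreads / carrier frequency / support of the bank.
    gabor_response : "real" (cosine kernel, the default) or "magnitude"
        (quadrature modulus).
    quantile : spectrum binarisation quantile on log-compressed amplitude.
    log_compress : whether to log-compress before thresholding.
    window : "hann" or "none".
    epsilon_floor : smallest admissible per-channel elongation; a channel
        below it signals degenerate isotropy rather than being clamped.
    min_side : smallest image side accepted for a stable spectrum.
    """

    gabor: GaborParams = field(default_factory=GaborParams)
    gabor_response: str = "real"
    quantile: float = 0.995
    log_compress: bool = True
    window: str = "hann"
    epsilon_floor: float = 1e-3
    min_side: int = 64

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def fingerprint(self) -> str:
        """12-hex-digit hash of the canonical JSON serialisation."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
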