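"""Pearson correlation reporting with Fisher-z confidence intervals.

Mirrors the correlation summaries used to relate the orientation index to
age or disease status: r, r^2, a two-sided p-value from the t-transform
with n-2 degrees of freedom, and a 95% CI for r via the Fisher
z-transform. Group tests (t-tests, ANOVA) are deliberately left to
downstream tools; the package emits tidy per-animal CSVs for that purpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = ["CorrelationReport", "pearson", "cohens_d"]


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    r2: float
    p: float
    ci_low: float
    ci_high: float
    n: int


def pearson(x, y, ci_level: float = 0.95) -> CorrelationReport:
    """Product-moment correlation with p-value and CI for r.

    The CI is for the correlation coefficient itself (Fisher z at the
    given level), not for a regression slope. Requires n >= 3 and
    non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need equal-length 1-D inputs, got {x.shape}, {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sstats.pearsonr(x, y)
    r = float(res.statistic)
    p = float(res.pvalue)
    # Fisher z CI; with n == 3 the SE is infinite and the CI is (-1, 1).
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zcrit = sstats.norm.ppf(0.5 + ci_level / 2.0)
        ci_low = float(np.tanh(z - zcrit * se))
        ci_high = float(np.tanh(z + zcrit * se))
    elif abs(r) >= 1.0:
        ci_low = ci_high = r
    else:
        ci_low, ci_high = -1.0, 1.0
    return CorrelationReport(r=r, r2=r * r, p=p, ci_low=ci_low, ci_high=ci_high, n=n)


def cohens_d(a, b) -> float:
    """Standardised mean difference (pooled-SD Cohen's d) between groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
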