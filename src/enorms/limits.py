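"""One-sided reference limits from a value set.

Whether the values come from a plateau extract (indirect route) or from a
directly sampled healthy control cohort (traditional route), the limit
calculation is the same: transform to approximate normality when the sample
is skewed, take mean +/- k standard deviations on the transformed scale
(k = 2 by convention, k = 2.5 as a more lenient variant compensating for
truncation-deflated SD), and back-transform.  An empirical-percentile
alternative (top/bottom 1%) sidesteps the normality assumption entirely.

Limits are one-sided: amplitudes and conduction velocities are abnormal
below their lower limit, latencies above their upper limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ContractError, InsufficientDataError

__all__ = [
    "TransformSpec",
    "IDENTITY",
    "LOG_SHIFT",
    "ReferenceLimit",
    "choose_transform",
    "sd_limit",
    "percentile_limit",
]


@dataclass(frozen=True)
class TransformSpec:
    """Monotone transform applied before mean +/- k*SD.

    ``log_shift`` is ``y = ln(x + c)`` with inverse ``x = exp(y) - c``; the
    small shift constant (default c = 0.1) keeps zero-valued measurements
    transformable.
    """

    kind: str = "identity"  # identity | log_shift
    shift: float = 0.1

    def __post_init__(self):
        if self.kind not in ("identity", "log_shift"):
            raise ContractError(f"unknown transform kind {self.kind!r}")

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return x
        if np.any(x <= -self.shift):
            raise ContractError(
                f"log_shift transform requires all values > {-self.shift}"
            )
        return np.log(x + self.shift)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        if self.kind == "identity":
            return y
        return np.exp(y) - self.shift


IDENTITY = TransformSpec("identity")
LOG_SHIFT = TransformSpec("log_shift", 0.1)


@dataclass(frozen=True)
class ReferenceLimit:
    """A one-sided reference limit in the measure's original units.

    ``direction`` is the measure's pathological side: readings are abnormal
    strictly below a ``low`` limit or strictly above a ``high`` limit.
    ``method`` records how the limit was derived (``sd`` with multiplier k,
    or ``percentile`` with tail percentage k).
    """

    limit: float
    direction: str  # low | high
    method: str  # sd | percentile
    k: float  # SD multiplier, or tail percentage for percentile limits
    transform: TransformSpec
    n_source: int
    measure: str | None = None

    def __post_init__(self):
        if self.direction not in ("low", "high"):
            raise ContractError(f"direction must be low|high, got {self.direction!r}")
        if not np.isfinite(self.limit):
            raise ContractError("reference limit must be finite")

    def to_dict(self) -> dict:
        return {
            "limit": self.limit,
            "direction": self.direction,
            "method": self.method,
            "k_or_p": self.k,
            "transform": self.transform.kind,
            "n": self.n_source,
            "measure": self.measure,
        }


def choose_transform(
    values: Sequence[float], skew_threshold: float = 0.5
) -> TransformSpec:
    """Pick identity or log-shift by sample skewness.

    Uses the adjusted Fisher-Pearson skewness coefficient; the log-shift
    transform is chosen only for clearly right-skewed samples
    (skewness > ``skew_threshold``) that the shifted log can handle.
    Degenerate (constant) samples count as symmetric.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 10:
        raise InsufficientDataError(
            f"transform choice needs at least 10 values, got {len(v)}"
        )
    if np.ptp(v) == 0:
        return IDENTITY
    skew = stats.skew(v, bias=False)
    if np.isfinite(skew) and skew > skew_threshold and np.all(v > -LOG_SHIFT.shift):
        return LOG_SHIFT
    return IDENTITY


def sd_limit(
    values: Sequence[float],
    k: float,
    direction: str,
    transform: TransformSpec = IDENTITY,
    measure: str | None = None,
) -> ReferenceLimit:
    """Mean +/- k*SD limit on the transformed scale, back-transformed.

    The sample SD uses the n-1 denominator.  ``direction='low'`` yields
    ``inverse(m - k*s)``; ``direction='high'`` yields ``inverse(m + k*s)``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InsufficientDataError(f"sd limit needs n >= 2, got {len(v)}")
    if direction not in ("low", "high"):
        raise ContractError(f"direction must be low|high, got {direction!r}")
    t = transform.forward(v)
    m = float(np.mean(t))
    s = float(np.std(t, ddof=1))
    if s == 0 and k > 0:
        warnings.warn(
            "zero variance in transformed values; limit equals the mean",
            stacklevel=2,
        )
    shifted = m - k * s if direction == "low" else m + k * s
    return ReferenceLimit(
        limit=float(transform.inverse(shifted)),
        direction=direction,
        method="sd",
        k=float(k),
        transform=transform,
        n_source=len(v),
        measure=measure,
    )


def percentile_limit(
    values: Sequence[float],
    p: float,
    direction: str,
    measure: str | None = None,
) -> ReferenceLimit:
    """Empirical tail-percentile limit (e.g. bottom/top 1%).

    Uses linear interpolation of the order statistics with plotting position
    ``(i-1)/(n-1)``.  ``direction='low'`` takes the p-th percentile,
    ``direction='high'`` the (100-p)-th.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 10:
        raise InsufficientDataError(f"percentile limit needs n >= 10, got {len(v)}")
    if not (0 < p < 50):
        raise ContractError(f"tail percentage must be in (0, 50), got {p}")
    if direction not in ("low", "high"):
        raise ContractError(f"direction must be low|high, got {direction!r}")
    q = p / 100.0 if direction == "low" else 1.0 - p / 100.0
    return ReferenceLimit(
        limit=float(np.quantile(v, q, method="linear")),
        direction=direction,
        method="percentile",
        k=float(p),
        transform=IDENTITY,
        n_source=len(v),
        measure=measure,
    )
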