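"""Rank-order S-curve construction.

The extrapolated-norms method starts from a mixed historical sample: the
values are sorted ascending and plotted against rank, producing an inverted
S-curve whose steep tails hold abnormal readings and whose flat central
plateau holds the cluster of normal ones.  This module builds that curve and
its visual-aid series: first-order differences between consecutive sorted
values, a right-aligned rolling mean of those differences, and an ordinary
least-squares cubic of value on rank (the cubic tends to cross the data near
the plateau's inflection points).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, InsufficientDataError

__all__ = [
    "ENormsCurve",
    "CubicCrossings",
    "build_curve",
    "first_differences",
    "rolling_mean",
    "effective_window",
    "fit_cubic",
    "cubic_crossings",
]


@dataclass(frozen=True)
class ENormsCurve:
    """Sorted values against 1-based rank, with smoothing and cubic overlay.

    Attributes
    ----------
    values : ndarray
        Measurement values sorted ascending (length n).
    ranks : ndarray
        Integers 1..n.
    diffs : ndarray
        First-order differences ``values[i+1] - values[i]`` (length n-1).
    smoothed_diffs : ndarray
        Right-aligned rolling mean of ``diffs`` (length n-1); leading
        positions use the available prefix (partial windows).
    window : int
        Rolling-window width actually used (>= 3).
    cubic : tuple
        Coefficients ``(a3, a2, a1, a0)`` of the least-squares cubic of
        value on raw rank.
    meta : dict
        Pass-through measure metadata (nerve, measure kind, units...).
    """

    values: np.ndarray
    ranks: np.ndarray
    diffs: np.ndarray
    smoothed_diffs: np.ndarray
    window: int
    cubic: tuple[float, float, float, float]
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def value_range(self) -> float:
        return float(self.values[-1] - self.values[0])

    def cubic_at(self, rank) -> np.ndarray:
        """Evaluate the fitted cubic at (possibly fractional) rank."""
        a3, a2, a1, a0 = self.cubic
        r = np.asarray(rank, dtype=float)
        return ((a3 * r + a2) * r + a1) * r + a0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "window": self.window,
            "values": self.values.tolist(),
            "diffs": self.diffs.tolist(),
            "smoothed_diffs": self.smoothed_diffs.tolist(),
            "cubic": list(self.cubic),
            "meta": dict(self.meta),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ENormsCurve":
        values = np.asarray(d["values"], dtype=float)
        return cls(
            values=values,
            ranks=np.arange(1, len(values) + 1),
            diffs=np.asarray(d["diffs"], dtype=float),
            smoothed_diffs=np.asarray(d["smoothed_diffs"], dtype=float),
            window=int(d["window"]),
            cubic=tuple(d["cubic"]),
            meta=dict(d.get("meta", {})),
        )

    @classmethod
    def from_json(cls, path) -> "ENormsCurve":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CubicCrossings:
    """Ranks where the sorted data crosses its fitted cubic.

    ``crossings`` holds the left rank of each residual sign change;
    ``inflection_rank`` is the cubic's analytic inflection -a2/(3*a3)
    (None when the cubic degenerates, a3 == 0).
    """

    crossings: list[int]
    inflection_rank: float | None


def first_differences(sorted_values: Sequence[float]) -> np.ndarray:
    """Consecutive differences of an ascending-sorted series.

    Returns ``v[1]-v[0], v[2]-v[1], ...`` (length n-1, all >= 0).  Small
    differences mark the plateau; spikes mark the tails.
    """
    v = np.asarray(sorted_values, dtype=float)
    d = np.diff(v)
    if len(d) and d.min() < 0:
        raise ContractError("input to first_differences must be non-decreasing")
    return d


def rolling_mean(series: Sequence[float], window: int) -> np.ndarray:
    """Right-aligned rolling mean with partial prefix windows.

    Element i is ``mean(series[max(0, i-window+1) .. i])``, so the output has
    the same length as the input and the leading elements average the
    available prefix rather than being undefined.
    """
    if window < 1:
        raise ContractError(f"window must be >= 1, got {window}")
    s = pd.Series(np.asarray(series, dtype=float))
    if s.empty:
        raise ContractError("series must be non-empty")
    return s.rolling(window=window, min_periods=1).mean().to_numpy()


def effective_window(n: int, fraction: float) -> int:
    """Rolling-window width: ``max(3, ceil(fraction * n))``.

    The nominal width is a fixed fraction of the sample (default 0.1%); the
    floor of 3 keeps smoothing defined for the smallest admissible groups.
    """
    if n < 10:
        raise InsufficientDataError(f"n must be >= 10, got {n}")
    if not (0 < fraction < 1):
        raise ContractError(f"fraction must be in (0, 1), got {fraction}")
    return max(3, math.ceil(fraction * n))


def fit_cubic(
    ranks: Sequence[float], values: Sequence[float]
) -> tuple[float, float, float, float]:
    """Ordinary least-squares cubic of value on rank.

    Returns coefficients ``(a3, a2, a1, a0)`` in the raw-rank basis.  The fit
    is performed on an internally scaled domain for conditioning and
    converted back.
    """
    r = np.asarray(ranks, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(r) < 4:
        raise InsufficientDataError(
            f"cubic fit needs at least 4 points, got {len(r)}"
        )
    poly = np.polynomial.Polynomial.fit(r, v, deg=3).convert()
    a0, a1, a2, a3 = np.pad(poly.coef, (0, 4 - len(poly.coef)))
    return (float(a3), float(a2), float(a1), float(a0))


def cubic_crossings(curve: ENormsCurve) -> CubicCrossings:
    """Where the S-curve intersects its cubic overlay.

    Reports the left rank of each residual sign change (exact zeros are
    carried through to the next non-zero residual) together with the cubic's
    own analytic inflection rank.
    """
    residuals = curve.values - curve.cubic_at(curve.ranks)
    signs = np.sign(residuals)
    nz = np.nonzero(signs)[0]
    crossings: list[int] = []
    for left, right in zip(nz[:-1], nz[1:]):
        if signs[left] != signs[right]:
            crossings.append(int(curve.ranks[left]))
    a3, a2 = curve.cubic[0], curve.cubic[1]
    inflection = None if a3 == 0 else float(-a2 / (3.0 * a3))
    return CubicCrossings(crossings=crossings, inflection_rank=inflection)


def build_curve(
    values: Sequence[float],
    window_fraction: float = 0.001,
    meta: dict | None = None,
) -> ENormsCurve:
    """Sort a sample ascending and assemble the full e-norms curve.

    Parameters
    ----------
    values : sequence of float
        Raw measurement values for one (stratum, nerve, measure) group;
        at least 10 finite values.
    window_fraction : float
        Rolling-window width as a fraction of n (default 0.001, i.e. 0.1%
        of the sample), floored at 3 points.
    meta : dict, optional
        Measure metadata carried through to reports and plots.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ContractError("values must be one-dimensional")
    if len(v) < 10:
        raise InsufficientDataError(
            f"an e-norms curve needs at least 10 values, got {len(v)}"
        )
    if not np.all(np.isfinite(v)):
        raise ContractError("values must all be finite")
    v = np.sort(v, kind="stable")
    n = len(v)
    window = effective_window(n, window_fraction)
    diffs = first_differences(v)
    smoothed = rolling_mean(diffs, window)
    ranks = np.arange(1, n + 1)
    cubic = fit_cubic(ranks, v)
    return ENormsCurve(
        values=v,
        ranks=ranks,
        diffs=diffs,
        smoothed_diffs=smoothed,
        window=window,
        cubic=cubic,
        meta=dict(meta or {}),
    )
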