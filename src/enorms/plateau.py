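"""Plateau identification on the rank-order S-curve.

The plateau — the flat central run of ranks — is interpreted as the cluster
of normal measurements.  Historically it is marked by human raters fitting a
tangent by eye, matched with the interval of lowest first-order derivatives;
two blinded raters mark independently, similar marks (< 10% difference in
plateau size) are averaged, and disagreements go to a third rater.  This
module implements that rater protocol over marker files, plus an automated
detector: the longest rank window whose least-squares line stays within a
residual tolerance, constrained to lie in the low-derivative region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curve import ENormsCurve
from .exceptions import ContractError, NoPlateauError, ProtocolError

__all__ = [
    "Plateau",
    "TangentFit",
    "RaterMarks",
    "ThirdRaterNeeded",
    "default_min_size",
    "detect_plateau_auto",
    "fit_tangent",
    "reconcile",
    "resolve_third",
    "plateau_values",
    "read_ratings",
    "write_ratings",
]

#: Exhaustive all-window scan is used up to this n; above it a
#: stride-then-refine scan keeps detection near-linear.
EXACT_SCAN_MAX_N = 5000


@dataclass(frozen=True)
class Plateau:
    """Inclusive 1-based rank interval marking the normal cluster."""

    start_rank: int
    end_rank: int
    provenance: str = "auto"  # auto | rater:<id> | reconciled | third_rater

    def __post_init__(self):
        if not (1 <= self.start_rank < self.end_rank):
            raise ContractError(
                f"invalid plateau bounds ({self.start_rank}, {self.end_rank})"
            )

    @property
    def size(self) -> int:
        return self.end_rank - self.start_rank + 1

    def to_dict(self) -> dict:
        return {
            "start_rank": self.start_rank,
            "end_rank": self.end_rank,
            "size": self.size,
            "provenance": self.provenance,
        }


@dataclass(frozen=True)
class TangentFit:
    """Least-squares line over a plateau window (the automated tangent)."""

    slope: float
    intercept: float
    rmse: float

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "rmse": self.rmse}


@dataclass(frozen=True)
class RaterMarks:
    """One rater's plateau marks for one (blinded) curve."""

    rater_id: str
    curve_id: str
    start_rank: int
    end_rank: int

    @property
    def size(self) -> int:
        return self.end_rank - self.start_rank + 1


@dataclass(frozen=True)
class ThirdRaterNeeded:
    """Signal that two raters' marks differ too much to average."""

    a: RaterMarks
    b: RaterMarks
    relative_size_difference: float


def default_min_size(n: int) -> int:
    """Default minimum plateau size: max(30, 10% of the sample)."""
    return max(30, math.ceil(0.1 * n))


def _window_stats(values: np.ndarray, smoothed: np.ndarray):
    """Prefix sums enabling O(1) per-window OLS residuals and diff means.

    Values are centred on their grand mean before squaring to limit
    cancellation in the RSS identity.
    """
    vc = values - values.mean()
    s1 = np.concatenate(([0.0], np.cumsum(vc)))
    s2 = np.concatenate(([0.0], np.cumsum(vc * vc)))
    x = np.arange(len(values), dtype=float)
    sxy = np.concatenate(([0.0], np.cumsum(x * vc)))
    sd = np.concatenate(([0.0], np.cumsum(smoothed)))
    return s1, s2, sxy, sd


def _window_rmse(s1, s2, sxy, starts: np.ndarray, length: int) -> np.ndarray:
    """RMSE of the per-window OLS line for all windows [i, i+length-1]."""
    i = starts
    j = starts + length - 1
    sum_y = s1[j + 1] - s1[i]
    sum_y2 = s2[j + 1] - s2[i]
    sum_xy = sxy[j + 1] - sxy[i]
    sum_x = (i + j) * length / 2.0
    # consecutive integer abscissae: Sxx has the exact closed form
    sxx = length * (float(length) ** 2 - 1.0) / 12.0
    sxy_c = sum_xy - sum_x * sum_y / length
    syy = sum_y2 - sum_y * sum_y / length
    if sxx > 0:
        rss = syy - sxy_c * sxy_c / sxx
    else:
        rss = syy
    return np.sqrt(np.maximum(rss, 0.0) / length)


def _scan_length(
    s1, s2, sxy, sd, length: int, n: int, rmse_max: float, diff_cap: float,
    starts: np.ndarray | None = None,
):
    """Best feasible window of a given length, or None.

    Feasible: OLS rmse <= rmse_max AND mean smoothed first-difference over
    the window <= diff_cap.  Ties on rmse resolve to the smallest start.
    """
    if starts is None:
        starts = np.arange(0, n - length + 1)
    if len(starts) == 0:
        return None
    rmse = _window_rmse(s1, s2, sxy, starts, length)
    # window [i, j] spans diffs i .. j-1
    mean_sd = (sd[starts + length - 1] - sd[starts]) / (length - 1)
    ok = (rmse <= rmse_max) & (mean_sd <= diff_cap)
    if not ok.any():
        return None
    idx = np.flatnonzero(ok)
    best = idx[np.argmin(rmse[idx])]  # argmin takes first occurrence: min start
    return int(best), float(rmse[best])


def detect_plateau_auto(
    curve: ENormsCurve,
    rmse_tolerance: float = 0.005,
    min_size: int | None = None,
) -> Plateau:
    """Find the plateau as the longest tolerably-linear low-derivative window.

    Operationalizes tangent fitting as: the longest contiguous rank window
    whose least-squares line has root-mean-square residual at most
    ``rmse_tolerance`` times the curve's total value range, restricted to
    windows whose mean smoothed first-difference does not exceed the
    curve-wide median (the "interval of lowest first-order derivatives").
    Length ties break to smaller rmse, then to the leftmost window.

    Parameters
    ----------
    rmse_tolerance : float
        Linearity tolerance as a fraction of the value range (default 0.005,
        i.e. 0.5%).  Must be > 0 in a meaningful run; 0 demands an exact line.
    min_size : int, optional
        Smallest admissible plateau; defaults to ``max(30, 0.1 * n)``.

    Raises
    ------
    NoPlateauError
        If no window of at least ``min_size`` ranks satisfies the tolerance.
    """
    if rmse_tolerance < 0:
        raise ContractError("rmse_tolerance must be >= 0")
    n = curve.n
    if min_size is None:
        min_size = default_min_size(n)
    if min_size < 10:
        raise ContractError(f"min_size must be >= 10, got {min_size}")
    min_size = max(min_size, 2)
    if min_size > n:
        raise NoPlateauError(f"min_size {min_size} exceeds sample size {n}")

    rmse_max = rmse_tolerance * curve.value_range
    # tie tolerance: an exactly-constant diff series rounds to ulp-level
    # jitter, so the window mean may exceed the median by ~1e-15 relative
    med = float(np.median(curve.smoothed_diffs))
    diff_cap = med + 1e-9 * max(abs(med), float(np.mean(curve.smoothed_diffs)))
    s1, s2, sxy, sd = _window_stats(curve.values, curve.smoothed_diffs)

    if n <= EXACT_SCAN_MAX_N:
        for length in range(n, min_size - 1, -1):
            hit = _scan_length(s1, s2, sxy, sd, length, n, rmse_max, diff_cap)
            if hit is not None:
                i, _ = hit
                return Plateau(i + 1, i + length, provenance="auto")
        raise NoPlateauError(
            f"no window of >= {min_size} ranks has rmse <= {rmse_max:.6g}"
        )

    # stride-then-refine: coarse scan on a stride grid, then exact search in
    # the neighbourhood of the first coarse hit
    stride = max(1, n // 2000)
    coarse_hit = None
    for length in range(n, min_size - 1, -stride):
        starts = np.arange(0, n - length + 1, stride)
        hit = _scan_length(
            s1, s2, sxy, sd, length, n, rmse_max, diff_cap, starts=starts
        )
        if hit is not None:
            coarse_hit = length
            break
    if coarse_hit is None:
        raise NoPlateauError(
            f"no window of >= {min_size} ranks has rmse <= {rmse_max:.6g}"
        )
    hi = min(n, coarse_hit + 2 * stride)
    for length in range(hi, min_size - 1, -1):
        hit = _scan_length(s1, s2, sxy, sd, length, n, rmse_max, diff_cap)
        if hit is not None:
            i, _ = hit
            return Plateau(i + 1, i + length, provenance="auto")
    raise NoPlateauError("stride scan found no refinable plateau")  # pragma: no cover


def fit_tangent(curve: ENormsCurve, start_rank: int, end_rank: int) -> TangentFit:
    """OLS line of value on rank restricted to [start_rank, end_rank]."""
    if not (1 <= start_rank <= end_rank <= curve.n):
        raise ContractError(
            f"window ({start_rank}, {end_rank}) out of bounds for n={curve.n}"
        )
    if end_rank - start_rank + 1 < 2:
        raise ContractError("tangent window must span at least 2 ranks")
    r = curve.ranks[start_rank - 1 : end_rank].astype(float)
    v = curve.values[start_rank - 1 : end_rank]
    slope, intercept = np.polyfit(r, v, 1)
    resid = v - (slope * r + intercept)
    return TangentFit(
        slope=float(slope),
        intercept=float(intercept),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reconcile(
    a: RaterMarks, b: RaterMarks, size_threshold: float = 0.10
) -> Plateau | ThirdRaterNeeded:
    """Merge two blinded raters' marks, or escalate.

    When the relative plateau-size difference, ``|size_a - size_b|`` over the
    mean size, is strictly below ``size_threshold`` (default 10%), the
    coordinates are averaged (round half-up) into a reconciled plateau.
    Otherwise a :class:`ThirdRaterNeeded` signal carries both marks.
    """
    if a.curve_id != b.curve_id:
        raise ProtocolError(
            f"marks refer to different curves: {a.curve_id!r} vs {b.curve_id!r}"
        )
    rel = abs(a.size - b.size) / ((a.size + b.size) / 2.0)
    if rel < size_threshold:
        return Plateau(
            start_rank=_round_half_up((a.start_rank + b.start_rank) / 2.0),
            end_rank=_round_half_up((a.end_rank + b.end_rank) / 2.0),
            provenance="reconciled",
        )
    return ThirdRaterNeeded(a=a, b=b, relative_size_difference=rel)


def resolve_third(a: RaterMarks, b: RaterMarks, choice: str) -> Plateau:
    """Third blinded rater picks whichever mark best adheres to the method."""
    if choice == a.rater_id:
        chosen = a
    elif choice == b.rater_id:
        chosen = b
    else:
        raise ProtocolError(
            f"choice {choice!r} names neither rater "
            f"({a.rater_id!r}, {b.rater_id!r})"
        )
    return Plateau(chosen.start_rank, chosen.end_rank, provenance="third_rater")


def plateau_values(curve: ENormsCurve, p: Plateau) -> np.ndarray:
    """Extract the sorted values inside the plateau (inclusive bounds)."""
    if not (1 <= p.start_rank and p.end_rank <= curve.n):
        raise ContractError(
            f"plateau ({p.start_rank}, {p.end_rank}) out of bounds for n={curve.n}"
        )
    return curve.values[p.start_rank - 1 : p.end_rank]


def read_ratings(path) -> list[RaterMarks]:
    """Load rater marks from a CSV with columns
    rater_id, curve_id, start_rank, end_rank (1-based, inclusive)."""
    df = pd.read_csv(path, dtype={"rater_id": str, "curve_id": str})
    required = {"rater_id", "curve_id", "start_rank", "end_rank"}
    missing = required - set(df.columns)
    if missing:
        raise ProtocolError(f"ratings file missing columns: {sorted(missing)}")
    return [
        RaterMarks(
            rater_id=row.rater_id,
            curve_id=row.curve_id,
            start_rank=int(row.start_rank),
            end_rank=int(row.end_rank),
        )
        for row in df.itertuples(index=False)
    ]


def write_ratings(marks: list[RaterMarks], path) -> None:
    pd.DataFrame([m.__dict__ for m in marks]).to_csv(Path(path), index=False)
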