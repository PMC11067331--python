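"""Comparison statistics between two sets of reference limits.

Mock real-world comparison of indirectly and traditionally derived limits:
classify every reading in the mixed historical dataset against each limit,
report the percentage abnormal per measure, form per-measure abnormality
ratios (% abnormal indirect / % abnormal traditional), summarize the ratios
by their geometric mean (log-transform, average, exponentiate), and compute
reading-level percentage agreement between the two classifications.

A published lower-limb nerve-conduction comparison table (per-measure n,
median, IQR, limit and % abnormal for both methods, three age strata) ships
with the package for "table mode" runs; :func:`load_published_comparison`
returns it as a DataFrame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, EmptyInputError, UndefinedRatioError
from .limits import ReferenceLimit

__all__ = [
    "AbnormalityResult",
    "RatioSummary",
    "ComparisonReport",
    "classify_abnormal",
    "abnormal_mask",
    "abnormality_ratio",
    "summarize_ratios",
    "percentage_agreement",
    "load_published_comparison",
    "compare_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbnormalityResult:
    """Abnormal-classification outcome of one limit on one value set."""

    n: int
    n_abnormal: int
    limit: ReferenceLimit
    measure: str | None = None

    @property
    def pct_abnormal(self) -> float:
        return 100.0 * self.n_abnormal / self.n


@dataclass(frozen=True)
class RatioSummary:
    geometric_mean: float
    min: float
    max: float
    n_ratios: int


@dataclass(frozen=True)
class ComparisonReport:
    """Per-measure percentage pairs with ratio summary and agreement."""

    measures: list[str]
    pct_enorms: list[float]
    pct_traditional: list[float]
    ratios: list[float]
    excluded: list[str]  # measures with traditional % = 0, dropped from ratios
    summary: RatioSummary
    mean_agreement: float | None = None
    per_measure_agreement: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "measures": self.measures,
            "pct_enorms": self.pct_enorms,
            "pct_traditional": self.pct_traditional,
            "ratios": self.ratios,
            "excluded": self.excluded,
            "ratio_geometric_mean": self.summary.geometric_mean,
            "ratio_min": self.summary.min,
            "ratio_max": self.summary.max,
            "mean_agreement": self.mean_agreement,
        }


def abnormal_mask(values: Sequence[float], limit: ReferenceLimit) -> np.ndarray:
    """Boolean abnormal flags: strictly beyond the limit on its pathological
    side (a value exactly equal to the limit is normal)."""
    v = np.asarray(values, dtype=float)
    return v < limit.limit if limit.direction == "low" else v > limit.limit


def classify_abnormal(
    values: Sequence[float], limit: ReferenceLimit, measure: str | None = None
) -> AbnormalityResult:
    """Count readings abnormal under a one-sided reference limit."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise EmptyInputError("cannot compute % abnormal of an empty value set")
    mask = abnormal_mask(v, limit)
    return AbnormalityResult(
        n=len(v),
        n_abnormal=int(mask.sum()),
        limit=limit,
        measure=measure or limit.measure,
    )


def abnormality_ratio(pct_enorms: float, pct_traditional: float) -> float:
    """Per-measure abnormality ratio: % abnormal indirect / % traditional."""
    if pct_traditional <= 0:
        raise UndefinedRatioError(
            "abnormality ratio undefined: traditional % abnormal is zero"
        )
    return pct_enorms / pct_traditional


def summarize_ratios(ratios: Sequence[float]) -> RatioSummary:
    """Geometric mean (exp of the mean log-ratio) with min and max."""
    r = np.asarray(ratios, dtype=float)
    if len(r) == 0:
        raise EmptyInputError("no ratios to summarize")
    if np.any(r <= 0):
        raise ContractError("all ratios must be > 0 for the geometric mean")
    return RatioSummary(
        geometric_mean=float(np.exp(np.mean(np.log(r)))),
        min=float(r.min()),
        max=float(r.max()),
        n_ratios=len(r),
    )


def percentage_agreement(
    class_a: Sequence[bool], class_b: Sequence[bool]
) -> float:
    """Reading-level classification concordance between two limits, in %."""
    a = np.asarray(class_a, dtype=bool)
    b = np.asarray(class_b, dtype=bool)
    if a.shape != b.shape:
        raise ContractError(
            f"classification vectors differ in length: {a.shape} vs {b.shape}"
        )
    if a.size == 0:
        raise EmptyInputError("cannot compute agreement on empty classifications")
    return 100.0 * float(np.mean(a == b))


def load_published_comparison() -> pd.DataFrame:
    """The shipped published comparison table (lower-limb NCS measures,
    three age strata, both methods' printed n/median/IQR/limit/% abnormal)."""
    with resources.files("enorms.data").joinpath(
        "published_comparison.csv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def compare_table(
    table: pd.DataFrame,
    pct_enorms_col: str = "pct_abnormal_enorms",
    pct_traditional_col: str = "pct_abnormal_traditional",
) -> ComparisonReport:
    """Ratio summary over a table of per-measure % abnormal pairs.

    Rows whose traditional percentage is zero have an undefined ratio and are
    excluded from the summary (logged, and listed in ``excluded``).
    """
    for col in (pct_enorms_col, pct_traditional_col):
        if col not in table.columns:
            raise ContractError(f"comparison table missing column {col!r}")
    measures, pe, pt, ratios, excluded = [], [], [], [], []
    for _, row in table.iterrows():
        label = "/".join(
            str(row[c]) for c in ("group", "nerve", "measure_kind") if c in row
        ) or f"row{_}"
        e, t = float(row[pct_enorms_col]), float(row[pct_traditional_col])
        measures.append(label)
        pe.append(e)
        pt.append(t)
        try:
            ratios.append(abnormality_ratio(e, t))
        except UndefinedRatioError:
            logger.info("excluding %s from ratio summary (traditional %% = 0)", label)
            excluded.append(label)
    return ComparisonReport(
        measures=measures,
        pct_enorms=pe,
        pct_traditional=pt,
        ratios=ratios,
        excluded=excluded,
        summary=summarize_ratios(ratios),
    )
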