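"""End-to-end pipeline: mixed CSV in, reference-limit reports out.

Composes the full indirect workflow per (stratum, nerve, measure) group:
read -> exclude known controls -> stratify by age -> gate n > 100 -> build
curve -> plateau (automatic, or from a rater marks file) -> limits (k = 2
and 2.5, plus percentile limits when configured) -> classification of the
mixed data, and — when the input contains a control cohort — traditional
limits and the comparison statistics (abnormality ratios, agreement).

Every run writes its resolved configuration next to its outputs together
with a JSON-lines log, so a run can be re-executed bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__ as _pkg_version
from .compare import abnormal_mask, classify_abnormal, percentage_agreement
from .curve import build_curve
from .exceptions import ENormsError, InsufficientSampleError, NoPlateauError
from .io import (
    DEFAULT_STRATA,
    MEASURE_META,
    MeasurementTable,
    StratumSpec,
    exclude_subjects,
    read_table,
    require_min_n,
    stratify,
)
from .limits import choose_transform, percentile_limit, sd_limit
from .plateau import (
    Plateau,
    detect_plateau_auto,
    fit_tangent,
    plateau_values,
    read_ratings,
    reconcile,
)
from .synthetic import DEFAULT_SEED
from .viz import render_enorms_plot

__all__ = ["RunConfig", "GroupResult", "RunResult", "run_pipeline"]

logger = logging.getLogger(__name__)


class DetectorConfig(BaseModel):
    rmse_tolerance: float = 0.005
    min_size: int | None = None


class LimitConfig(BaseModel):
    method: str = "sd"  # sd | percentile
    k_values: list[float] = Field(default_factory=lambda: [2.0, 2.5])
    percentile: float = 1.0
    skew_threshold: float = 0.5


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    input_path: str
    column_map: dict[str, str] = Field(default_factory=dict)
    exclude_subject_ids: list[str] = Field(default_factory=list)
    strata: list[tuple[str, int, int]] = Field(
        default_factory=lambda: [("9-18", 9, 18), ("20-44", 20, 44), ("45-60", 45, 60)]
    )
    min_n: int = 100
    window_fraction: float = 0.001
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    limit: LimitConfig = Field(default_factory=LimitConfig)
    ratings_path: str | None = None  # rater marks CSV; None -> automatic detector
    dedupe: str = "none"  # first | last | none
    render_plots: bool = False
    hide_axes: bool = True
    out_dir: str = "enorms_out"
    seed: int = DEFAULT_SEED

    def stratum_spec(self) -> StratumSpec:
        return StratumSpec(tuple((l, lo, hi) for l, lo, hi in self.strata))


@dataclass
class GroupResult:
    stratum: str
    nerve: str
    measure_kind: str
    status: str  # ok | skipped:insufficient_n | error:<stage>
    detail: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "nerve": self.nerve,
            "measure_kind": self.measure_kind,
            "status": self.status,
            **self.detail,
        }


@dataclass
class RunResult:
    config: RunConfig
    groups: list[GroupResult]
    load_report: dict
    rows_excluded: int
    rows_outside_strata: int

    def to_dict(self) -> dict:
        return {
            "version": _pkg_version,
            "config": self.config.model_dump(),
            "load_report": self.load_report,
            "rows_excluded": self.rows_excluded,
            "rows_outside_strata": self.rows_outside_strata,
            "groups": [g.to_dict() for g in self.groups],
        }


def _group_plateau(curve, config: RunConfig, curve_id: str, marks_by_curve):
    """Automatic detection, or reconciliation of two raters' marks."""
    if config.ratings_path is None:
        return detect_plateau_auto(
            curve,
            rmse_tolerance=config.detector.rmse_tolerance,
            min_size=config.detector.min_size,
        )
    marks = marks_by_curve.get(curve_id, [])
    if len(marks) < 2:
        raise ENormsError(
            f"ratings file has {len(marks)} mark(s) for curve {curve_id!r}; need 2"
        )
    merged = reconcile(marks[0], marks[1])
    if isinstance(merged, Plateau):
        return merged
    raise ENormsError(
        f"raters disagree on curve {curve_id!r} "
        f"(relative size difference {merged.relative_size_difference:.1%}); "
        "resolve with a third rater and re-run"
    )


def _derive_limits(extract, direction, config: RunConfig, measure):
    lc = config.limit
    out = []
    if lc.method in ("sd", "both"):
        tf = choose_transform(extract, skew_threshold=lc.skew_threshold)
        for k in lc.k_values:
            out.append(sd_limit(extract, k=k, direction=direction, transform=tf, measure=measure))
    if lc.method in ("percentile", "both"):
        out.append(percentile_limit(extract, p=lc.percentile, direction=direction, measure=measure))
    return out


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full workflow; group-level errors are recorded and the
    remaining groups still run."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_log.jsonl"
    log_fh = open(log_path, "w", encoding="utf-8")

    def log(stage: str, **kw):
        rec = {"stage": stage, **kw}
        log_fh.write(json.dumps(rec) + "\n")
        logger.info("%s %s", stage, kw)

    table = read_table(config.input_path, schema=config.column_map or None)
    table = table.dedupe(config.dedupe)
    log("load", **table.report.to_dict())

    table, n_excluded = exclude_subjects(table, set(config.exclude_subject_ids))
    log("exclude_subjects", rows_removed=n_excluded)

    historical = table.filter_cohort("historical")
    control = table.filter_cohort("control")

    strata, n_outside = stratify(historical, config.stratum_spec())
    control_strata, _ = stratify(control, config.stratum_spec())
    log("stratify", rows_outside_strata=n_outside)

    marks_by_curve: dict[str, list] = {}
    if config.ratings_path:
        for m in read_ratings(config.ratings_path):
            marks_by_curve.setdefault(m.curve_id, []).append(m)

    groups: list[GroupResult] = []
    rows = []
    for stratum_label, stratum_table in strata.items():
        for (nerve, kind), group in stratum_table.groups():
            coords = dict(stratum=stratum_label, nerve=nerve, measure_kind=kind)
            curve_id = f"{stratum_label}/{nerve}/{kind}"
            meta = MEASURE_META.get(kind)
            if meta is None:
                groups.append(GroupResult(**coords, status="error:unknown_measure"))
                log("unknown_measure", **coords)
                continue
            direction = meta.abnormal_direction
            try:
                require_min_n(group, config.min_n)
            except InsufficientSampleError as exc:
                groups.append(
                    GroupResult(
                        **coords,
                        status="skipped:insufficient_n",
                        detail={"n": exc.n, "min_n": exc.min_n},
                    )
                )
                log("skipped_insufficient_n", **coords, n=exc.n)
                continue
            try:
                values = group.df["value"].to_numpy(dtype=float)
                curve = build_curve(
                    values,
                    window_fraction=config.window_fraction,
                    meta={"curve_id": curve_id, "unit": meta.unit},
                )
                plat = _group_plateau(curve, config, curve_id, marks_by_curve)
                tangent = fit_tangent(curve, plat.start_rank, plat.end_rank)
                extract = plateau_values(curve, plat)
                lims = _derive_limits(extract, direction, config, curve_id)
                results = [classify_abnormal(values, lim) for lim in lims]
            except NoPlateauError as exc:
                groups.append(
                    GroupResult(**coords, status="error:no_plateau", detail={"message": str(exc)})
                )
                log("no_plateau", **coords, message=str(exc))
                continue
            except ENormsError as exc:
                groups.append(
                    GroupResult(**coords, status="error:pipeline", detail={"message": str(exc)})
                )
                log("group_error", **coords, message=str(exc))
                continue

            detail: dict[str, Any] = {
                "n": len(values),
                "plateau": plat.to_dict(),
                "tangent": tangent.to_dict(),
                "limits": [lim.to_dict() for lim in lims],
                "pct_abnormal": [res.pct_abnormal for res in results],
            }

            # comparison against a traditional limit when a matching control
            # group exists
            ctrl = control_strata.get(stratum_label)
            ctrl_values = (
                ctrl.values_for(nerve, kind) if ctrl is not None else []
            )
            if len(ctrl_values) >= 10:
                tf = choose_transform(ctrl_values, config.limit.skew_threshold)
                trad = sd_limit(ctrl_values, k=2.0, direction=direction, transform=tf, measure=curve_id)
                trad_res = classify_abnormal(values, trad)
                primary = results[0]
                detail["traditional"] = {
                    "limit": trad.to_dict(),
                    "pct_abnormal": trad_res.pct_abnormal,
                    "agreement": percentage_agreement(
                        abnormal_mask(values, lims[0]), abnormal_mask(values, trad)
                    ),
                    "abnormality_ratio": (
                        primary.pct_abnormal / trad_res.pct_abnormal
                        if trad_res.pct_abnormal > 0
                        else None
                    ),
                }

            if config.render_plots:
                plot_path = out_dir / f"{curve_id.replace('/', '_')}.svg"
                render_enorms_plot(
                    curve,
                    plot_path,
                    hide_axes=config.hide_axes,
                    markers=(plat.start_rank, plat.end_rank),
                )
                detail["plot"] = str(plot_path)

            groups.append(GroupResult(**coords, status="ok", detail=detail))
            log("group_ok", **coords, n=len(values))
            for lim, res in zip(lims, results):
                rows.append(
                    {
                        **coords,
                        "n": len(values),
                        "method": lim.method,
                        "k_or_p": lim.k,
                        "transform": lim.transform.kind,
                        "limit": lim.limit,
                        "pct_abnormal": res.pct_abnormal,
                    }
                )

    result = RunResult(
        config=config,
        groups=groups,
        load_report=table.report.to_dict(),
        rows_excluded=n_excluded,
        rows_outside_strata=n_outside,
    )
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    with open(out_dir / "resolved_config.json", "w", encoding="utf-8") as fh:
        json.dump({"version": _pkg_version, **config.model_dump()}, fh, indent=2)
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "limits.csv", index=False)
    log_fh.close()
    return result
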