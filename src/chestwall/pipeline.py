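"""End-to-end orchestration: simulate/ingest -> standardize -> sample ->
compare -> fit -> areas -> volumes -> distribution -> report.

The pipeline consumes either a point-set CSV (with a frames CSV supplying
per-subject anatomical origins) or a synthetic cohort configuration, and
produces per-plane comparison tables, mean-curve polynomial models, signed
areas, the volume estimate, and per-subject distribution summaries. Given a
seed and inputs the run is deterministic; the report JSON carries a config
hash and seed (no timestamp) so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cw_io
from .asymmetry_metrics import (
    AreaDistributionSummary,
    VolumeEstimate,
    prominence_summary,
    round_half_up,
)
from .curve_geometry import (
    DEFAULT_SPAN_MM,
    CenterlinePointSet,
    Plane,
    SampledCurve,
    Side,
    StandardFrame,
    mean_curve,
    sample_projection,
    standardize,
)
from .curve_model import (
    AreaResult,
    PolynomialModel,
    fit_through_origin,
    integrate_difference,
    per_subject_area,
)
from .errors import ConfigError
from .pointwise_stats import CurveComparisonResult, compare_curve_sets
from .synthetic_cohort import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "AsymmetryReport", "run", "write_report"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one input source is used: ``pointset_csv`` (+ optional
    ``frames_csv``) or ``cohort``; with neither set, a default synthetic
    cohort is simulated. ``seed`` overrides the cohort seed when given.
    """

    pointset_csv: str | None = None
    frames_csv: str | None = None
    cohort: CohortConfig | None = None
    grid_spacing_mm: float = 10.0
    max_degree: int = 5
    df_convention: str = "paper_k_minus_1"
    multiplier_horizontal_mm: float = 100.0
    multiplier_vertical_mm: float = 120.0
    area_method: str = "polynomial"
    out_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pointset_csv is not None and self.cohort is not None:
            raise ConfigError("give either pointset_csv or cohort, not both")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        cohort = raw.pop("cohort", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        if cohort is not None:
            cfg.cohort = CohortConfig(**cohort)
        return cfg

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("cohort", "out_dir")
        }
        if self.cohort is not None:
            c = dataclasses.asdict(self.cohort)
            c["planes"] = [p.value for p in self.cohort.planes]
            c["templates"] = None if self.cohort.templates is None else "custom"
            d["cohort"] = c
        else:
            d["cohort"] = None
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class AsymmetryReport:
    """Full-precision results of one pipeline run."""

    n_subjects: int
    comparisons: dict[Plane, CurveComparisonResult]
    mean_models: dict[tuple[Plane, Side], PolynomialModel]
    mean_areas: dict[Plane, AreaResult]
    subject_areas: dict[Plane, list[AreaResult]]
    distributions: dict[Plane, AreaDistributionSummary]
    volume: VolumeEstimate | None
    warnings: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        planes = {}
        for plane, comp in self.comparisons.items():
            planes[plane.value] = {
                "n_left": comp.points[0].n_left,
                "n_right": comp.points[0].n_right,
                "omnibus": {
                    "sum_chisq": comp.sum_chisq,
                    "df": comp.omnibus_df,
                    "p": comp.omnibus_p,
                    "df_convention": comp.df_convention,
                    "n_included_points": comp.n_included,
                },
                "mean_models": {
                    side.value: self.mean_models[(plane, side)].to_dict()
                    for side in (Side.LEFT, Side.RIGHT)
                    if (plane, side) in self.mean_models
                },
                "mean_area_mm2": self.mean_areas[plane].area_mm2
                if plane in self.mean_areas
                else None,
                "distribution": self.distributions[plane].to_dict()
                if plane in self.distributions
                else None,
            }
        return {
            "n_subjects": self.n_subjects,
            "planes": planes,
            "volumes": self.volume.to_dict() if self.volume else None,
            "warnings": self.warnings,
            "provenance": self.provenance,
        }

    def summary_text(self) -> str:
        lines = [
            "Chest-wall asymmetry report",
            f"generated: {datetime.datetime.now().isoformat(timespec='seconds')}",
            f"subjects: {self.n_subjects}",
            "",
        ]
        for plane, comp in self.comparisons.items():
            lines.append(f"[{plane.value}]")
            lines.append(
                f"  omnibus sum of chi-square Q = {comp.sum_chisq:.2f} "
                f"(df = {comp.omnibus_df}, p = {comp.omnibus_p:.2e}, "
                f"{comp.df_convention})"
            )
            if plane in self.mean_areas:
                lines.append(
                    f"  mean left-minus-right area = "
                    f"{self.mean_areas[plane].area_mm2:.1f} mm^2"
                )
            if plane in self.distributions:
                d = self.distributions[plane]
                lines.append(
                    f"  left-dominant subjects: {d.n_positive}/{d.n} "
                    f"({100 * d.proportion_left_dominant:.0f}%)"
                )
                if d.skewness is not None:
                    p_txt = f", p_skew = {d.p_skew:.2f}" if d.p_skew is not None else ""
                    lines.append(f"  area skewness = {d.skewness:.2f}{p_txt}")
            lines.append("")
        if self.volume is not None:
            v = self.volume
            lines.append(
                "volume discrepancy estimate: "
                f"horizontal {round_half_up(v.volume_horizontal_cc):.1f} cc, "
                f"vertical {round_half_up(v.volume_vertical_cc):.1f} cc, "
                f"mean {round_half_up(v.volume_mean_cc):.1f} cc"
            )
        return "\n".join(lines) + "\n"


def _load_inputs(
    config: PipelineConfig,
) -> tuple[list[CenterlinePointSet], dict[tuple[str, Plane], StandardFrame]]:
    if config.pointset_csv is not None:
        pointsets = cw_io.read_pointsets(config.pointset_csv)
        frames = (
            cw_io.read_frames(config.frames_csv) if config.frames_csv else {}
        )
        return pointsets, frames
    cohort = config.cohort if config.cohort is not None else CohortConfig()
    if config.seed is not None:
        cohort = dataclasses.replace(cohort, seed=config.seed)
    subjects = generate_cohort(cohort)
    pointsets = [ps for s in subjects for ps in s.pointsets.values()]
    frames = {
        (s.subject_id, plane): frame
        for s in subjects
        for plane, frame in s.frames.items()
    }
    return pointsets, frames


def run(config: PipelineConfig) -> AsymmetryReport:
    """Execute the full analysis and (if configured) write all outputs."""
    warnings: list[str] = []
    pointsets, frames = _load_inputs(config)
    if not pointsets:
        raise ConfigError("no input centerlines")

    # standardize and sample
    curves: dict[tuple[Plane, Side], list[SampledCurve]] = {}
    for ps in pointsets:
        frame = frames.get(
            (ps.subject_id, ps.plane), StandardFrame(plane=ps.plane)
        )
        frame = dataclasses.replace(frame, grid_spacing_mm=config.grid_spacing_mm)
        std = standardize(ps, frame)
        curve = sample_projection(std, frame)
        curves.setdefault((ps.plane, ps.side), []).append(curve)

    subject_ids = sorted({c.subject_id for group in curves.values() for c in group})
    planes = sorted(
        {plane for (plane, _side) in curves},
        key=lambda p: (p is not Plane.HORIZONTAL),
    )

    comparisons: dict[Plane, CurveComparisonResult] = {}
    mean_models: dict[tuple[Plane, Side], PolynomialModel] = {}
    mean_areas: dict[Plane, AreaResult] = {}
    subject_areas: dict[Plane, list[AreaResult]] = {}
    distributions: dict[Plane, AreaDistributionSummary] = {}

    for plane in planes:
        left = curves.get((plane, Side.LEFT), [])
        right = curves.get((plane, Side.RIGHT), [])
        if len(left) < 2 or len(right) < 2:
            warnings.append(
                f"plane {plane.value}: fewer than 2 subjects per side, skipped"
            )
            continue
        comparisons[plane] = compare_curve_sets(left, right, config.df_convention)

        span = float(left[0].grid_mm[-1])
        for side, group in ((Side.LEFT, left), (Side.RIGHT, right)):
            mc = mean_curve(group, label="mean")
            mean_models[(plane, side)] = fit_through_origin(
                mc.grid_mm,
                mc.projection_mm,
                config.max_degree,
                plane,
                f"mean_{side.value}",
            )
        mean_areas[plane] = integrate_difference(
            mean_models[(plane, Side.LEFT)],
            mean_models[(plane, Side.RIGHT)],
            0.0,
            span,
        )

        by_subject_l = {c.subject_id: c for c in left}
        by_subject_r = {c.subject_id: c for c in right}
        areas = []
        for sid in sorted(set(by_subject_l) & set(by_subject_r)):
            areas.append(
                per_subject_area(
                    by_subject_l[sid],
                    by_subject_r[sid],
                    method=config.area_method,
                    max_degree=config.max_degree,
                )
            )
        subject_areas[plane] = areas
        if areas:
            distributions[plane] = prominence_summary([a.area_mm2 for a in areas])

    volume = None
    if Plane.HORIZONTAL in mean_areas and Plane.VERTICAL in mean_areas:
        volume = VolumeEstimate.from_areas(
            mean_areas[Plane.HORIZONTAL].area_mm2,
            mean_areas[Plane.VERTICAL].area_mm2,
            config.multiplier_horizontal_mm,
            config.multiplier_vertical_mm,
        )

    report = AsymmetryReport(
        n_subjects=len(subject_ids),
        comparisons=comparisons,
        mean_models=mean_models,
        mean_areas=mean_areas,
        subject_areas=subject_areas,
        distributions=distributions,
        volume=volume,
        warnings=warnings,
        provenance={"config_sha256": config.sha256(), "seed": config.seed},
    )

    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: AsymmetryReport, out_dir: str | Path) -> None:
    """Write comparison CSVs, model JSON, area CSV, report JSON and summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for plane, comp in report.comparisons.items():
        cw_io.write_csv_atomic(comp.to_frame(), out / f"comparison_{plane.value}.csv")
        cw_io.write_json_atomic(
            {
                "sum_chisq": comp.sum_chisq,
                "df": comp.omnibus_df,
                "p": comp.omnibus_p,
                "df_convention": comp.df_convention,
            },
            out / f"omnibus_{plane.value}.json",
        )
    cw_io.write_json_atomic(
        {f"{p.value}_{s.value}": m.to_dict() for (p, s), m in report.mean_models.items()},
        out / "models.json",
    )
    rows = []
    for plane, area in report.mean_areas.items():
        rows.append(("mean", plane.value, area.method, area.area_mm2))
    for plane, areas in report.subject_areas.items():
        for a in areas:
            rows.append((a.subject_id, plane.value, a.method, a.area_mm2))
    cw_io.write_csv_atomic(
        pd.DataFrame(rows, columns=["subject_id", "plane", "method", "area_mm2"]),
        out / "areas.csv",
    )
    cw_io.write_json_atomic(report.to_dict(), out / "report.json")
    cw_io._atomic_write(out / "summary.txt", lambda fh: fh.write(report.summary_text()))
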