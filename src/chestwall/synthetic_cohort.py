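"""Synthetic cohorts of left/right chest-wall curves.

No scan data ship with this package; instead, cohorts are simulated with the
statistical structure of the reference cohort tables. For each subject and
side the grid-level curve is

    curve = side mean + smooth zero-mean Gaussian deformation,

where the side means come from monotone piecewise-cubic (PCHIP) templates
through the reference right-side means and left-minus-right offsets, and the
deformation has the reference per-side pointwise SDs with squared-exponential
correlation along the grid (correlation length 30 mm by default — a
rib-scale smoothness the reference tables cannot constrain, needed for
realistic centerlines). Left and right deformations are independent by
default, matching the unpaired df = 98 of the reference comparison; a
within-subject correlation knob is provided for sensitivity work.

Curves are emitted both as exact grid samples (ground truth) and as dense 3D
centerlines (2-mm spacing) in a randomly translated scanner frame whose
fixed axis is quantized to the 3-mm slice thickness, so the full pipeline
(standardize -> sample -> compare -> fit -> report) can run end to end.

Template anchoring: the horizontal origin is fixed at zero for both sides
(the standardized curves pass through it by construction), so its SD is zero
even though the reference table prints a nonzero right-side SD there; the
vertical origin is anchored on the right side only, as printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import reference_tables
from .curve_geometry import (
    DEFAULT_SPAN_MM,
    GRID_SPACING_MM,
    CenterlinePointSet,
    Plane,
    SampledCurve,
    Side,
    StandardFrame,
    quarter_width_offset,
)
from .errors import ConfigError

__all__ = [
    "PlaneTemplate",
    "CohortConfig",
    "SyntheticSubject",
    "table_template",
    "generate_cohort",
    "draw_grid_curves",
    "cohort_to_pointsets",
    "frames_table",
    "truth_table",
    "curves_from_matrices",
]


@dataclass(frozen=True)
class PlaneTemplate:
    """Mean/offset/SD fields for one plane, as callables of distance (mm)."""

    mean_template: Callable[[np.ndarray], np.ndarray]
    offset_field: Callable[[np.ndarray], np.ndarray]
    sd_field: Callable[[Side, np.ndarray], np.ndarray]


def table_template(plane: Plane | str) -> PlaneTemplate:
    """Reference-table template: PCHIP interpolants through the printed
    right-side means, left-minus-right offsets, and per-side SDs."""
    plane = Plane(plane)
    df = reference_tables.comparison_table(plane)
    s = df["s_mm"].to_numpy()
    sd_l = df["sd_left"].to_numpy().copy()
    sd_r = df["sd_right"].to_numpy().copy()
    if plane is Plane.HORIZONTAL:
        sd_l[0] = 0.0
        sd_r[0] = 0.0  # anchored origin; printed 1.24 is not usable here
    mean_i = PchipInterpolator(s, df["mean_right"].to_numpy())
    offset_i = PchipInterpolator(s, df["diff"].to_numpy())
    sd_i = {Side.LEFT: PchipInterpolator(s, sd_l), Side.RIGHT: PchipInterpolator(s, sd_r)}

    def sd_field(side: Side, x: np.ndarray) -> np.ndarray:
        return np.maximum(sd_i[Side(side)](x), 0.0)

    return PlaneTemplate(
        mean_template=lambda x: np.asarray(mean_i(x), dtype=float),
        offset_field=lambda x: np.asarray(offset_i(x), dtype=float),
        sd_field=sd_field,
    )


@dataclass
class CohortConfig:
    """Conditions for a synthetic cohort.

    Defaults emulate the reference study: 50 subjects, both planes,
    reference-table mean/offset/SD fields, 30-mm deformation correlation
    length, 3-mm slice quantization, independent left/right deformations,
    and a thorax-width distribution with mean 234 mm.
    """

    n_subjects: int = 50
    planes: tuple[Plane, ...] = (Plane.HORIZONTAL, Plane.VERTICAL)
    templates: dict[Plane, PlaneTemplate] | None = None
    smoothness_mm: float = 30.0
    slice_thickness_mm: float = 3.0
    within_subject_correlation: float = 0.0
    centerline_spacing_mm: float = 2.0
    include_centerlines: bool = True
    thorax_width_mean_mm: float = reference_tables.MEAN_CHEST_WIDTH_MM
    thorax_width_sd_mm: float = 17.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.planes = tuple(Plane(p) for p in self.planes)
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.smoothness_mm <= 0:
            raise ConfigError("smoothness_mm (correlation length) must be > 0")
        if self.slice_thickness_mm <= 0:
            raise ConfigError("slice_thickness_mm must be > 0")
        if not 0.0 <= self.within_subject_correlation <= 1.0:
            raise ConfigError("within_subject_correlation must be in [0, 1]")
        if self.centerline_spacing_mm <= 0:
            raise ConfigError("centerline_spacing_mm must be > 0")

    def template(self, plane: Plane) -> PlaneTemplate:
        if self.templates is not None and plane in self.templates:
            return self.templates[plane]
        return table_template(plane)


@dataclass
class SyntheticSubject:
    """One simulated subject: scanner-frame centerlines plus ground truth."""

    subject_id: str
    thorax_width_mm: float
    translation: np.ndarray
    pointsets: dict[tuple[Plane, Side], CenterlinePointSet]
    truth: dict[tuple[Plane, Side], SampledCurve]
    frames: dict[Plane, StandardFrame]


def _correlation_cholesky(grid: np.ndarray, length_mm: float) -> np.ndarray:
    d2 = (grid[:, None] - grid[None, :]) ** 2
    with np.errstate(under="ignore"):
        c = np.exp(-d2 / (2.0 * length_mm**2))
    c[np.diag_indices_from(c)] += 1e-10
    return np.linalg.cholesky(c)


def draw_grid_curves(
    config: CohortConfig, plane: Plane | str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw all subjects' grid curves for one plane, vectorized.

    Returns (grid, left, right) with left/right of shape (n_subjects, k).
    Consumes exactly three (n, k) standard-normal blocks from ``rng`` (shared,
    left, right) regardless of the correlation setting, so streams stay
    aligned across configurations.
    """
    plane = Plane(plane)
    tmpl = config.template(plane)
    span = DEFAULT_SPAN_MM[plane]
    k = int(round(span / GRID_SPACING_MM)) + 1
    grid = np.arange(k) * GRID_SPACING_MM

    mean_r = tmpl.mean_template(grid)
    offset = tmpl.offset_field(grid)
    sd_l = tmpl.sd_field(Side.LEFT, grid)
    sd_r = tmpl.sd_field(Side.RIGHT, grid)
    chol = _correlation_cholesky(grid, config.smoothness_mm)

    n = config.n_subjects
    z_shared = rng.standard_normal((n, k))
    z_left = rng.standard_normal((n, k))
    z_right = rng.standard_normal((n, k))
    rho = config.within_subject_correlation
    zl = np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * z_left
    zr = np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * z_right

    left = mean_r + offset + (zl @ chol.T) * sd_l
    right = mean_r + (zr @ chol.T) * sd_r
    return grid, left, right


def _quantize(value: float, step: float) -> float:
    return float(step * np.round(value / step))


def _dense_centerline(
    grid: np.ndarray, values: np.ndarray, span: float, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Densify a grid curve with a PCHIP interpolant that passes through the
    grid nodes exactly (the dense abscissa includes every grid node)."""
    dense = np.unique(np.concatenate([np.arange(0.0, span + 1e-9, spacing), grid]))
    interp = PchipInterpolator(grid, values)
    y = np.asarray(interp(dense), dtype=float)
    # exact node values, bit for bit
    idx = np.searchsorted(dense, grid)
    y[idx] = values
    return dense, y


def generate_cohort(config: CohortConfig) -> list[SyntheticSubject]:
    """Generate a fully reproducible synthetic cohort from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    per_plane: dict[Plane, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for plane in config.planes:
        per_plane[plane] = draw_grid_curves(config, plane, rng)

    translations = rng.uniform(-200.0, 200.0, size=(n, 3))
    widths = rng.normal(config.thorax_width_mean_mm, config.thorax_width_sd_mm, size=n)
    axial_levels = rng.uniform(-60.0, 60.0, size=n)

    subjects: list[SyntheticSubject] = []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        t = translations[i]
        pointsets: dict[tuple[Plane, Side], CenterlinePointSet] = {}
        truth: dict[tuple[Plane, Side], SampledCurve] = {}
        frames: dict[Plane, StandardFrame] = {}
        for plane in config.planes:
            grid, left, right = per_plane[plane]
            span = float(grid[-1])
            if plane is Plane.HORIZONTAL:
                level = _quantize(axial_levels[i], config.slice_thickness_mm)
            else:
                level = _quantize(
                    quarter_width_offset(widths[i]), config.slice_thickness_mm
                )
            ia, ip, ifx = StandardFrame(plane=plane).axis_indices
            origin = np.array(t, dtype=float)
            origin[ifx] += level
            frames[plane] = StandardFrame(plane=plane, origin=tuple(origin))
            for side, values in ((Side.LEFT, left[i]), (Side.RIGHT, right[i])):
                truth[(plane, side)] = SampledCurve(sid, side, plane, grid, values)
                if config.include_centerlines:
                    dense, y = _dense_centerline(
                        grid, values, span, config.centerline_spacing_mm
                    )
                    pts = np.empty((dense.size, 3))
                    pts[:, ia] = t[ia] + dense
                    pts[:, ip] = t[ip] + y
                    pts[:, ifx] = t[ifx] + level
                    pointsets[(plane, side)] = CenterlinePointSet(sid, side, plane, pts)
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                thorax_width_mm=float(widths[i]),
                translation=np.array(t, dtype=float),
                pointsets=pointsets,
                truth=truth,
                frames=frames,
            )
        )
    return subjects


_SIDE_CODE = {Side.LEFT: "L", Side.RIGHT: "R"}


def cohort_to_pointsets(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    """Flatten a cohort's centerlines into the point-set CSV schema."""
    rows = []
    for subj in subjects:
        for (plane, side), ps in subj.pointsets.items():
            for idx, (x, y, z) in enumerate(ps.points):
                rows.append(
                    (subj.subject_id, _SIDE_CODE[side], plane.value, idx, x, y, z)
                )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "side", "plane", "point_index", "x_mm", "y_mm", "z_mm"],
    )


def frames_table(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    """Per-subject standard-frame origins (the anatomical landmarks that a
    real analysis would supply alongside the exported centerlines)."""
    rows = []
    for subj in subjects:
        for plane, frame in subj.frames.items():
            rows.append((subj.subject_id, plane.value, *frame.origin))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "plane", "origin_x_mm", "origin_y_mm", "origin_z_mm"],
    )


def truth_table(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    """Ground-truth grid curves in the sampled-curve CSV schema."""
    rows = []
    for subj in subjects:
        for (plane, side), curve in subj.truth.items():
            for s, y in zip(curve.grid_mm, curve.projection_mm):
                rows.append((subj.subject_id, _SIDE_CODE[side], plane.value, s, y))
    return pd.DataFrame(
        rows, columns=["subject_id", "side", "plane", "s_mm", "projection_mm"]
    )


def curves_from_matrices(
    grid: np.ndarray, matrix: np.ndarray, side: Side, plane: Plane
) -> list[SampledCurve]:
    """Wrap an (n, k) grid-curve matrix into SampledCurve objects."""
    return [
        SampledCurve(f"S{i + 1:03d}", side, plane, grid, row)
        for i, row in enumerate(matrix)
    ]
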