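"""Standardized frames, centerline standardization, and fixed-grid sampling.

A chest-wall centerline is an ordered sequence of 3D points (millimeters)
exported from CT segmentation in an arbitrary scanner frame. Analysis happens
in one of two standardized Cartesian frames:

* horizontal plane — abscissa is lateral distance from the sternal origin
  (the anterior median line at the fourth-rib insertion), the anterior
  projection is the dependent value, and the axial slice level is held fixed;
  the grid spans 0-100 mm.
* vertical plane — abscissa is inferior distance from the superior edge of
  the manubrium along a parasagittal section at one quarter of the thorax
  width; the grid spans 0-120 mm.

Conventions: right-handed axes, millimeters, +projection = anterior, abscissa
zero at the anatomical origin. Anterior projections are sampled at 10-mm
intervals (grid endpoints inclusive) by linear interpolation — no smoothing
is applied before the pointwise statistics; smoothing happens later in the
polynomial fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import CoverageError, FrameViolationError, OrderingError

__all__ = [
    "Side",
    "Plane",
    "CenterlinePointSet",
    "StandardFrame",
    "SampledCurve",
    "DEFAULT_SPAN_MM",
    "GRID_SPACING_MM",
    "standardize",
    "sample_projection",
    "mean_curve",
    "quarter_width_offset",
]


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Plane(str, Enum):
    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"


#: Grid span per plane, mm (grids include both endpoints).
DEFAULT_SPAN_MM = {Plane.HORIZONTAL: 100.0, Plane.VERTICAL: 120.0}

#: Sampling interval, mm (1 cm).
GRID_SPACING_MM = 10.0

# Axis indices (abscissa, projection, fixed) per plane. The projection axis
# is y in both planes; the horizontal curve lives on a static z (axial slice),
# the vertical curve on a static x (parasagittal offset).
_PLANE_AXES = {
    Plane.HORIZONTAL: (0, 1, 2),
    Plane.VERTICAL: (2, 1, 0),
}

_AXIS_LABELS = "xyz"


def quarter_width_offset(thorax_width_mm: float) -> float:
    """Parasagittal offset of the vertical analysis plane: one quarter of the
    thorax width measured at the fourth-rib insertion."""
    return float(thorax_width_mm) / 4.0


@dataclass
class CenterlinePointSet:
    """Ordered 3D centerline for one subject/side/plane.

    ``points`` is an (n, 3) float array in millimeters, either in the scanner
    frame or (after :func:`standardize`) in the plane's standard frame.
    """

    subject_id: str
    side: Side
    plane: Plane
    points: np.ndarray

    def __post_init__(self) -> None:
        self.side = Side(self.side)
        self.plane = Plane(self.plane)
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if pts.shape[0] < 2:
            raise ValueError("a centerline needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("all coordinates must be finite")
        self.points = pts


@dataclass(frozen=True)
class StandardFrame:
    """Standardized analysis frame for one plane.

    ``origin`` is the anatomical origin expressed in the source (scanner)
    frame; standardization translates it to (0, 0, 0). The fixed axis must be
    constant along the curve to within ``fixed_axis_tol_mm`` (default half of
    the 3-mm axial slice thickness).
    """

    plane: Plane
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    span_mm: float | None = None
    grid_spacing_mm: float = GRID_SPACING_MM
    fixed_axis_tol_mm: float = 1.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "plane", Plane(self.plane))
        span = self.span_mm if self.span_mm is not None else DEFAULT_SPAN_MM[self.plane]
        if span <= 0 or self.grid_spacing_mm <= 0:
            raise ValueError("span and grid spacing must be positive")
        n = span / self.grid_spacing_mm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("span_mm must be divisible by grid_spacing_mm")
        object.__setattr__(self, "span_mm", float(span))
        object.__setattr__(self, "origin", tuple(float(c) for c in self.origin))

    @property
    def abscissa_axis(self) -> str:
        return _AXIS_LABELS[_PLANE_AXES[self.plane][0]]

    @property
    def fixed_axis(self) -> str:
        return _AXIS_LABELS[_PLANE_AXES[self.plane][2]]

    @property
    def axis_indices(self) -> tuple[int, int, int]:
        """(abscissa, projection, fixed) axis indices."""
        return _PLANE_AXES[self.plane]

    @property
    def grid_mm(self) -> np.ndarray:
        k = int(round(self.span_mm / self.grid_spacing_mm))
        return np.arange(k + 1) * self.grid_spacing_mm


@dataclass
class SampledCurve:
    """Anterior projection values on the fixed 10-mm grid."""

    subject_id: str
    side: Side
    plane: Plane
    grid_mm: np.ndarray
    projection_mm: np.ndarray

    def __post_init__(self) -> None:
        self.side = Side(self.side)
        self.plane = Plane(self.plane)
        self.grid_mm = np.asarray(self.grid_mm, dtype=float)
        self.projection_mm = np.asarray(self.projection_mm, dtype=float)
        if self.grid_mm.shape != self.projection_mm.shape or self.grid_mm.ndim != 1:
            raise ValueError("grid and projection must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.projection_mm)):
            raise ValueError("projection values must be finite")
        if np.any(np.diff(self.grid_mm) <= 0):
            raise ValueError("grid must be strictly increasing")


def standardize(points: CenterlinePointSet, frame: StandardFrame) -> CenterlinePointSet:
    """Express a centerline in the plane's standard frame.

    Translates so ``frame.origin`` maps to the origin, orients the abscissa so
    it increases along the ordered curve (flipping its sign if the curve was
    traced in the decreasing direction), re-sorts by abscissa and averages
    exact duplicate abscissa values. The anterior projection axis is assumed
    already signed +anterior.

    Raises
    ------
    FrameViolationError
        if the fixed-axis spread exceeds ``frame.fixed_axis_tol_mm``.
    OrderingError
        if fewer than two distinct abscissa values remain.
    """
    ia, ip, ifx = frame.axis_indices
    pts = points.points - np.asarray(frame.origin, dtype=float)

    spread = float(np.ptp(pts[:, ifx]))
    if spread > frame.fixed_axis_tol_mm:
        raise FrameViolationError(
            f"fixed axis {frame.fixed_axis!r} spread {spread:.3f} mm exceeds "
            f"tolerance {frame.fixed_axis_tol_mm} mm for subject "
            f"{points.subject_id!r} ({points.side.value}/{points.plane.value})"
        )

    # Orient the abscissa along the traced direction.
    if pts[-1, ia] < pts[0, ia]:
        pts[:, ia] = -pts[:, ia]

    order = np.argsort(pts[:, ia], kind="stable")
    pts = pts[order]

    # Average exact duplicate abscissa values.
    a = pts[:, ia]
    uniq, inverse, counts = np.unique(a, return_inverse=True, return_counts=True)
    if uniq.size < 2:
        raise OrderingError(
            f"degenerate centerline: fewer than 2 distinct abscissa values for "
            f"subject {points.subject_id!r}"
        )
    if uniq.size != a.size:
        summed = np.zeros((uniq.size, 3))
        np.add.at(summed, inverse, pts)
        pts = summed / counts[:, None]
        pts[:, ia] = uniq

    return CenterlinePointSet(points.subject_id, points.side, points.plane, pts)


def sample_projection(points: CenterlinePointSet, frame: StandardFrame) -> SampledCurve:
    """Sample the anterior projection at the frame's 10-mm grid.

    Values are linearly interpolated between the two bracketing centerline
    points; where an input point sits exactly on a grid coordinate its value
    is used as-is.

    Raises
    ------
    CoverageError
        if the centerline's abscissa range does not cover [0, span].
    """
    ia, ip, _ = frame.axis_indices
    a = points.points[:, ia]
    y = points.points[:, ip]
    grid = frame.grid_mm

    eps = 1e-9
    lo, hi = float(a.min()), float(a.max())
    if lo > eps or hi < frame.span_mm - eps:
        missing = []
        if lo > eps:
            missing.append(f"[0, {lo:.3f})")
        if hi < frame.span_mm - eps:
            missing.append(f"({hi:.3f}, {frame.span_mm:g}]")
        raise CoverageError(
            f"centerline for subject {points.subject_id!r} "
            f"({points.side.value}/{points.plane.value}) covers [{lo:.3f}, {hi:.3f}] mm "
            f"but the grid requires [0, {frame.span_mm:g}] mm; missing {', '.join(missing)}"
        )

    proj = np.interp(grid, a, y)
    return SampledCurve(points.subject_id, points.side, points.plane, grid, proj)


def mean_curve(curves: Sequence[SampledCurve], label: str = "mean") -> SampledCurve:
    """Pointwise mean of sampled curves sharing one plane/side/grid."""
    if not curves:
        raise ValueError("need at least one curve")
    plane, side, grid = curves[0].plane, curves[0].side, curves[0].grid_mm
    for c in curves[1:]:
        if c.plane != plane or not np.array_equal(c.grid_mm, grid):
            raise ValueError("curves must share one plane and grid")
    values = np.mean([c.projection_mm for c in curves], axis=0)
    return SampledCurve(label, side, plane, grid, values)
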