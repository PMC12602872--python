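"""CSV/JSON interchange: point sets, sampled curves, frames, and reports.

All writes are atomic (temp file in the target directory, then rename), so a
crashed run never leaves a truncated table behind. Reads validate schemas
strictly and report offending row numbers.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curve_geometry import CenterlinePointSet, Plane, SampledCurve, Side, StandardFrame
from .errors import SchemaError

__all__ = [
    "read_pointsets",
    "write_pointsets",
    "read_frames",
    "write_frames",
    "read_curves",
    "write_curves",
    "write_csv_atomic",
    "write_json_atomic",
]

POINTSET_COLUMNS = ["subject_id", "side", "plane", "point_index", "x_mm", "y_mm", "z_mm"]
CURVE_COLUMNS = ["subject_id", "side", "plane", "s_mm", "projection_mm"]
FRAME_COLUMNS = ["subject_id", "plane", "origin_x_mm", "origin_y_mm", "origin_z_mm"]

_SIDE_CODES = {"L": Side.LEFT, "R": Side.RIGHT,
               "left": Side.LEFT, "right": Side.RIGHT}


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv_atomic(df: pd.DataFrame, path: Path) -> None:
    _atomic_write(Path(path), lambda fh: df.to_csv(fh, index=False))


def write_json_atomic(obj, path: Path) -> None:
    _atomic_write(
        Path(path), lambda fh: json.dump(obj, fh, indent=2, sort_keys=True)
    )


def _read_table(path: Path, required: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{label} file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{label} file is empty: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{label} file {path} is missing required column(s): {', '.join(missing)}"
        )
    if len(df) == 0:
        raise SchemaError(f"{label} file has a header but no rows: {path}")
    return df


def _parse_sides(df: pd.DataFrame, path: Path) -> pd.Series:
    sides = df["side"].astype(str)
    bad = ~sides.isin(_SIDE_CODES)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise SchemaError(f"invalid side value(s) in {path} at row(s) {rows}")
    return sides.map(_SIDE_CODES)


def _parse_planes(df: pd.DataFrame, path: Path) -> pd.Series:
    planes = df["plane"].astype(str)
    valid = {p.value for p in Plane}
    bad = ~planes.isin(valid)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]
        raise SchemaError(f"invalid plane value(s) in {path} at row(s) {rows}")
    return planes.map(Plane)


def read_pointsets(path: Path) -> list[CenterlinePointSet]:
    """Read the point-set CSV into per-(subject, side, plane) centerlines.

    Rows within each group are ordered by ``point_index``. Mixed planes and
    sides in one file are accepted and grouped.
    """
    df = _read_table(path, POINTSET_COLUMNS, "point-set")
    coords = df[["x_mm", "y_mm", "z_mm"]].apply(pd.to_numeric, errors="coerce")
    bad = coords.isna().any(axis=1) | ~np.isfinite(coords).all(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]
        raise SchemaError(f"non-numeric or non-finite coordinates in {path} at row(s) {rows}")
    df = df.assign(side=_parse_sides(df, path), plane=_parse_planes(df, path))
    out: list[CenterlinePointSet] = []
    for (sid, side, plane), grp in df.groupby(
        ["subject_id", "side", "plane"], sort=True
    ):
        grp = grp.sort_values("point_index")
        pts = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        out.append(CenterlinePointSet(str(sid), side, plane, pts))
    return out


def write_pointsets(df: pd.DataFrame, path: Path) -> None:
    """Write a point-set table (columns as in ``POINTSET_COLUMNS``)."""
    missing = [c for c in POINTSET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"point-set frame missing column(s): {', '.join(missing)}")
    write_csv_atomic(df[POINTSET_COLUMNS], path)


def read_frames(path: Path) -> dict[tuple[str, Plane], StandardFrame]:
    """Read per-subject standard-frame origins keyed by (subject_id, plane)."""
    df = _read_table(path, FRAME_COLUMNS, "frames")
    df = df.assign(plane=_parse_planes(df, path))
    out: dict[tuple[str, Plane], StandardFrame] = {}
    for row in df.itertuples(index=False):
        out[(str(row.subject_id), row.plane)] = StandardFrame(
            plane=row.plane,
            origin=(float(row.origin_x_mm), float(row.origin_y_mm), float(row.origin_z_mm)),
        )
    return out


def write_frames(df: pd.DataFrame, path: Path) -> None:
    write_csv_atomic(df[FRAME_COLUMNS], path)


def read_curves(path: Path) -> list[SampledCurve]:
    """Read the sampled-curve CSV into SampledCurve objects."""
    df = _read_table(path, CURVE_COLUMNS, "sampled-curve")
    df = df.assign(side=_parse_sides(df, path), plane=_parse_planes(df, path))
    out: list[SampledCurve] = []
    for (sid, side, plane), grp in df.groupby(["subject_id", "side", "plane"], sort=True):
        grp = grp.sort_values("s_mm")
        out.append(
            SampledCurve(
                str(sid),
                side,
                plane,
                grp["s_mm"].to_numpy(dtype=float),
                grp["projection_mm"].to_numpy(dtype=float),
            )
        )
    return out


def write_curves(curves: Sequence[SampledCurve], path: Path) -> None:
    rows = [
        (c.subject_id, "L" if c.side is Side.LEFT else "R", c.plane.value, s, y)
        for c in curves
        for s, y in zip(c.grid_mm, c.projection_mm)
    ]
    write_csv_atomic(pd.DataFrame(rows, columns=CURVE_COLUMNS), path)
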