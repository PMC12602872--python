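"""Reference cohort summary tables (50 healthy adult females, chest CT).

These are the published grid-level summary statistics for the reference
cohort that this package's synthetic generator emulates: per-grid-point mean
and SD of the anterior projection for the left and right chest walls, the
pointwise comparison statistics, the summed-chi-square footers, and the
best-fit through-origin polynomial coefficients for the mean curves. They
serve three roles: seed data for :mod:`chestwall.synthetic_cohort` templates,
worked-example inputs, and frozen expectations in the test suite.

Values are stored exactly as printed (two decimals); blank statistic cells
are NaN. Known quirks, kept as printed: the horizontal x=0 row carries a
nonzero right-side SD (1.24) despite an anchored origin, the same 1.24
appears again at x=100, and the printed SE column is not reproducible from
the printed SDs under the unpooled formula.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curve_geometry import Plane

__all__ = [
    "horizontal_table",
    "vertical_table",
    "comparison_table",
    "MEAN_CURVE_POLYNOMIALS",
    "SUM_CHISQ",
    "N_SUBJECTS",
    "MEAN_CHEST_WIDTH_MM",
    "AREA_HORIZONTAL_MM2",
    "AREA_VERTICAL_MM2",
    "VOLUME_HORIZONTAL_CC",
    "VOLUME_VERTICAL_CC",
    "VOLUME_MEAN_CC",
]

N_SUBJECTS = 50
MEAN_CHEST_WIDTH_MM = 234.0

#: Headline mean-curve results: areas (mm^2) and volumes (cc).
AREA_HORIZONTAL_MM2 = 143.0
AREA_VERTICAL_MM2 = 202.0
VOLUME_HORIZONTAL_CC = 14.3
VOLUME_VERTICAL_CC = 24.2
VOLUME_MEAN_CC = 19.3

#: Printed omnibus footers: (sum of chi-square, df). The horizontal sum
#: covers the rows 10-100 mm; the vertical sum covers 0-110 mm (the printed
#: footer omits the z=120 row, chi-square 0.01).
SUM_CHISQ = {
    Plane.HORIZONTAL: (43.79, 9),
    Plane.VERTICAL: (31.43, 11),
}

_COLUMNS = ["s_mm", "mean_left", "sd_left", "mean_right", "sd_right",
            "diff", "se", "t", "df", "chisq"]

_NAN = float("nan")

# Horizontal plane, x = distance from the sternal origin (mm).
_HORIZONTAL_ROWS = [
    #  x    mL      sdL    mR      sdR    diff   se    t     df  chi2
    (   0,   0.00,  0.00,   0.00,  1.24,  0.00, 0.00, _NAN, _NAN, _NAN),
    (  10,   0.34,  1.09,  -0.13,  2.08,  0.47, 0.23, 2.00,   98, 3.91),
    (  20,   0.96,  1.77,  -0.59,  3.04,  1.55, 0.39, 4.01,   98, 14.80),
    (  30,   0.95,  2.70,  -0.99,  4.16,  1.94, 0.58, 3.38,   98, 10.76),
    (  40,   0.57,  3.40,  -1.27,  5.09,  1.84, 0.76, 2.42,   98, 5.65),
    (  50,  -0.52,  4.17,  -2.50,  6.50,  1.98, 0.93, 2.13,   98, 4.41),
    (  60,  -2.92,  4.87,  -4.30,  7.69,  1.38, 1.15, 1.20,   98, 1.43),
    (  70,  -6.28,  6.04,  -7.96,  8.96,  1.68, 1.38, 1.21,   98, 1.45),
    (  80, -11.30,  7.46, -12.66, 10.52,  1.36, 1.65, 0.82,   98, 0.67),
    (  90, -17.97,  9.53, -19.40, 13.58,  1.43, 2.01, 0.71,   98, 0.51),
    ( 100, -28.09, 13.33, -29.30,  1.24,  1.21, 2.69, 0.45,   98, 0.20),
]

# Vertical plane, z = distance below the superior manubrium (mm).
_VERTICAL_ROWS = [
    (   0,   2.59,  4.82,   0.00,  0.00,  2.59, 0.68, 3.81,   98, 13.45),
    (  10,  11.19,  5.08,   9.14,  4.22,  2.05, 0.93, 2.20,   98, 4.68),
    (  20,  16.86,  5.87,  14.80,  5.58,  2.06, 1.15, 1.79,   98, 3.15),
    (  30,  21.73,  6.97,  19.61,  6.71,  2.12, 1.37, 1.55,   98, 2.36),
    (  40,  26.45,  7.81,  24.40,  7.56,  2.05, 1.54, 1.33,   98, 1.75),
    (  50,  30.57,  8.30,  28.27,  8.24,  2.30, 1.65, 1.39,   98, 1.91),
    (  60,  33.66,  8.96,  31.24,  9.34,  2.42, 1.83, 1.32,   98, 1.72),
    (  70,  36.33,  9.62,  34.21, 10.31,  2.12, 1.99, 1.06,   98, 1.12),
    (  80,  38.30, 10.37,  36.54, 11.24,  1.76, 2.16, 0.81,   98, 0.66),
    (  90,  39.88, 11.12,  38.60, 12.05,  1.28, 2.32, 0.55,   98, 0.30),
    ( 100,  41.08, 11.76,  39.88, 12.74,  1.21, 2.45, 0.49,   98, 0.24),
    ( 110,  41.88, 12.29,  41.13, 13.32,  0.75, 2.56, 0.29,   98, 0.09),
    ( 120,  42.14, 13.45,  41.90, 14.23,  0.24, 2.77, 0.09,   98, 0.01),
]

#: Row indices included in each printed omnibus footer sum.
SUM_ROWS = {
    Plane.HORIZONTAL: slice(1, 11),   # 10-100 mm
    Plane.VERTICAL: slice(0, 12),     # 0-110 mm
}

#: Printed best-fit through-origin polynomial coefficients for the mean
#: curves, ascending from the linear term. The vertical coefficients are
#: known to be numerically inconsistent with the vertical grid means (frame
#: or sign of that printed form is unclear); they are kept for reference and
#: are not used as ground truth anywhere in the pipeline.
MEAN_CURVE_POLYNOMIALS = {
    (Plane.HORIZONTAL, "left"): [-0.00364, 0.00532, -0.000180, 1.812e-6, -8.169e-9],
    (Plane.HORIZONTAL, "right"): [-0.0368, 0.000887, -0.0000119, -2.2585e-7],
    (Plane.VERTICAL, "left"): [-1.265, -0.0275, -0.000429, -3.422e-6, -1.018e-8],
    (Plane.VERTICAL, "right"): [-1.0195, -0.0178, -0.0002562, -1.983e-6, -5.799e-9],
}


def _build(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df["s_mm"] = df["s_mm"].astype(float)
    return df


def horizontal_table() -> pd.DataFrame:
    """Horizontal-plane reference table (grid 0-100 mm)."""
    return _build(_HORIZONTAL_ROWS)


def vertical_table() -> pd.DataFrame:
    """Vertical-plane reference table (grid 0-120 mm)."""
    return _build(_VERTICAL_ROWS)


def comparison_table(plane: Plane | str) -> pd.DataFrame:
    """Reference table for a plane."""
    plane = Plane(plane)
    return horizontal_table() if plane is Plane.HORIZONTAL else vertical_table()


def footer_chisq_values(plane: Plane | str) -> np.ndarray:
    """The printed per-point chi-square values included in the footer sum."""
    plane = Plane(plane)
    df = comparison_table(plane)
    return df["chisq"].to_numpy()[SUM_ROWS[plane]]
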