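"""Plane volumes, averaged volume discrepancy, and per-subject area distribution.

Each plane's signed area (mm^2) is scaled by the orthogonal chest dimension
to a crude volume estimate: horizontal area x chest width along the grid
(default 100 mm), vertical area x chest height along the grid (default
120 mm), converted to cc (1 cc = 1000 mm^3), and the two plane volumes are
averaged into the headline discrepancy. These are planar-integration
estimates, not true 3D volumes.

The per-subject area distribution is summarized by the sign split
(left-dominant proportion), the bias-corrected Fisher-Pearson skewness, the
D'Agostino skewness z-test, and the D'Agostino-Pearson K^2 omnibus normality
test (K^2 = z_skew^2 + z_kurt^2 against chi-square with 2 df).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "VolumeEstimate",
    "AreaDistributionSummary",
    "plane_volume",
    "mean_volume",
    "skewness",
    "dagostino_tests",
    "prominence_summary",
    "round_half_up",
]

#: Smallest sample for which the D'Agostino normal-approximation transforms
#: are considered reliable.
DAGOSTINO_MIN_N = 8


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 19.25 -> 19.3 at one decimal), for reports."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def plane_volume(area_mm2: float, multiplier_mm: float) -> float:
    """Volume (cc) = area (mm^2) x orthogonal chest dimension (mm) / 1000."""
    if multiplier_mm <= 0:
        raise ValueError("multiplier must be positive")
    return area_mm2 * multiplier_mm / 1000.0


def mean_volume(volume_h_cc: float, volume_v_cc: float) -> float:
    """Arithmetic mean of the two plane volume estimates."""
    return (volume_h_cc + volume_v_cc) / 2.0


@dataclass
class VolumeEstimate:
    """Plane volumes and their average, from the two mean-curve areas."""

    area_horizontal_mm2: float
    area_vertical_mm2: float
    multiplier_horizontal_mm: float
    multiplier_vertical_mm: float
    volume_horizontal_cc: float
    volume_vertical_cc: float
    volume_mean_cc: float

    @classmethod
    def from_areas(
        cls,
        area_horizontal_mm2: float,
        area_vertical_mm2: float,
        multiplier_horizontal_mm: float = 100.0,
        multiplier_vertical_mm: float = 120.0,
    ) -> "VolumeEstimate":
        vh = plane_volume(area_horizontal_mm2, multiplier_horizontal_mm)
        vv = plane_volume(area_vertical_mm2, multiplier_vertical_mm)
        return cls(
            area_horizontal_mm2=float(area_horizontal_mm2),
            area_vertical_mm2=float(area_vertical_mm2),
            multiplier_horizontal_mm=float(multiplier_horizontal_mm),
            multiplier_vertical_mm=float(multiplier_vertical_mm),
            volume_horizontal_cc=vh,
            volume_vertical_cc=vv,
            volume_mean_cc=mean_volume(vh, vv),
        )

    def to_dict(self) -> dict:
        return {
            "area_horizontal_mm2": self.area_horizontal_mm2,
            "area_vertical_mm2": self.area_vertical_mm2,
            "multipliers_mm": {
                "horizontal": self.multiplier_horizontal_mm,
                "vertical": self.multiplier_vertical_mm,
            },
            "volume_horizontal_cc": self.volume_horizontal_cc,
            "volume_vertical_cc": self.volume_vertical_cc,
            "volume_mean_cc": self.volume_mean_cc,
        }


def skewness(values, bias_corrected: bool = True) -> float:
    """Sample skewness: adjusted Fisher-Pearson standardized third moment.

    ``bias_corrected=False`` returns the plain moment coefficient g1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(v) == 0 or np.var(v) == 0:
        raise ValueError("skewness undefined for zero-variance sample")
    return float(stats.skew(v, bias=not bias_corrected))


def dagostino_tests(values) -> dict:
    """D'Agostino skewness test and D'Agostino-Pearson K^2 omnibus test.

    Returns {"z_skew", "p_skew", "k2", "p_k2"}; p-values are two-sided
    (skewness) and upper-tail chi-square with 2 df (omnibus).
    """
    v = np.asarray(values, dtype=float)
    if v.size < DAGOSTINO_MIN_N:
        raise ValueError(
            f"D'Agostino tests need at least n = {DAGOSTINO_MIN_N} values, got {v.size}"
        )
    z_skew, p_skew = stats.skewtest(v)
    k2, p_k2 = stats.normaltest(v)
    return {
        "z_skew": float(z_skew),
        "p_skew": float(p_skew),
        "k2": float(k2),
        "p_k2": float(p_k2),
    }


@dataclass
class AreaDistributionSummary:
    """Sign split and distribution shape of per-subject signed areas."""

    areas_mm2: np.ndarray
    n: int
    n_positive: int
    n_negative: int
    n_zero: int
    proportion_left_dominant: float
    skewness: float | None
    p_skew: float | None
    k2: float | None
    p_k2: float | None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_zero": self.n_zero,
            "proportion_left_dominant": self.proportion_left_dominant,
            "skewness": self.skewness,
            "p_skew": self.p_skew,
            "k2": self.k2,
            "p_k2": self.p_k2,
        }


def prominence_summary(areas) -> AreaDistributionSummary:
    """Summarize per-subject signed areas: sign counts plus shape statistics.

    Positive area = left side more anterior (left-dominant). Skewness needs
    n >= 3 with nonzero variance; the D'Agostino tests need n >= 8 — below
    those floors the corresponding fields are None.
    """
    v = np.asarray(list(areas), dtype=float)
    if v.size < 1:
        raise ValueError("need at least one area")
    n_pos = int(np.sum(v > 0))
    n_neg = int(np.sum(v < 0))
    n_zero = int(np.sum(v == 0))

    skew = p_skew = k2 = p_k2 = None
    if v.size >= 3 and np.var(v) > 0:
        skew = skewness(v)
    if v.size >= DAGOSTINO_MIN_N and np.var(v) > 0:
        d = dagostino_tests(v)
        p_skew, k2, p_k2 = d["p_skew"], d["k2"], d["p_k2"]

    return AreaDistributionSummary(
        areas_mm2=v,
        n=int(v.size),
        n_positive=n_pos,
        n_negative=n_neg,
        n_zero=n_zero,
        proportion_left_dominant=n_pos / v.size,
        skewness=skew,
        p_skew=p_skew,
        k2=k2,
        p_k2=p_k2,
    )
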