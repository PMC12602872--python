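"""Pointwise t statistics, the t-to-chi-square conversion, and the omnibus sum."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chestwall import reference_tables as rt
from chestwall.curve_geometry import Plane, Side
from chestwall.errors import UndefinedStatisticError
from chestwall.pointwise_stats import (
    compare_curve_sets,
    summed_chisq,
    t_to_chisq,
    two_sample_t,
)
from chestwall.synthetic_cohort import (
    CohortConfig,
    PlaneTemplate,
    curves_from_matrices,
    draw_grid_curves,
    table_template,
)


class TestTwoSampleT:
    def test_closed_form(self):
        s = two_sample_t(1.0, 1.0, 50, 0.0, 1.0, 50)
        assert s.diff == 1.0
        assert s.se == pytest.approx(0.2)
        assert s.t == pytest.approx(5.0)
        assert s.df == 98

    def test_equal_means_give_t_zero_p_one(self):
        s = two_sample_t(3.0, 2.0, 20, 3.0, 2.0, 20)
        assert s.t == 0.0
        assert s.p == 1.0
        assert s.chisq == 0.0

    def test_both_sds_zero_raises(self):
        with pytest.raises(UndefinedStatisticError):
            two_sample_t(1.0, 0.0, 10, 0.0, 0.0, 10)

    @pytest.mark.parametrize("plane", [Plane.HORIZONTAL, Plane.VERTICAL])
    def test_t_consistent_with_printed_diff_over_se(self, plane):
        # the printed t column should equal diff/se up to two-decimal rounding
        # of the printed diff and se columns
        df = rt.comparison_table(plane).dropna(subset=["t"])
        for row in df.itertuples():
            ratio = row.diff / row.se
            slack = (0.005 + 0.005 * abs(ratio)) / row.se + 0.005
            assert abs(row.t - ratio) <= slack, f"s={row.s_mm}"


class TestTToChisq:
    def test_zero_t_maps_to_zero(self):
        assert t_to_chisq(0.0, 98) == 0.0

    def test_large_t_is_finite_and_monotone(self):
        values = [t_to_chisq(t, 98) for t in (5.0, 20.0, 100.0, 500.0)]
        assert all(np.isfinite(values))
        assert values == sorted(values)

    def test_converges_to_t_squared_at_large_df(self):
        # relative gap < 1% at df = 1e6, t = 2
        assert t_to_chisq(2.0, 1_000_000) == pytest.approx(4.0, rel=0.01)

    @given(t=st.floats(0.01, 30), df=st.integers(2, 200))
    def test_even_in_t(self, t, df):
        assert t_to_chisq(t, df) == t_to_chisq(-t, df)

    @given(df=st.integers(2, 200))
    def test_strictly_increasing_in_magnitude(self, df):
        ts = np.linspace(0.1, 8.0, 12)
        vals = [t_to_chisq(t, df) for t in ts]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestSummedChisq:
    def test_single_value_is_its_own_sum(self):
        q, df, p = summed_chisq([2.5], df_convention="theoretical_k")
        assert q == 2.5 and df == 1

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            summed_chisq([])

    def test_negative_value_raises(self):
        with pytest.raises(ValueError):
            summed_chisq([1.0, -0.1])

    def test_sum_exact_and_p_monotone(self):
        vals = [1.0, 2.0, 3.0]
        q, df, p = summed_chisq(vals)
        assert q == 6.0 and df == 2
        q2, _, p2 = summed_chisq([v + 1 for v in vals])
        assert p2 < p


class TestCompareCurveSets:
    def test_matches_brute_force_means_and_sds(self, toy_cohort):
        grid, left_rows, right_rows, left, right = toy_cohort
        res = compare_curve_sets(left, right)
        lm = np.array(left_rows)
        rm = np.array(right_rows)
        for j, pt in enumerate(res.points):
            assert pt.mean_left == pytest.approx(lm[:, j].mean(), abs=0)
            assert pt.mean_right == pytest.approx(rm[:, j].mean(), abs=0)
            assert pt.sd_left == pytest.approx(lm[:, j].std(ddof=1), rel=1e-15)
            assert pt.sd_right == pytest.approx(rm[:, j].std(ddof=1), rel=1e-15)
            assert pt.diff == pt.mean_left - pt.mean_right
        assert res.sum_chisq == pytest.approx(
            sum(p.chisq for p in res.points if p.included)
        )

    def test_swapping_sides_negates_t_preserves_chisq(self, toy_cohort):
        _, _, _, left, right = toy_cohort
        fwd = compare_curve_sets(left, right)
        rev = compare_curve_sets(right, left)
        for a, b in zip(fwd.points, rev.points):
            assert a.t == pytest.approx(-b.t, rel=1e-12)
            assert a.diff == -b.diff
            assert a.chisq == pytest.approx(b.chisq, rel=1e-9)
        assert fwd.sum_chisq == pytest.approx(rev.sum_chisq, rel=1e-9)

    def test_identical_collections_give_zero_statistics(self, toy_cohort):
        _, _, _, left, _ = toy_cohort
        mirror = [
            type(c)(c.subject_id, Side.RIGHT, c.plane, c.grid_mm, c.projection_mm)
            for c in left
        ]
        res = compare_curve_sets(left, mirror)
        assert all(p.t == 0.0 for p in res.points if p.included)
        assert res.sum_chisq == 0.0

    def test_mismatched_grids_raise(self, toy_cohort):
        _, _, _, left, right = toy_cohort
        bad = type(right[0])(
            "S9", Side.RIGHT, Plane.HORIZONTAL, right[0].grid_mm * 2, right[0].projection_mm
        )
        with pytest.raises(ValueError, match="grid"):
            compare_curve_sets(left, [right[0], bad])

    def test_constant_offset_expected_t(self):
        # +2 mm offset, SD 4, n = 200/side: expected t = 2/(4 sqrt(2/200)) = 5
        flat = PlaneTemplate(
            mean_template=lambda s: np.zeros_like(np.asarray(s, float)),
            offset_field=lambda s: np.full_like(np.asarray(s, float), 2.0),
            sd_field=lambda side, s: np.full_like(np.asarray(s, float), 4.0),
        )
        cfg = CohortConfig(
            n_subjects=200,
            templates={Plane.HORIZONTAL: flat},
            include_centerlines=False,
        )
        rng = np.random.default_rng(42)
        reps = 30
        tmat = []
        for _ in range(reps):
            grid, L, R = draw_grid_curves(cfg, Plane.HORIZONTAL, rng)
            res = compare_curve_sets(
                curves_from_matrices(grid, L, Side.LEFT, Plane.HORIZONTAL),
                curves_from_matrices(grid, R, Side.RIGHT, Plane.HORIZONTAL),
            )
            tmat.append([p.t for p in res.points])
        tmat = np.array(tmat)
        mean_t = tmat.mean(axis=0)
        se_t = tmat.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean_t - 5.0) <= 3.0 * se_t)

    def test_cohort_t_sampling_distribution_tracks_printed_column(self):
        # cohorts regenerated from the reference means/SDs at n=50 give
        # per-point t values scattered about the printed column
        cfg = CohortConfig(n_subjects=50, include_centerlines=False)
        printed = (
            rt.horizontal_table().dropna(subset=["t"]).set_index("s_mm")["t"]
        )
        rng = np.random.default_rng(77)
        hits = total = 0
        for _ in range(40):
            grid, L, R = draw_grid_curves(cfg, Plane.HORIZONTAL, rng)
            res = compare_curve_sets(
                curves_from_matrices(grid, L, Side.LEFT, Plane.HORIZONTAL),
                curves_from_matrices(grid, R, Side.RIGHT, Plane.HORIZONTAL),
            )
            for p in res.points:
                if p.included and p.grid_mm in printed.index:
                    total += 1
                    hits += abs(p.t - printed[p.grid_mm]) <= 1.0
        assert hits / total >= 0.5
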