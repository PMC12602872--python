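"""Through-origin polynomial fitting, evaluation, and signed-area integration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from chestwall import reference_tables as rt
from chestwall.curve_geometry import Plane, SampledCurve, Side
from chestwall.curve_model import (
    PolynomialModel,
    evaluate,
    fit_through_origin,
    integrate_difference,
    per_subject_area,
)

GRID_H = np.arange(0.0, 101.0, 10.0)

coeff_lists = st.lists(
    st.floats(-1e-2, 1e-2, allow_nan=False), min_size=1, max_size=5
)


def model(coeffs, plane=Plane.HORIZONTAL, label="m"):
    return PolynomialModel(plane, label, np.asarray(coeffs, float), (0.0, 100.0), 0.0)


class TestFit:
    def test_exact_line_selects_degree_one(self):
        m = fit_through_origin(GRID_H, 2.0 * GRID_H)
        assert m.degree == 1
        assert m.coefficients[0] == pytest.approx(2.0, rel=1e-12)
        assert m.residual_variance < 1e-15

    def test_recovers_exact_cubic(self):
        y = 0.01 * GRID_H**2 - 0.0001 * GRID_H**3
        m = fit_through_origin(GRID_H, y)
        assert m.degree == 3
        assert m.coefficients[1] == pytest.approx(0.01, rel=1e-9)
        assert m.coefficients[2] == pytest.approx(-0.0001, rel=1e-9)
        assert abs(m.coefficients[0]) < 1e-9

    @pytest.mark.parametrize("column", ["mean_left", "mean_right"])
    def test_reference_mean_columns_fitted_within_1mm(self, column):
        table = rt.horizontal_table()
        m = fit_through_origin(table["s_mm"].to_numpy(), table[column].to_numpy())
        fitted = evaluate(m, table["s_mm"].to_numpy())
        assert np.max(np.abs(fitted - table[column].to_numpy())) < 1.0

    def test_selected_degree_minimizes_residual_variance(self, rng):
        y = 0.02 * GRID_H**2 - 2e-5 * GRID_H**3 + rng.normal(0, 0.5, GRID_H.size)
        m = fit_through_origin(GRID_H, y)
        for d in range(1, 6):
            X = np.vander(GRID_H, d + 1, increasing=True)[:, 1:]
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            var = np.sum((X @ coef - y) ** 2) / (GRID_H.size - d)
            assert m.residual_variance <= var + 1e-9

    def test_scale_equivariance(self, rng):
        y = rng.normal(0, 2, GRID_H.size)
        m1 = fit_through_origin(GRID_H, y)
        m3 = fit_through_origin(GRID_H, 3.0 * y)
        assert m3.degree == m1.degree
        np.testing.assert_allclose(m3.coefficients, 3.0 * m1.coefficients, rtol=1e-9)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="points"):
            fit_through_origin(GRID_H[:4], GRID_H[:4])

    def test_duplicate_grid_raises(self):
        g = np.array([0.0, 10.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            fit_through_origin(g, g)


class TestEvaluate:
    def test_origin_is_zero_for_any_model(self):
        m = model([0.3, -0.02, 1e-4, -1e-6, 1e-8])
        assert evaluate(m, 0.0) == 0.0

    def test_identity_model(self):
        assert evaluate(model([1.0]), 50.0) == 50.0

    def test_reference_horizontal_left_polynomial_at_10mm(self):
        # direct arithmetic on the printed coefficients:
        # -0.00364*10 + 0.00532*100 - 0.000180*1000 + 1.812e-6*1e4 - 8.169e-9*1e5
        m = model(rt.MEAN_CURVE_POLYNOMIALS[(Plane.HORIZONTAL, "left")])
        assert evaluate(m, 10.0) == pytest.approx(0.3329031, abs=1e-7)


class TestIntegrateDifference:
    def test_identical_models_give_zero(self):
        m = model([0.5, -0.01])
        assert integrate_difference(m, m, 0.0, 100.0).area_mm2 == 0.0

    def test_linear_closed_form(self):
        area = integrate_difference(model([1.0]), model([0.0]), 0.0, 10.0)
        assert area.area_mm2 == pytest.approx(50.0, rel=1e-12)

    def test_invalid_bounds_raise(self):
        m = model([1.0])
        with pytest.raises(ValueError):
            integrate_difference(m, m, 10.0, 10.0)

    @given(cl=coeff_lists, cr=coeff_lists)
    def test_antisymmetric_and_additive(self, cl, cr):
        ml, mr = model(cl), model(cr)
        full = integrate_difference(ml, mr, 0.0, 100.0).area_mm2
        rev = integrate_difference(mr, ml, 0.0, 100.0).area_mm2
        assert full == pytest.approx(-rev, rel=1e-12, abs=1e-12)
        a = integrate_difference(ml, mr, 0.0, 40.0).area_mm2
        b = integrate_difference(ml, mr, 40.0, 100.0).area_mm2
        assert full == pytest.approx(a + b, rel=1e-9, abs=1e-9)

    @given(cl=coeff_lists, cr=coeff_lists)
    def test_matches_adaptive_quadrature(self, cl, cr):
        ml, mr = model(cl), model(cr)
        exact = integrate_difference(ml, mr, 0.0, 100.0).area_mm2
        num, _ = quad(lambda s: evaluate(ml, s) - evaluate(mr, s), 0.0, 100.0)
        assert exact == pytest.approx(num, rel=1e-9, abs=1e-9)


class TestPerSubjectArea:
    def _curves(self, yl, yr, grid=GRID_H):
        left = SampledCurve("S1", Side.LEFT, Plane.HORIZONTAL, grid, yl)
        right = SampledCurve("S1", Side.RIGHT, Plane.HORIZONTAL, grid, yr)
        return left, right

    @pytest.mark.parametrize("method", ["polynomial", "trapezoid"])
    def test_identical_sides_give_zero(self, method):
        y = 0.01 * GRID_H**2
        left, right = self._curves(y, y.copy())
        assert per_subject_area(left, right, method).area_mm2 == pytest.approx(
            0.0, abs=1e-9
        )

    def test_constant_offset_rectangle_trapezoid(self):
        left, right = self._curves(np.full(11, 2.0), np.zeros(11))
        result = per_subject_area(left, right, "trapezoid")
        assert result.area_mm2 == pytest.approx(200.0)
        assert result.method == "trapezoid"

    def test_polynomial_method_reproduces_analytic_integral(self):
        cl = np.array([0.1, -0.003, 2e-5])
        cr = np.array([-0.05, 0.002, -1e-5])
        yl = sum(c * GRID_H ** (k + 1) for k, c in enumerate(cl))
        yr = sum(c * GRID_H ** (k + 1) for k, c in enumerate(cr))
        left, right = self._curves(yl, yr)
        d = cl - cr
        analytic = sum(c * 100.0 ** (k + 2) / (k + 2) for k, c in enumerate(d))
        result = per_subject_area(left, right, "polynomial")
        assert result.area_mm2 == pytest.approx(analytic, rel=1e-6)

    def test_mismatched_grids_raise(self):
        left, _ = self._curves(np.zeros(11), np.zeros(11))
        right = SampledCurve(
            "S1", Side.RIGHT, Plane.HORIZONTAL, GRID_H / 2.0, np.zeros(11)
        )
        with pytest.raises(ValueError, match="grid"):
            per_subject_area(left, right)
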