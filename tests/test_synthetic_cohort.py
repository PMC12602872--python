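"""Synthetic cohort generator: templates, reproducibility, and contracts."""

import numpy as np
import pytest

from chestwall import io as cw_io
from chestwall.curve_geometry import Plane, Side, sample_projection, standardize
from chestwall.curve_model import per_subject_area
from chestwall.errors import ConfigError
from chestwall.synthetic_cohort import (
    CohortConfig,
    PlaneTemplate,
    cohort_to_pointsets,
    draw_grid_curves,
    generate_cohort,
    table_template,
)


def flat_template(offset=0.0, sd=0.0):
    as_arr = lambda s: np.asarray(s, dtype=float)
    return PlaneTemplate(
        mean_template=lambda s: 0.05 * as_arr(s),
        offset_field=lambda s: np.full_like(as_arr(s), offset),
        sd_field=lambda side, s: np.full_like(as_arr(s), sd),
    )


class TestTableTemplate:
    def test_interpolants_hit_the_printed_knots(self):
        h = table_template(Plane.HORIZONTAL)
        assert h.offset_field(30.0) == pytest.approx(1.94)
        assert h.mean_template(0.0) == pytest.approx(0.0)
        v = table_template(Plane.VERTICAL)
        assert v.offset_field(0.0) == pytest.approx(2.59)
        assert v.sd_field(Side.RIGHT, 0.0) == pytest.approx(0.0)

    def test_horizontal_origin_is_anchored_on_both_sides(self):
        h = table_template(Plane.HORIZONTAL)
        assert h.sd_field(Side.LEFT, 0.0) == 0.0
        assert h.sd_field(Side.RIGHT, 0.0) == 0.0


class TestGenerateCohort:
    def test_zero_noise_zero_offset_gives_identical_sides(self):
        cfg = CohortConfig(
            n_subjects=3,
            planes=(Plane.HORIZONTAL,),
            templates={Plane.HORIZONTAL: flat_template()},
        )
        for subj in generate_cohort(cfg):
            left = subj.truth[(Plane.HORIZONTAL, Side.LEFT)]
            right = subj.truth[(Plane.HORIZONTAL, Side.RIGHT)]
            np.testing.assert_array_equal(left.projection_mm, right.projection_mm)
            assert per_subject_area(left, right, "trapezoid").area_mm2 == 0.0

    def test_zero_noise_constant_offset_gives_rectangle_areas(self):
        cfg = CohortConfig(
            n_subjects=3,
            planes=(Plane.HORIZONTAL,),
            templates={Plane.HORIZONTAL: flat_template(offset=2.0)},
        )
        for subj in generate_cohort(cfg):
            area = per_subject_area(
                subj.truth[(Plane.HORIZONTAL, Side.LEFT)],
                subj.truth[(Plane.HORIZONTAL, Side.RIGHT)],
                "trapezoid",
            )
            assert area.area_mm2 == pytest.approx(200.0)

    def test_same_seed_is_bit_identical_different_seed_differs(self):
        cfg_a = CohortConfig(n_subjects=4, seed=9)
        cfg_b = CohortConfig(n_subjects=4, seed=9)
        cfg_c = CohortConfig(n_subjects=4, seed=10)
        a, b, c = generate_cohort(cfg_a), generate_cohort(cfg_b), generate_cohort(cfg_c)
        key = (Plane.HORIZONTAL, Side.LEFT)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(
                sa.truth[key].projection_mm, sb.truth[key].projection_mm
            )
            np.testing.assert_array_equal(sa.pointsets[key].points, sb.pointsets[key].points)
        assert not np.array_equal(
            a[0].truth[key].projection_mm, c[0].truth[key].projection_mm
        )

    def test_fixed_axis_quantized_to_slice_thickness(self):
        cfg = CohortConfig(n_subjects=5, slice_thickness_mm=3.0, seed=2)
        for subj in generate_cohort(cfg):
            for (plane, _side), ps in subj.pointsets.items():
                ifx = subj.frames[plane].axis_indices[2]
                level = ps.points[:, ifx] - subj.translation[ifx]
                ratio = level / 3.0
                np.testing.assert_allclose(ratio, np.round(ratio), atol=1e-9)

    def test_sample_sd_converges_to_sd_field(self):
        cfg = CohortConfig(n_subjects=10_000, include_centerlines=False, seed=6)
        rng = np.random.default_rng(cfg.seed)
        grid, L, R = draw_grid_curves(cfg, Plane.HORIZONTAL, rng)
        tmpl = table_template(Plane.HORIZONTAL)
        for mat, side in ((L, Side.LEFT), (R, Side.RIGHT)):
            target = tmpl.sd_field(side, grid)
            sample = mat.std(axis=0, ddof=1)
            mask = target > 0
            np.testing.assert_allclose(sample[mask], target[mask], rtol=0.05)
            np.testing.assert_allclose(sample[~mask], 0.0, atol=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_subjects=1)
        with pytest.raises(ConfigError):
            CohortConfig(within_subject_correlation=1.5)


class TestPointsetExport:
    def test_roundtrip_preserves_coordinates(self, tmp_path):
        subjects = generate_cohort(CohortConfig(n_subjects=2, seed=3))
        df = cohort_to_pointsets(subjects)
        path = tmp_path / "pointsets.csv"
        cw_io.write_pointsets(df, path)
        back = cw_io.read_pointsets(path)
        by_key = {(ps.subject_id, ps.plane, ps.side): ps for ps in back}
        for subj in subjects:
            for (plane, side), ps in subj.pointsets.items():
                got = by_key[(subj.subject_id, plane, side)]
                np.testing.assert_allclose(got.points, ps.points, rtol=0, atol=1e-9)

    def test_two_subject_cohort_has_eight_curve_groups(self):
        subjects = generate_cohort(CohortConfig(n_subjects=2, seed=3))
        df = cohort_to_pointsets(subjects)
        groups = df.groupby(["subject_id", "side", "plane"]).ngroups
        assert groups == 2 * 2 * 2

    def test_pipeline_sampling_recovers_ground_truth_exactly(self):
        subjects = generate_cohort(CohortConfig(n_subjects=2, seed=4))
        for subj in subjects:
            for (plane, side), ps in subj.pointsets.items():
                frame = subj.frames[plane]
                curve = sample_projection(standardize(ps, frame), frame)
                np.testing.assert_allclose(
                    curve.projection_mm,
                    subj.truth[(plane, side)].projection_mm,
                    rtol=0,
                    atol=1e-9,
                )
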