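"""SECT calibration curves, curve application, and error statistics."""

import numpy as np
import pandas as pd
import pytest

from pedrsp.exceptions import CalibrationError, ValidationError
from pedrsp.pediatric import build_pediatric_database
from pedrsp.reference_data import AGE_GROUPS, SEXES, TissueDatabase
from pedrsp.sect_calibration import (
    CalibrationCurve,
    Segment,
    apply_curve,
    build_age_specific_curve,
    build_conventional_curve,
    error_stats,
    evaluate_database,
    rsp_error,
)


class TestConventionalCurve:
    def test_four_segments_with_spec_boundaries(self, pipeline):
        curve = pipeline.conventional_curve
        bounds = [s.lo for s in curve.segments] + [curve.segments[-1].hi]
        assert bounds == [-1000.0, -150.0, -95.0, 200.0, 3100.0]

    def test_soft_segment_near_water_point(self, pipeline):
        # water's (0 HU, RSP 1) should be close to the soft-tissue line
        assert apply_curve(pipeline.conventional_curve, 0.0) == pytest.approx(1.0, abs=0.02)

    def test_missing_bone_tissues_raise(self, pipeline, adult_db, ctx, elements):
        no_bones = TissueDatabase(
            source="adult70-nobones",
            tissues=[t for t in adult_db if t.group != "bone"],
        )
        with pytest.raises(CalibrationError, match="bone"):
            build_conventional_curve(pipeline.schneider, no_bones, ctx, elements)

    def test_json_round_trip(self, pipeline, tmp_path):
        p = tmp_path / "curve.json"
        pipeline.conventional_curve.to_json(p)
        again = CalibrationCurve.from_json(p)
        assert again.segments == pipeline.conventional_curve.segments

    def test_per_segment_mean_residual_vanishes(self, pipeline, adult_db, ctx, elements):
        # OLS property: the mean signed residual per fitted segment is ~0
        table = evaluate_database(adult_db, pipeline.conventional_curve,
                                  pipeline.schneider, ctx, elements)
        curve = pipeline.conventional_curve
        for seg in curve.segments:
            if seg.name == "lung":
                continue  # lung line is air-anchored, not pure OLS on tissues
            sub = table[(table.hu >= seg.lo) & (table.hu < seg.hi)]
            resid = sub.rsp_ref - (seg.slope * sub.hu + seg.intercept)
            assert abs(resid.mean()) < 1e-10


class TestAgeSpecificCurve:
    def test_full_sweep_yields_12_curves(self, pipeline):
        curves = [pipeline.age_specific_curve(a, s) for a in AGE_GROUPS for s in SEXES]
        assert len(curves) == 12
        for c in curves:
            assert len(c.segments) == 3

    def test_1y_female_boundaries(self, pipeline):
        c = pipeline.age_specific_curve("1y", "female")
        bounds = [s.lo for s in c.segments] + [c.hi_max]
        assert bounds == [-1000.0, -100.0, 200.0, 4100.0]
        assert (c.age_group, c.sex) == ("1y", "female")

    def test_self_consistency_mean_residual(self, pipeline, ctx, elements):
        db = build_pediatric_database("5y", "male")
        curve = pipeline.age_specific_curve("5y", "male")
        table = evaluate_database(db, curve, pipeline.schneider, ctx, elements)
        table = table[table.group != "excluded"]
        for seg in curve.segments:
            if seg.name == "lung":
                continue
            sub = table[(table.hu >= seg.lo) & (table.hu < seg.hi)]
            resid = sub.rsp_ref - (seg.slope * sub.hu + seg.intercept)
            assert abs(resid.mean()) < 1e-10

    def test_degenerate_single_tissue_segment_raises(self, pipeline, ctx, elements):
        # a database whose bone region (>= 200 HU) holds a single tissue
        db = build_pediatric_database("1y", "female")
        keep = [t for t in db
                if t.tissue_id in (29, 33, 36, 37, 38, 39, 41, 44, 47, 50, 2)]
        thinned = TissueDatabase(source="pediatric53-thin", tissues=keep)
        with pytest.raises(CalibrationError, match="bone"):
            build_age_specific_curve(pipeline.schneider, thinned, ctx, elements)


class TestApplyCurve:
    @pytest.fixture()
    def toy_curve(self):
        return CalibrationCurve(
            kind="age-specific", spectrum_label="140kVp",
            segments=[
                Segment(-1000.0, -100.0, 1e-3, 1.0, "lung"),
                Segment(-100.0, 200.0, 5e-4, 1.0, "soft"),
                Segment(200.0, 4100.0, 3e-4, 1.05, "bone"),
            ],
        )

    def test_boundary_belongs_to_right_segment(self, toy_curve):
        assert apply_curve(toy_curve, 200.0) == pytest.approx(1.05 + 3e-4 * 200)
        assert apply_curve(toy_curve, -100.0) == pytest.approx(1.0 + 5e-4 * -100)

    def test_exact_linearity_inside_segment(self, toy_curve):
        hu = np.linspace(-50.0, 150.0, 7)
        np.testing.assert_allclose(apply_curve(toy_curve, hu), 1.0 + 5e-4 * hu, rtol=1e-14)

    def test_below_floor_clamped(self, toy_curve):
        assert apply_curve(toy_curve, -2000.0) == apply_curve(toy_curve, -1000.0)

    def test_result_floored_at_zero(self, toy_curve):
        assert apply_curve(toy_curve, -1000.0) == pytest.approx(0.0)

    def test_extrapolates_bone_line_above_top(self, toy_curve):
        assert apply_curve(toy_curve, 5000.0) == pytest.approx(1.05 + 3e-4 * 5000)

    def test_two_point_segments_reproduce_exact_line(self, pipeline, ctx, elements):
        # tissues lying exactly on a line are reproduced exactly by the fit
        curve = pipeline.age_specific_curve("adult", "male")
        for seg in curve.segments:
            mid = 0.5 * (max(seg.lo, -1000) + min(seg.hi, 2000))
            assert apply_curve(curve, mid) == pytest.approx(seg(mid), rel=1e-12)


class TestErrors:
    def test_rsp_error_basic(self):
        assert rsp_error(1.02, 1.00) == pytest.approx(0.02)
        assert rsp_error(1.37, 1.37) == 0.0

    def test_rsp_error_rejects_nonpositive_reference(self):
        with pytest.raises(ValidationError):
            rsp_error(1.0, 0.0)

    def test_error_recomputation_consistency(self, pipeline):
        # per-tissue error equals recomputation from its own table columns
        tab = pipeline.sect_evaluation("10y", "male")
        recomputed = (tab.rsp_est - tab.rsp_ref) / tab.rsp_ref
        np.testing.assert_allclose(tab.error, recomputed, rtol=1e-12)

    def test_constant_error_vector_stats(self):
        tab = pd.DataFrame({
            "tissue_id": [30, 31, 32], "group": ["soft"] * 3,
            "error": [0.02, 0.02, 0.02],
        })
        (st,) = error_stats(tab, groups=("soft",))
        assert st.mean == pytest.approx(2.0)
        assert st.sd == pytest.approx(0.0)
        assert st.n == 3

    def test_exclusion_list_applied(self, pipeline):
        with_all = error_stats(pipeline.sect_evaluation("newborn", "female"))
        without = error_stats(pipeline.sect_evaluation("newborn", "female"),
                              exclude_ids=(22, 23, 25))
        soft_all = next(s for s in with_all if s.group == "soft")
        soft_ex = next(s for s in without if s.group == "soft")
        assert soft_ex.n == soft_all.n - 3
        assert soft_ex.mean < soft_all.mean  # medullary cavities are overestimated

    def test_empty_group_raises(self):
        tab = pd.DataFrame({"tissue_id": [1], "group": ["soft"], "error": [0.0]})
        with pytest.raises(ValidationError):
            error_stats(tab, groups=("bone",))


class TestSignPattern:
    """Qualitative structure of the per-group errors on the tissue databases."""

    def test_pediatric_soft_over_bone_under(self, pipeline):
        for age in ("newborn", "1y", "5y", "10y", "15y"):
            soft, bone = error_stats(pipeline.sect_evaluation(age, "female"))
            assert soft.mean > 0, age
            assert bone.mean < 0, age

    def test_adult_errors_smaller_than_pediatric(self, pipeline):
        newborn_soft, newborn_bone = error_stats(pipeline.sect_evaluation("newborn", "male"))
        adult_soft, adult_bone = error_stats(pipeline.sect_evaluation("adult", "male"))
        assert abs(adult_soft.mean) < newborn_soft.mean
        assert abs(adult_bone.mean) < abs(newborn_bone.mean)

    def test_age_specific_reduces_mean_errors(self, pipeline):
        for age in ("newborn", "1y", "5y"):
            conv = error_stats(pipeline.sect_evaluation(age, "female"))
            spec = error_stats(pipeline.age_specific_evaluation(age, "female"))
            for c, s in zip(conv, spec):
                assert abs(s.mean) <= abs(c.mean) + 1e-9, (age, c.group)
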