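"""Geometry and asymmetry-statistic unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneeasym.errors import InsufficientDataError, InvariantError, MeasurementError
from kneeasym.morphometry import (
    MEASURE_FIELDS,
    LandmarkSet,
    MorphometrySet,
    PixelSpacing,
    asymmetry,
    asymmetry_vector,
    femur_width,
    intercondylar_distance,
    joint_space,
    measure_knee,
    rater_variability,
    tibia_width,
)
from kneeasym.synthetic import LayoutConfig, construct_landmarks

from conftest import random_measures


def _ls(points, spacing=PixelSpacing(0.2, 0.2), side="right"):
    return LandmarkSet(knee_side=side, spacing=spacing, points=points)


class TestDistances:
    @pytest.mark.parametrize(
        "femur,tibia,spacing,expected",
        [
            ((10, 20), (10, 26), PixelSpacing(0.2, 0.2), 1.2),
            ((10, 20), (10, 20), PixelSpacing(0.2, 0.2), 0.0),
            ((10, 20), (13, 24), PixelSpacing(0.2, 0.1), math.sqrt(0.73)),
        ],
    )
    def test_joint_space(self, femur, tibia, spacing, expected):
        ls = _ls({"medial_js_femur": femur, "medial_js_tibia": tibia}, spacing)
        assert joint_space(ls, "medial") == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_joint_space_inverted_pair(self):
        ls = _ls({"medial_js_femur": (10, 26), "medial_js_tibia": (10, 20)})
        with pytest.raises(InvariantError):
            joint_space(ls, "medial")

    def test_joint_space_missing_point(self):
        with pytest.raises(MeasurementError, match="medial_js_tibia"):
            joint_space(_ls({"medial_js_femur": (10, 20)}), "medial")

    @pytest.mark.parametrize(
        "xs,expected",
        [
            (((100, 100), (200, 200)), 20.0),  # pairs share centerline x
            (((150, 150), (150, 150)), 0.0),
            (((100, 102), (198, 200)), 19.6),  # mean-x per compartment
        ],
    )
    def test_intercondylar(self, xs, expected):
        (m1, m2), (l1, l2) = xs
        ls = _ls(
            {
                "medial_js_femur": (m1, 10),
                "medial_js_tibia": (m2, 40),
                "lateral_js_femur": (l1, 10),
                "lateral_js_tibia": (l2, 40),
            }
        )
        assert intercondylar_distance(ls) == pytest.approx(expected, abs=1e-12)

    def test_femur_width_examples(self):
        ls = _ls({"femur_margin_medial": (50, 30), "femur_margin_lateral": (450, 30)})
        assert femur_width(ls) == pytest.approx(80.0)
        ls = _ls({"femur_margin_medial": (50, 30), "femur_margin_lateral": (450, 34)})
        assert femur_width(ls) == pytest.approx(math.hypot(80.0, 0.8), rel=1e-12)
        # coincident margins measure as zero width...
        ls = _ls({"femur_margin_medial": (50, 30), "femur_margin_lateral": (50, 30)})
        assert femur_width(ls) == 0.0
        # ...and the joint-space < femur-width invariant then fails downstream
        with pytest.raises(InvariantError):
            MorphometrySet(6, 5, 45, 0.0, 80, 33, 4, 2).validate()

    def test_tibia_width_symmetric_in_labels(self):
        pts = {"tibia_margin_medial_1cm": (60, 300), "tibia_margin_lateral_1cm": (440, 300)}
        swapped = {
            "tibia_margin_medial_1cm": pts["tibia_margin_lateral_1cm"],
            "tibia_margin_lateral_1cm": pts["tibia_margin_medial_1cm"],
        }
        assert tibia_width(_ls(pts), "1cm") == pytest.approx(76.0)
        assert tibia_width(_ls(swapped), "1cm") == tibia_width(_ls(pts), "1cm")
        tilted = {"tibia_margin_medial_1cm": (60, 300), "tibia_margin_lateral_1cm": (420, 310)}
        assert tibia_width(_ls(tilted), "1cm") == pytest.approx(math.hypot(72.0, 2.0), rel=1e-12)

    def test_translation_invariance(self, reference_measures):
        ls = construct_landmarks(reference_measures)
        shifted = LandmarkSet(
            knee_side=ls.knee_side,
            spacing=ls.spacing,
            points={k: (x + 37.0, y + 11.0) for k, (x, y) in ls.points.items()},
        )
        m0, m1 = measure_knee(ls), measure_knee(shifted)
        for name in MEASURE_FIELDS:
            assert getattr(m1, name) == pytest.approx(getattr(m0, name), rel=1e-9, abs=1e-9)


class TestAngles:
    def test_requested_angles_recovered_exactly(self, reference_measures):
        got = measure_knee(construct_landmarks(reference_measures))
        assert got.ft_angle_deg == pytest.approx(4.0, abs=1e-9)
        assert got.vv_angle_deg == pytest.approx(2.0, abs=1e-9)

    def test_joint_rotation_leaves_angles_unchanged(self, reference_measures):
        base = measure_knee(construct_landmarks(reference_measures))
        rot = measure_knee(
            construct_landmarks(reference_measures, layout=LayoutConfig(rotation_deg=3.0))
        )
        assert rot.ft_angle_deg == pytest.approx(base.ft_angle_deg, abs=1e-9)
        assert rot.vv_angle_deg == pytest.approx(base.vv_angle_deg, abs=1e-9)

    def test_mirror_flips_angle_sign_only(self, reference_measures):
        ls = construct_landmarks(reference_measures, knee_side="right")
        width = max(x for x, _ in ls.points.values()) + 10
        mirrored = LandmarkSet(
            knee_side="right",
            spacing=ls.spacing,
            points={k: (width - x, y) for k, (x, y) in ls.points.items()},
        )
        m0, m1 = measure_knee(ls), measure_knee(mirrored)
        assert m1.ft_angle_deg == pytest.approx(-m0.ft_angle_deg, abs=1e-9)
        assert m1.vv_angle_deg == pytest.approx(-m0.vv_angle_deg, abs=1e-9)
        for name in MEASURE_FIELDS[:6]:
            assert getattr(m1, name) == pytest.approx(getattr(m0, name), rel=1e-9)

    def test_anisotropic_spacing_changes_angle(self, reference_measures):
        iso = measure_knee(construct_landmarks(reference_measures))
        # same pixel coordinates, different physical spacing
        ls = construct_landmarks(reference_measures)
        squashed = LandmarkSet("right", PixelSpacing(0.3, 0.2), points=ls.points)
        assert measure_knee(squashed).ft_angle_deg != pytest.approx(iso.ft_angle_deg, abs=1e-6)

    def test_degenerate_tangent_raises(self):
        m = MorphometrySet(6, 5, 45, 75, 80, 33, 4, 2)
        ls = construct_landmarks(m)
        pts = dict(ls.points)
        pts["lateral_js_femur"] = pts["medial_js_femur"]
        from kneeasym.morphometry import ft_angle

        with pytest.raises(MeasurementError):
            ft_angle(LandmarkSet("right", ls.spacing, pts))


class TestMeasureKnee:
    def test_missing_landmark_named(self, reference_measures):
        ls = construct_landmarks(reference_measures)
        pts = dict(ls.points)
        del pts["fossa_top"]
        with pytest.raises(MeasurementError, match="fossa_top"):
            measure_knee(LandmarkSet("right", ls.spacing, pts))

    def test_deterministic(self, reference_measures):
        ls = construct_landmarks(reference_measures)
        a, b = measure_knee(ls), measure_knee(ls)
        assert a.as_array().tobytes() == b.as_array().tobytes()

    def test_roundtrip_with_random_measures(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m = random_measures(rng)
            got = measure_knee(construct_landmarks(m))
            for name in MEASURE_FIELDS:
                assert getattr(got, name) == pytest.approx(
                    getattr(m, name), rel=1e-9, abs=1e-9
                ), name


class TestAsymmetry:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            (4.0, 4.0, 0.0),
            (4.2, 3.8, 0.1),
            (5.0, 0.0, 2.0),
            (-3.0, 3.0, 0.0),  # magnitudes equal; denominator |0|? no: mean=0 -> nan
        ],
    )
    def test_examples(self, left, right, expected):
        if left == -3.0:
            assert math.isnan(asymmetry(left, right))
        else:
            assert asymmetry(left, right) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_flagged(self):
        assert math.isnan(asymmetry(1.0, -1.0))
        m1 = MorphometrySet(6, 5, 45, 75, 80, 33, 1.0, 2)
        m2 = MorphometrySet(6, 5, 45, 75, 80, 33, -1.0, 2)
        vec = asymmetry_vector(m1, m2)
        assert vec.undefined["ft_angle_deg"]
        assert not vec.undefined["medial_js_mm"]

    @given(
        x=st.floats(0.01, 1e6),
        y=st.floats(0.01, 1e6),
        scale=st.floats(0.001, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_eq1_properties(self, x, y, scale):
        a = asymmetry(x, y)
        assert 0.0 <= a <= 2.0
        assert asymmetry(y, x) == a  # swap symmetry
        assert asymmetry(scale * x, scale * y) == pytest.approx(a, rel=1e-9, abs=1e-12)
        if x == y:
            assert a == 0.0
        if a == 0.0:
            assert x == pytest.approx(y, rel=1e-12)

    def test_vector_symmetries(self, reference_measures):
        other = MorphometrySet(5.5, 5.2, 46, 74, 81, 32, 3.0, -1.0)
        v1 = asymmetry_vector(reference_measures, other)
        v2 = asymmetry_vector(other, reference_measures)
        assert v1.values == v2.values
        scaled_l = MorphometrySet(*(3 * v for v in reference_measures.as_array()))
        scaled_r = MorphometrySet(*(3 * v for v in other.as_array()))
        v3 = asymmetry_vector(scaled_l, scaled_r)
        for name in MEASURE_FIELDS:
            assert v3.values[name] == pytest.approx(v1.values[name], rel=1e-9)
        v0 = asymmetry_vector(reference_measures, reference_measures)
        assert all(v == 0.0 for v in v0.values.values())


class TestRaterVariability:
    def _pair(self, base, **overrides):
        d = base.as_dict()
        d.update(overrides)
        return MorphometrySet.from_dict(d)

    def test_identical_repeats_zero(self, reference_measures):
        report = rater_variability([(reference_measures, reference_measures)] * 3)
        frame = report.to_frame()
        assert (frame["relative_pct"] == 0).all()
        assert (frame["mean_abs_diff"] == 0).all()

    def test_hand_computed_example(self, reference_measures):
        # medial JS repeat pairs (5.0, 5.2) and (4.0, 4.2)
        p1 = (
            self._pair(reference_measures, medial_js_mm=5.0),
            self._pair(reference_measures, medial_js_mm=5.2),
        )
        p2 = (
            self._pair(reference_measures, medial_js_mm=4.0),
            self._pair(reference_measures, medial_js_mm=4.2),
        )
        report = rater_variability([p1, p2])
        assert report.mean_abs_diff["medial_js_mm"] == pytest.approx(0.2, abs=1e-12)
        assert report.relative_pct["medial_js_mm"] == pytest.approx(0.2 / 4.6 * 100, rel=1e-9)

    def test_locality(self, reference_measures):
        p = (reference_measures, self._pair(reference_measures, vv_angle_deg=2.5))
        q = (reference_measures, reference_measures)
        report = rater_variability([p, q])
        for name in MEASURE_FIELDS:
            if name == "vv_angle_deg":
                assert report.mean_abs_diff[name] > 0
            else:
                assert report.mean_abs_diff[name] == 0.0

    def test_insufficient_pairs(self, reference_measures):
        with pytest.raises(InsufficientDataError):
            rater_variability([(reference_measures, reference_measures)])
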