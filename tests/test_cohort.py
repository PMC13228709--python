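"""Exclusion cascade, KL grouping and dataset-assembly tests."""

import numpy as np
import pandas as pd
import pytest

from kneeasym.cohort import (
    Cohort,
    ExclusionConfig,
    apply_baseline_exclusions,
    build_asymmetry_dataset,
    build_baseline_knee_dataset,
    build_longitudinal_dataset,
    knee_group,
    knee_groups,
    stratify_by_baseline_kl,
    subject_group,
)
from kneeasym.errors import SchemaError
from kneeasym.synthetic import CohortConfig, generate_cohort

from conftest import build_cohort, make_knee, make_measure_row, make_subject, simple_cohort


def _default_rows(sid, **knee_kw):
    knees = [make_knee(sid, s, **knee_kw) for s in ("right", "left")]
    meas = [make_measure_row(sid, s) for s in ("right", "left")]
    return knees, meas


class TestExclusionCascade:
    def _fixture(self):
        """10 subjects: 2 aged over the cutoff, 1 with arthroscopy history,
        1 with a +12 kg weight change (all disjoint)."""
        subs, knees, meas = [], [], []
        specs = [
            ("S0", {}), ("S1", {}),
            ("S2", {"age": 70.0}), ("S3", {"age": 71.0}),
            ("S4", {"injury": True}),
            ("S5", {"weight_path": (70, 72, 75, 82, 82, 82, 82, 82)}),
            ("S6", {}), ("S7", {}), ("S8", {}), ("S9", {}),
        ]
        for sid, kw in specs:
            age = kw.pop("age", 55.0)
            wp = kw.pop("weight_path", None)
            subs.append(make_subject(sid, age=age, weight_path=wp))
            k, m = _default_rows(sid, **kw)
            knees += k
            meas += m
        return build_cohort(subs, knees, meas)

    def test_pooled_counts_match_hand_tabulation(self):
        cohort = self._fixture()
        filtered, audit = apply_baseline_exclusions(cohort)
        steps = audit.to_frame()
        assert steps.loc[0, "n_subjects_excluded"] == 4
        assert steps.loc[0, "n_knees_excluded"] == 8
        assert steps.loc[0, "n_subjects_remaining"] == 6
        assert steps.loc[1, "criterion"] == "limited_tibia_view"
        assert steps.loc[1, "n_subjects_excluded"] == 0
        assert len(filtered.subjects) == 6
        audit.check()

    def test_subject_meeting_two_criteria_counted_once(self):
        subs = [make_subject("A", age=70.0, weight_path=(70,) * 7 + (85,)), make_subject("B")]
        knees, meas = [], []
        for sid in ("A", "B"):
            k, m = _default_rows(sid)
            knees += k
            meas += m
        filtered, audit = apply_baseline_exclusions(build_cohort(subs, knees, meas))
        assert audit.steps[0].n_subjects_excluded == 1
        assert len(filtered.subjects) == 1

    def test_disabled_config_is_identity(self):
        cohort = self._fixture()
        filtered, audit = apply_baseline_exclusions(cohort, ExclusionConfig.disabled())
        assert len(filtered.subjects) == 10
        assert all(s.n_subjects_excluded == 0 for s in audit.steps)

    def test_age_cutoff_is_strict(self):
        subs = [make_subject("A", age=67.0), make_subject("B", age=67.01)]
        knees, meas = [], []
        for sid in ("A", "B"):
            k, m = _default_rows(sid)
            knees += k
            meas += m
        filtered, _ = apply_baseline_exclusions(build_cohort(subs, knees, meas))
        assert list(filtered.subjects["subject_id"]) == ["A"]

    def test_baseline_kl_above_two_excludes_subject(self):
        subs = [make_subject("A"), make_subject("B")]
        knees = [
            make_knee("A", "right", kl_baseline=3), make_knee("A", "left", kl_baseline=0),
            make_knee("B", "right", kl_baseline=2), make_knee("B", "left", kl_baseline=2),
        ]
        meas = [make_measure_row(s, sd) for s in ("A", "B") for sd in ("right", "left")]
        filtered, _ = apply_baseline_exclusions(build_cohort(subs, knees, meas))
        assert list(filtered.subjects["subject_id"]) == ["B"]

    def test_limited_view_step_follows_pooled(self):
        subs = [make_subject("A"), make_subject("B")]
        knees = [
            make_knee("A", "right", limited_view=True), make_knee("A", "left"),
            make_knee("B", "right"), make_knee("B", "left"),
        ]
        meas = [make_measure_row(s, sd) for s in ("A", "B") for sd in ("right", "left")]
        filtered, audit = apply_baseline_exclusions(build_cohort(subs, knees, meas))
        assert audit.steps[1].n_subjects_excluded == 1
        assert list(filtered.subjects["subject_id"]) == ["B"]

    def test_missing_required_field_is_schema_error(self):
        subs = [make_subject("A")]
        subs[0]["age_baseline"] = np.nan
        knees, meas = _default_rows("A")
        with pytest.raises(SchemaError, match="A"):
            build_cohort(subs, knees, meas)


class TestGrouping:
    @pytest.mark.parametrize(
        "kl_fu8,surgery,expected",
        [
            (0, "none", "KL01"),
            (1, "none", "KL01"),
            (2, "none", "KL2"),
            (3, "none", "KL34S"),
            (4, "none", "KL34S"),
            (None, "TKA", "KL34S"),  # surgery is absorbing
            (1, "PKA", "KL34S"),
            (None, "none", None),
        ],
    )
    def test_knee_group(self, kl_fu8, surgery, expected):
        assert knee_group(np.nan if kl_fu8 is None else kl_fu8, surgery) == expected

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("KL01", "KL2", "KL2"),
            ("KL01", "KL34S", "KL34S"),
            ("KL01", "KL01", "KL01"),
            ("KL2", None, None),
        ],
    )
    def test_subject_group_max_rule(self, a, b, expected):
        assert subject_group(a, b) == expected

    def test_group_labels_partition_dataset(self):
        sc = generate_cohort(CohortConfig(n_subjects=300, seed=21))
        cohort = Cohort.from_synthetic(sc)
        groups = knee_groups(cohort.knees)
        gradable = groups.dropna()
        assert set(gradable) <= {"KL01", "KL2", "KL34S"}
        ds = build_baseline_knee_dataset(cohort)
        assert ds["group"].notna().all()
        assert len(ds) == len(gradable)


class TestAsymmetryDataset:
    def test_kl_difference_two_excluded(self):
        subs, knees, meas = [], [], []
        for i in range(20):
            sid = f"S{i:02d}"
            subs.append(make_subject(sid))
            kl_pair = (0, 2) if i < 3 else (0, 1)  # 3 subjects at difference 2
            for side, kl in zip(("right", "left"), kl_pair):
                knees.append(make_knee(sid, side, kl_baseline=kl))
                meas.append(make_measure_row(sid, side))
        ds = build_asymmetry_dataset(build_cohort(subs, knees, meas))
        assert len(ds) == 17
        assert not ds["subject_id"].isin(["S00", "S01", "S02"]).any()

    def test_difference_one_included(self):
        subs = [make_subject("A")]
        knees = [make_knee("A", "right", kl_baseline=1), make_knee("A", "left", kl_baseline=2)]
        meas = [make_measure_row("A", s) for s in ("right", "left")]
        ds = build_asymmetry_dataset(build_cohort(subs, knees, meas))
        assert len(ds) == 1

    def test_one_knee_ungradable_excludes_subject(self):
        subs = [make_subject("A"), make_subject("B")]
        knees = [
            make_knee("A", "right", kl_fu8=None), make_knee("A", "left"),
            make_knee("B", "right"), make_knee("B", "left"),
        ]
        meas = [make_measure_row(s, sd) for s in ("A", "B") for sd in ("right", "left")]
        ds = build_asymmetry_dataset(build_cohort(subs, knees, meas))
        assert list(ds["subject_id"]) == ["B"]

    def test_asymmetry_values_match_hand_computation(self):
        cohort = simple_cohort(n=2, medial_js_delta={"S000": 0.5})
        ds = build_asymmetry_dataset(cohort).set_index("subject_id")
        # left 5.25, right 4.75 -> |0.5| / 5.0
        assert ds.loc["S000", "asym_medial_js_mm"] == pytest.approx(0.1)
        assert ds.loc["S001", "asym_medial_js_mm"] == 0.0

    def test_outcome_flag_follows_max_group(self):
        subs = [make_subject("A")]
        knees = [make_knee("A", "right", kl_fu8=1), make_knee("A", "left", kl_fu8=3)]
        meas = [make_measure_row("A", s) for s in ("right", "left")]
        ds = build_asymmetry_dataset(build_cohort(subs, knees, meas))
        assert ds.loc[0, "group"] == "KL34S"
        assert bool(ds.loc[0, "oa"])


class TestLongitudinalDataset:
    def _cohort_with_implants(self):
        subs, knees, meas = [], [], []
        for i in range(6):  # 12 knees, 2 implants
            sid = f"S{i}"
            subs.append(make_subject(sid))
            for j, side in enumerate(("right", "left")):
                implant = i == 0  # both knees of S0 replaced
                knees.append(
                    make_knee(
                        sid, side,
                        kl_fu8=None if implant else 1,
                        surgery="TKA" if implant else "none",
                        surgery_year=5 if implant else None,
                    )
                )
                meas.append(make_measure_row(sid, side, timepoint="baseline"))
                meas.append(make_measure_row(sid, side, timepoint="fu8", medial_js=4.5))
        return build_cohort(subs, knees, meas)

    def test_implant_zero_joint_space_and_kl34_exclusion(self):
        ds = build_longitudinal_dataset(self._cohort_with_implants())
        assert len(ds) == 12  # KL34S summaries see all knees
        implants = ds[~ds["in_kl34"]]
        assert len(implants) == 2
        assert (implants["medial_js_mm_fu8"] == 0.0).all()
        assert (implants["lateral_js_mm_fu8"] == 0.0).all()
        assert (implants["group"] == "KL34S").all()
        assert len(ds[ds["in_kl34"]]) == 10

    def test_both_timepoints_linked_per_knee(self):
        ds = build_longitudinal_dataset(self._cohort_with_implants())
        row = ds[(ds["subject_id"] == "S1") & (ds["side"] == "right")].iloc[0]
        assert row["medial_js_mm_baseline"] == 5.0
        assert row["medial_js_mm_fu8"] == 4.5

    def test_missing_fu_without_implant_dropped(self):
        subs = [make_subject("A")]
        knees = [make_knee("A", "right"), make_knee("A", "left")]
        meas = [
            make_measure_row("A", "right", timepoint="baseline"),
            make_measure_row("A", "right", timepoint="fu8"),
            make_measure_row("A", "left", timepoint="baseline"),  # no follow-up
        ]
        ds = build_longitudinal_dataset(build_cohort(subs, knees, meas))
        assert len(ds) == 1
        assert ds.loc[0, "side"] == "right"


class TestStratification:
    def test_filter_cases(self):
        df = pd.DataFrame({"kl_baseline": [0, 1, 2, 2, 1], "v": range(5)})
        assert len(stratify_by_baseline_kl(df, "KL01")) == 3
        assert len(stratify_by_baseline_kl(df, "KL2")) == 2
        empty = df[df["kl_baseline"] > 10]
        assert len(stratify_by_baseline_kl(empty, "KL01")) == 0
        with pytest.raises(ValueError):
            stratify_by_baseline_kl(df, "KL34S")

    def test_subject_level_uses_max_baseline_kl(self):
        df = pd.DataFrame({"kl_baseline_max": [0, 1, 2], "v": range(3)})
        assert len(stratify_by_baseline_kl(df, "KL2")) == 1


class TestDeterminismAndConservation:
    def test_rerun_identical(self):
        sc = generate_cohort(CohortConfig(n_subjects=150, seed=33))
        cohort = Cohort.from_synthetic(sc)
        f1, a1 = apply_baseline_exclusions(cohort)
        f2, a2 = apply_baseline_exclusions(cohort)
        pd.testing.assert_frame_equal(f1.subjects, f2.subjects)
        pd.testing.assert_frame_equal(
            build_asymmetry_dataset(f1), build_asymmetry_dataset(f2)
        )
        assert a1.to_json() == a2.to_json()

    def test_audit_conserved_through_dataset_assembly(self):
        sc = generate_cohort(CohortConfig(n_subjects=400, seed=13))
        filtered, audit = apply_baseline_exclusions(Cohort.from_synthetic(sc))
        build_asymmetry_dataset(filtered, audit)
        audit.check()
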