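"""Cohort assembly: exclusion cascade, KL grouping and analysis datasets.

The cohort is held as three tidy tables:

``subjects``  one row per subject: ``subject_id, sex, age_baseline,
              height_mm, weight_y0..weight_yK`` (kg, baseline = y0);
``knees``     one row per knee: ``subject_id, side, kl_baseline, kl_fu8,
              surgery (none|PKA|TKA), surgery_year,
              injury_or_surgery_history, limited_tibia_view``;
``measures``  one row per knee per timepoint (``baseline`` / ``fu8``) with
              the eight morphometry columns.

The exclusion cascade removes, in order: (1) a pooled step — subjects over
the age cutoff, with injury / knee-surgery / arthroscopy history, with a
baseline KL grade above 2, or whose weight changed by more than 10 kg from
baseline at any recorded follow-up visit — each subject counted once; then
(2) subjects whose radiographs truncate the proximal tibia (limited view).
Every step is recorded in an audit whose counts are conserved.

Grouping uses the 8-year follow-up KL grade: KL01 (grades 0-1), KL2
(grade 2), KL34S (grades 3-4 or partial/total knee arthroplasty); knee
replacement is absorbing, so a knee with surgery but no follow-up grade is
KL34S.  KL34 is KL34S minus the implant knees and is the group used for
follow-up statistics, because implant joint spaces are set to zero by
convention rather than measured.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError
from .morphometry import MEASURE_FIELDS

__all__ = [
    "GROUP_LABELS",
    "ExclusionConfig",
    "ExclusionAudit",
    "Cohort",
    "apply_baseline_exclusions",
    "knee_group",
    "knee_groups",
    "subject_group",
    "build_baseline_knee_dataset",
    "build_asymmetry_dataset",
    "build_longitudinal_dataset",
    "stratify_by_baseline_kl",
]

GROUP_LABELS = ("KL01", "KL2", "KL34S")
_GROUP_ORDER = {g: i for i, g in enumerate(GROUP_LABELS)}

_SUBJECT_COLS = ("subject_id", "sex", "age_baseline", "height_mm", "weight_y0")
_KNEE_COLS = (
    "subject_id",
    "side",
    "kl_baseline",
    "kl_fu8",
    "surgery",
    "injury_or_surgery_history",
    "limited_tibia_view",
)
_MEASURE_COLS = ("subject_id", "side", "timepoint") + MEASURE_FIELDS


@dataclass
class Cohort:
    """The three cohort tables, schema-checked on construction."""

    subjects: pd.DataFrame
    knees: pd.DataFrame
    measures: pd.DataFrame

    def __post_init__(self) -> None:
        for df, cols, name in (
            (self.subjects, _SUBJECT_COLS, "subjects"),
            (self.knees, _KNEE_COLS, "knees"),
            (self.measures, _MEASURE_COLS, "measures"),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} table is missing columns {missing}")
        for col in ("age_baseline", "height_mm", "weight_y0"):
            bad = self.subjects.loc[self.subjects[col].isna(), "subject_id"]
            if len(bad):
                raise SchemaError(f"subject {bad.iloc[0]!r}: missing required field {col!r}")
        kl = self.knees["kl_baseline"]
        ok = kl.isna() | ((kl >= 0) & (kl <= 4) & (kl == kl.round()))
        if not ok.all():
            bad = self.knees.loc[~ok].iloc[0]
            raise SchemaError(
                f"subject {bad['subject_id']!r}: kl_baseline must be an integer in [0, 4]"
            )

    @property
    def weight_cols(self) -> list[str]:
        cols = [c for c in self.subjects.columns if c.startswith("weight_y")]
        return sorted(cols, key=lambda c: int(c.split("weight_y")[1]))

    @property
    def bmi_baseline(self) -> pd.Series:
        """Baseline BMI in kg/m^2, derived from weight_y0 and height."""
        return self.subjects["weight_y0"] / (self.subjects["height_mm"] / 1000.0) ** 2

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        ids = set(subject_ids)
        return Cohort(
            subjects=self.subjects[self.subjects["subject_id"].isin(ids)].reset_index(drop=True),
            knees=self.knees[self.knees["subject_id"].isin(ids)].reset_index(drop=True),
            measures=self.measures[self.measures["subject_id"].isin(ids)].reset_index(drop=True),
        )

    @classmethod
    def from_dir(cls, path) -> "Cohort":
        p = Path(path)
        try:
            return cls(
                subjects=pd.read_csv(p / "subjects.csv"),
                knees=pd.read_csv(p / "knees.csv"),
                measures=pd.read_csv(p / "measures.csv"),
            )
        except FileNotFoundError as exc:
            raise SchemaError(f"cohort directory {p} is missing a table: {exc}") from exc

    @classmethod
    def from_synthetic(cls, synthetic_cohort) -> "Cohort":
        return cls(
            subjects=synthetic_cohort.subjects.copy(),
            knees=synthetic_cohort.knees.copy(),
            measures=synthetic_cohort.measures.copy(),
        )


@dataclass(frozen=True)
class ExclusionConfig:
    """Which baseline exclusion criteria are active, and their cutoffs."""

    max_age: float | None = 67.0
    exclude_injury_history: bool = True
    max_baseline_kl: int | None = 2
    max_weight_change_kg: float | None = 10.0
    exclude_limited_view: bool = True

    @classmethod
    def disabled(cls) -> "ExclusionConfig":
        return cls(
            max_age=None,
            exclude_injury_history=False,
            max_baseline_kl=None,
            max_weight_change_kg=None,
            exclude_limited_view=False,
        )


@dataclass
class AuditStep:
    criterion: str
    n_subjects_excluded: int
    n_knees_excluded: int
    n_subjects_remaining: int
    n_knees_remaining: int


@dataclass
class ExclusionAudit:
    """Ordered record of the cascade; counts are conserved at every step."""

    n_subjects_initial: int
    n_knees_initial: int
    steps: list[AuditStep] = field(default_factory=list)

    def record(self, criterion: str, n_subj_excl: int, n_knee_excl: int) -> None:
        prev_s, prev_k = self.current()
        self.steps.append(
            AuditStep(criterion, n_subj_excl, n_knee_excl, prev_s - n_subj_excl, prev_k - n_knee_excl)
        )

    def current(self) -> tuple[int, int]:
        if self.steps:
            last = self.steps[-1]
            return last.n_subjects_remaining, last.n_knees_remaining
        return self.n_subjects_initial, self.n_knees_initial

    def check(self) -> None:
        s, k = self.n_subjects_initial, self.n_knees_initial
        for st in self.steps:
            if st.n_subjects_remaining != s - st.n_subjects_excluded:
                raise AssertionError(f"subject counts not conserved at step {st.criterion}")
            if st.n_knees_remaining != k - st.n_knees_excluded:
                raise AssertionError(f"knee counts not conserved at step {st.criterion}")
            s, k = st.n_subjects_remaining, st.n_knees_remaining

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_subjects_initial": self.n_subjects_initial,
                "n_knees_initial": self.n_knees_initial,
                "steps": [vars(s) for s in self.steps],
            },
            indent=1,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def apply_baseline_exclusions(
    cohort: Cohort, config: ExclusionConfig | None = None
) -> tuple[Cohort, ExclusionAudit]:
    """Run the baseline exclusion cascade; returns the filtered cohort + audit.

    The four baseline criteria (age, injury/surgery history, baseline KL,
    weight change from baseline) are pooled: a subject meeting several is
    counted once.  The limited-tibia-view exclusion follows as its own step.
    """
    cfg = config or ExclusionConfig()
    subj = cohort.subjects.set_index("subject_id", drop=False)
    knees = cohort.knees
    audit = ExclusionAudit(n_subjects_initial=len(subj), n_knees_initial=len(knees))

    pooled = pd.Series(False, index=subj.index)
    if cfg.max_age is not None:
        pooled |= subj["age_baseline"] > cfg.max_age
    if cfg.exclude_injury_history:
        flagged = knees.loc[knees["injury_or_surgery_history"].astype(bool), "subject_id"]
        pooled |= subj.index.isin(flagged)
    if cfg.max_baseline_kl is not None:
        high = knees.loc[knees["kl_baseline"] > cfg.max_baseline_kl, "subject_id"]
        pooled |= subj.index.isin(high)
    if cfg.max_weight_change_kg is not None:
        wcols = cohort.weight_cols
        if len(wcols) > 1:
            w = subj[wcols]
            change = (w.sub(w["weight_y0"], axis=0)).abs().max(axis=1)
            pooled |= change > cfg.max_weight_change_kg

    keep_ids = subj.index[~pooled]
    n_knee_excl = int((~knees["subject_id"].isin(keep_ids)).sum())
    audit.record("baseline_pooled(age,injury,kl,weight)", int(pooled.sum()), n_knee_excl)
    cohort = cohort.subset(keep_ids)

    if cfg.exclude_limited_view:
        flagged = set(cohort.knees.loc[cohort.knees["limited_tibia_view"].astype(bool), "subject_id"])
        n_knee_excl = int(cohort.knees["subject_id"].isin(flagged).sum())
        audit.record("limited_tibia_view", len(flagged), n_knee_excl)
        cohort = cohort.subset(set(cohort.subjects["subject_id"]) - flagged)
    else:
        audit.record("limited_tibia_view", 0, 0)
    audit.check()
    return cohort, audit


# ---------------------------------------------------------------------------
# KL grouping
# ---------------------------------------------------------------------------

def knee_group(kl_fu8, surgery: str = "none") -> str | None:
    """Follow-up severity group of one knee; ``None`` when ungradable.

    Knee replacement is absorbing (assumed static-or-increasing severity),
    so surgery without a follow-up grade still maps to KL34S.
    """
    if isinstance(surgery, str) and surgery.upper() in ("PKA", "TKA"):
        return "KL34S"
    if kl_fu8 is None or (isinstance(kl_fu8, float) and math.isnan(kl_fu8)):
        return None
    kl = int(kl_fu8)
    if kl <= 1:
        return "KL01"
    if kl == 2:
        return "KL2"
    return "KL34S"


def knee_groups(knees: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`knee_group` over a knees table."""
    return pd.Series(
        [knee_group(kl, s) for kl, s in zip(knees["kl_fu8"], knees["surgery"].fillna("none"))],
        index=knees.index,
        dtype=object,
    )


def subject_group(group_a: str | None, group_b: str | None) -> str | None:
    """Subject-level group: the maximum severity of the two knees."""
    if group_a is None or group_b is None:
        return None
    return max(group_a, group_b, key=lambda g: _GROUP_ORDER[g])


# ---------------------------------------------------------------------------
# analysis datasets
# ---------------------------------------------------------------------------

def _baseline_measures(cohort: Cohort) -> pd.DataFrame:
    return cohort.measures[cohort.measures["timepoint"] == "baseline"]


def build_baseline_knee_dataset(
    cohort: Cohort, audit: ExclusionAudit | None = None
) -> pd.DataFrame:
    """Knee-level baseline dataset: one row per gradable knee with its
    follow-up group label and baseline measures."""
    knees = cohort.knees.copy()
    knees["group"] = knee_groups(knees)
    gradable = knees[knees["group"].notna()].copy()
    if audit is not None:
        audit.record(
            "fu_kl_missing_knees",
            0,
            int(len(knees) - len(gradable)),
        )
    df = gradable.merge(_baseline_measures(cohort), on=["subject_id", "side"], how="inner")
    demo = cohort.subjects[["subject_id", "sex", "age_baseline", "height_mm", "weight_y0"]].copy()
    demo["bmi_baseline"] = cohort.bmi_baseline.values
    return df.merge(demo, on="subject_id", how="left").reset_index(drop=True)


def build_asymmetry_dataset(
    cohort: Cohort, audit: ExclusionAudit | None = None
) -> pd.DataFrame:
    """Subject-level asymmetry dataset.

    Keeps subjects with both knees gradable at follow-up and a baseline KL
    difference below 2 between the knees, then attaches the relative
    left-right difference of every baseline measure (columns ``asym_*``,
    dimensionless fractions), the subject group (max severity of the two
    knees) and an ``oa`` outcome flag (group == KL34S).
    """
    knees = cohort.knees.copy()
    knees["group"] = knee_groups(knees)
    per_subj = knees.pivot_table(
        index="subject_id", columns="side", values="group", aggfunc="first", dropna=False
    )
    both_gradable = per_subj.notna().all(axis=1) & (per_subj.shape[1] == 2)
    n_drop_grade = int((~both_gradable).sum())
    keep = set(per_subj.index[both_gradable])
    if audit is not None:
        n_knees_drop = int((~cohort.knees["subject_id"].isin(keep)).sum())
        audit.record("fu_grade_missing_either_knee", n_drop_grade, n_knees_drop)

    klb = knees[knees["subject_id"].isin(keep)].pivot_table(
        index="subject_id", columns="side", values="kl_baseline", aggfunc="first"
    )
    diff_ok = (klb.max(axis=1) - klb.min(axis=1)) < 2
    n_drop_diff = int((~diff_ok).sum())
    keep2 = set(klb.index[diff_ok])
    if audit is not None:
        n_knees_drop = 2 * n_drop_diff
        audit.record("baseline_kl_difference_2", n_drop_diff, n_knees_drop)

    base = _baseline_measures(cohort)
    wide = base[base["subject_id"].isin(keep2)].pivot_table(
        index="subject_id", columns="side", values=list(MEASURE_FIELDS), aggfunc="first"
    )
    complete = wide.notna().all(axis=1)
    n_drop_meas = int((~complete).sum())
    if audit is not None:
        audit.record("baseline_measures_missing", n_drop_meas, 2 * n_drop_meas)
    wide = wide[complete]

    rows = pd.DataFrame(index=wide.index)
    for name in MEASURE_FIELDS:
        left = wide[(name, "left")].to_numpy(dtype=float)
        right = wide[(name, "right")].to_numpy(dtype=float)
        denom = np.abs((left + right) / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            asym = np.abs(np.abs(left) - np.abs(right)) / denom
        asym[denom == 0.0] = np.nan
        rows[f"asym_{name}"] = asym

    grp = per_subj.loc[rows.index]
    rows["group"] = [subject_group(a, b) for a, b in zip(grp["left"], grp["right"])]
    rows["oa"] = rows["group"] == "KL34S"
    rows["kl_baseline_max"] = klb.loc[rows.index].max(axis=1)
    demo = cohort.subjects.set_index("subject_id")
    rows["sex"] = demo["sex"]
    rows["age_baseline"] = demo["age_baseline"]
    rows["height_mm"] = demo["height_mm"]
    rows["weight_y0"] = demo["weight_y0"]
    rows["bmi_baseline"] = demo["weight_y0"] / (demo["height_mm"] / 1000.0) ** 2
    return rows.reset_index()


def build_longitudinal_dataset(
    cohort: Cohort, audit: ExclusionAudit | None = None
) -> pd.DataFrame:
    """Knee-level two-timepoint dataset.

    One row per gradable knee with ``<measure>_baseline`` and
    ``<measure>_fu8`` columns.  Implant (PKA/TKA) knees get zero follow-up
    joint spaces and ``in_kl34 = False``: they appear in KL34S summaries but
    are excluded from follow-up statistics.  Knees without a follow-up
    radiograph and no implant are dropped (audited).
    """
    knees = cohort.knees.copy()
    knees["group"] = knee_groups(knees)
    gradable = knees[knees["group"].notna()].copy()
    gradable["implant"] = gradable["surgery"].fillna("none").str.upper().isin(["PKA", "TKA"])

    meas = cohort.measures
    bl = meas[meas["timepoint"] == "baseline"][["subject_id", "side", *MEASURE_FIELDS]]
    fu = meas[meas["timepoint"] == "fu8"][["subject_id", "side", *MEASURE_FIELDS]]
    df = gradable.merge(bl, on=["subject_id", "side"], how="inner", validate="1:1")
    df = df.rename(columns={m: f"{m}_baseline" for m in MEASURE_FIELDS})
    df = df.merge(fu, on=["subject_id", "side"], how="left", validate="1:1")
    df = df.rename(columns={m: f"{m}_fu8" for m in MEASURE_FIELDS})

    has_fu = df[[f"{m}_fu8" for m in MEASURE_FIELDS]].notna().all(axis=1)
    drop = ~(has_fu | df["implant"])
    if audit is not None:
        audit.record("fu_measures_missing", 0, int(drop.sum()))
    df = df[~drop].copy()

    demo = cohort.subjects[["subject_id", "sex", "age_baseline", "height_mm", "weight_y0"]]
    df = df.merge(demo, on="subject_id", how="left")

    implant = df["implant"]
    df.loc[implant, "medial_js_mm_fu8"] = 0.0
    df.loc[implant, "lateral_js_mm_fu8"] = 0.0
    # implant knees keep their other follow-up measures if present, else baseline
    for m in MEASURE_FIELDS[2:]:
        df.loc[implant & df[f"{m}_fu8"].isna(), f"{m}_fu8"] = df.loc[
            implant & df[f"{m}_fu8"].isna(), f"{m}_baseline"
        ]
    df["in_kl34"] = ~implant
    return df.reset_index(drop=True)


def stratify_by_baseline_kl(dataset: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Restrict a dataset to baseline-KL01 or baseline-KL2 knees/subjects."""
    if stratum not in ("KL01", "KL2"):
        raise ValueError(f"stratum must be 'KL01' or 'KL2', got {stratum!r}")
    if "kl_baseline" in dataset.columns:
        col = dataset["kl_baseline"]
    elif "kl_baseline_max" in dataset.columns:
        col = dataset["kl_baseline_max"]
    else:
        raise SchemaError("dataset has neither 'kl_baseline' nor 'kl_baseline_max'")
    mask = col <= 1 if stratum == "KL01" else col == 2
    return dataset[mask].reset_index(drop=True)
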