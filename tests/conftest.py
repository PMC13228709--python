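"""Shared fixtures: reference measure sets and hand-built cohort tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kneeasym.cohort import Cohort
from kneeasym.morphometry import MEASURE_FIELDS, MorphometrySet, PixelSpacing


@pytest.fixture
def spacing_iso() -> PixelSpacing:
    return PixelSpacing(0.2, 0.2)


@pytest.fixture
def reference_measures() -> MorphometrySet:
    """A plausible healthy knee."""
    return MorphometrySet(
        lateral_js_mm=6.0,
        medial_js_mm=5.0,
        intercondylar_mm=45.0,
        femur_width_mm=75.0,
        prox_tibia_width_mm=80.0,
        dist_tibia_width_mm=33.0,
        ft_angle_deg=4.0,
        vv_angle_deg=2.0,
    )


def random_measures(rng: np.random.Generator, phantom_safe: bool = False) -> MorphometrySet:
    """Draw a valid random measure set; ``phantom_safe`` keeps the
    intercondylar notch wide enough for the renderer."""
    if phantom_safe:
        icd = rng.normal(48.0, 1.5)
        fw = rng.normal(75.0, 2.0)
    else:
        icd = rng.normal(45.0, 3.0)
        fw = rng.normal(75.0, 4.0)
    return MorphometrySet(
        lateral_js_mm=max(1.0, rng.normal(6.0, 0.7)),
        medial_js_mm=max(1.0, rng.normal(5.0, 0.6)),
        intercondylar_mm=icd,
        femur_width_mm=fw,
        prox_tibia_width_mm=rng.normal(80.0, 2.5),
        dist_tibia_width_mm=rng.normal(33.0, 2.0),
        ft_angle_deg=rng.normal(4.0, 2.0),
        vv_angle_deg=rng.normal(2.0, 1.5),
    )


# ---------------------------------------------------------------------------
# hand-built cohort tables
# ---------------------------------------------------------------------------

def make_subject(
    subject_id: str,
    sex: str = "female",
    age: float = 55.0,
    height_mm: float = 1650.0,
    weight0: float = 70.0,
    weight_path: tuple[float, ...] | None = None,
) -> dict:
    row = {
        "subject_id": subject_id,
        "sex": sex,
        "age_baseline": age,
        "height_mm": height_mm,
        "weight_y0": weight0,
    }
    path = weight_path if weight_path is not None else (weight0,) * 8
    for i, w in enumerate(path, start=1):
        row[f"weight_y{i}"] = w
    return row


def make_knee(
    subject_id: str,
    side: str,
    kl_baseline: int = 0,
    kl_fu8: float | None = 0,
    surgery: str = "none",
    surgery_year: float | None = None,
    injury: bool = False,
    limited_view: bool = False,
) -> dict:
    return {
        "subject_id": subject_id,
        "side": side,
        "kl_baseline": kl_baseline,
        "kl_fu8": np.nan if kl_fu8 is None else kl_fu8,
        "surgery": surgery,
        "surgery_year": np.nan if surgery_year is None else surgery_year,
        "injury_or_surgery_history": int(injury),
        "limited_tibia_view": int(limited_view),
    }


def make_measure_row(
    subject_id: str,
    side: str,
    timepoint: str = "baseline",
    medial_js: float = 5.0,
    lateral_js: float = 6.0,
    **overrides,
) -> dict:
    base = {
        "lateral_js_mm": lateral_js,
        "medial_js_mm": medial_js,
        "intercondylar_mm": 45.0,
        "femur_width_mm": 75.0,
        "prox_tibia_width_mm": 80.0,
        "dist_tibia_width_mm": 33.0,
        "ft_angle_deg": 4.0,
        "vv_angle_deg": 2.0,
    }
    base.update(overrides)
    return {"subject_id": subject_id, "side": side, "timepoint": timepoint, **base}


def build_cohort(subjects: list[dict], knees: list[dict], measures: list[dict]) -> Cohort:
    return Cohort(
        subjects=pd.DataFrame(subjects),
        knees=pd.DataFrame(knees),
        measures=pd.DataFrame(measures, columns=["subject_id", "side", "timepoint", *MEASURE_FIELDS]),
    )


def simple_cohort(n: int = 6, medial_js_delta=()) -> Cohort:
    """n subjects, all healthy, both knees measured at baseline; optional
    per-subject medial-JS left/right offsets to induce asymmetry."""
    subs, knees, meas = [], [], []
    deltas = dict(medial_js_delta)
    for i in range(n):
        sid = f"S{i:03d}"
        subs.append(make_subject(sid))
        d = deltas.get(sid, 0.0)
        for side in ("right", "left"):
            knees.append(make_knee(sid, side))
            mjs = 5.0 + (d / 2.0 if side == "left" else -d / 2.0)
            meas.append(make_measure_row(sid, side, medial_js=mjs))
    return build_cohort(subs, knees, meas)
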