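"""Synthetic cohorts and landmark layouts with known ground truth.

Two roles:

* :func:`construct_landmarks` places a full landmark set that measures back
  to a prescribed :class:`~kneeasym.morphometry.MorphometrySet` exactly (the
  inverse of :func:`~kneeasym.morphometry.measure_knee`), optionally under a
  rotated / translated / mirrored layout.  It is the geometry oracle used by
  the round-trip tests and by the phantom renderer's ground truth.

* :func:`generate_cohort` simulates a bilateral-knee cohort with the
  statistical structure the analysis assumes: correlated left/right knee
  dimensions, per-measure measurement noise at intra-rater magnitudes,
  demographics (age 45-67 at baseline, sex, height, weight history),
  Kellgren-Lawrence grades at baseline and 8-year follow-up, and a logistic
  outcome model linking the *measured* baseline medial joint-space asymmetry
  to radiographic OA at follow-up.  A hidden truth ledger accompanies the
  emitted tables so pipeline estimates can be checked against the generating
  parameters.

Population means and spreads of the knee dimensions are configuration
defaults chosen as anatomically plausible round numbers; they are NOT taken
from any cohort dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, ConstructionError
from .morphometry import (
    MEASURE_FIELDS,
    LandmarkSet,
    MorphometrySet,
    PixelSpacing,
    asymmetry,
)

__all__ = [
    "LayoutConfig",
    "CohortConfig",
    "SyntheticCohort",
    "construct_landmarks",
    "generate_cohort",
    "generate_repeat_measurements",
    "DEFAULT_POPULATION",
    "DEFAULT_NOISE_REL_SD",
    "DEFAULT_NOISE_ABS_SD",
]

_DIM_FIELDS = MEASURE_FIELDS[:6]
_ANGLE_FIELDS = MEASURE_FIELDS[6:]

#: (mean, sd, left-right correlation) per measure.  Config defaults, not
#: estimates from any dataset.
DEFAULT_POPULATION: dict[str, tuple[float, float, float]] = {
    "lateral_js_mm": (6.0, 0.9, 0.90),
    "medial_js_mm": (5.0, 0.8, 0.90),
    "intercondylar_mm": (45.0, 3.0, 0.95),
    "femur_width_mm": (75.0, 4.0, 0.97),
    "prox_tibia_width_mm": (80.0, 4.5, 0.97),
    "dist_tibia_width_mm": (33.0, 3.0, 0.95),
    "ft_angle_deg": (4.0, 2.0, 0.85),
    "vv_angle_deg": (2.0, 1.5, 0.85),
}

#: Relative (fractional) measurement-noise sd per dimension, at the reported
#: intra-rater variability magnitudes.
DEFAULT_NOISE_REL_SD: dict[str, float] = {
    "lateral_js_mm": 0.0496,
    "medial_js_mm": 0.0613,
    "intercondylar_mm": 0.0162,
    "femur_width_mm": 0.0094,
    "prox_tibia_width_mm": 0.0126,
    "dist_tibia_width_mm": 0.0233,
}

#: Additive measurement-noise sd (degrees) for the two angles, at the
#: reported intra-rater absolute-difference magnitudes.
DEFAULT_NOISE_ABS_SD: dict[str, float] = {
    "ft_angle_deg": 0.38,
    "vv_angle_deg": 0.79,
}


# ---------------------------------------------------------------------------
# landmark constructor (inverse of measure_knee)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutConfig:
    """Geometric layout for constructing a landmark set from target measures.

    ``joint_center_mm`` is the midpoint of the condylar tangent in mm space;
    ``rotation_deg`` rotates the whole layout about it (|rotation| < 60);
    ``mirror`` reflects the layout in x (producing the contralateral
    orientation).  ``femoral_axis_levels_mm`` are the two heights above the
    condylar tangent at which the femoral shaft margin pairs sit; the tibial
    levels are fixed at 1 cm / 10 cm below the plateau by definition.
    """

    joint_center_mm: tuple[float, float] = (110.0, 120.0)
    rotation_deg: float = 0.0
    mirror: bool = False
    fossa_offset_mm: float = 20.0
    femoral_axis_levels_mm: tuple[float, float] = (10.0, 100.0)
    shaft_width_mm: float = 30.0
    edge_margin_mm: float = 5.0


def construct_landmarks(
    measures: MorphometrySet,
    knee_side: str = "right",
    layout: LayoutConfig | None = None,
    spacing: PixelSpacing | None = None,
) -> LandmarkSet:
    """Place landmarks so that ``measure_knee`` returns ``measures`` exactly.

    Deterministic given the layout.  Raises :class:`ConstructionError` for
    geometrically unrealizable measure combinations (non-positive lengths,
    joint space >= femur width, angles outside (-90, 90), extreme rotation).
    """
    layout = layout or LayoutConfig()
    spacing = spacing or PixelSpacing(0.2, 0.2)
    m = measures

    for name in _DIM_FIELDS:
        if not getattr(m, name) > 0:
            raise ConstructionError(f"{name} must be > 0 to construct landmarks")
    for name in _ANGLE_FIELDS:
        if not -90.0 < getattr(m, name) < 90.0:
            raise ConstructionError(f"{name} must lie in (-90, 90)")
    if max(m.medial_js_mm, m.lateral_js_mm) >= m.femur_width_mm:
        raise ConstructionError("joint space must be smaller than femur width")
    if abs(layout.rotation_deg) >= 60.0:
        raise ConstructionError("|rotation_deg| must be < 60")
    a1, a2 = layout.femoral_axis_levels_mm
    if not 0 < a1 < a2:
        raise ConstructionError("femoral_axis_levels_mm must be increasing and positive")

    cx, y0 = layout.joint_center_mm
    side_sign = 1.0 if knee_side == "right" else -1.0
    ms = side_sign  # medial compartment toward the image midline
    mirror_sign = -1.0 if layout.mirror else 1.0
    ss_build = side_sign * mirror_sign
    phi = math.radians(layout.rotation_deg)

    theta_t = -math.radians(m.ft_angle_deg) * ss_build
    theta_f = theta_t + math.radians(m.vv_angle_deg) * ss_build

    # Condylar span: the intercondylar distance is mediolateral-only, so the
    # span must be solved against the layout's mirror/rotation to make the
    # measured x-separation of the centerlines equal the target.
    dy_mean = (m.lateral_js_mm - m.medial_js_mm) / 2.0
    k = mirror_sign * ms
    span = None
    for sign in (1.0, -1.0):
        cand = (sign * m.intercondylar_mm - math.sin(phi) * dy_mean) / (k * math.cos(phi))
        if cand > 0:
            span = cand
            break
    if span is None:
        raise ConstructionError("cannot realize intercondylar distance under this layout")

    x_med = cx + ms * span / 2.0
    x_lat = cx - ms * span / 2.0
    yp = y0 + (m.medial_js_mm + m.lateral_js_mm) / 2.0  # plateau reference

    def tib_axis_x(y: float) -> float:
        return cx + (y - (yp + 10.0)) * math.tan(theta_t)

    def fem_axis_x(y: float) -> float:
        return cx + (y - y0) * math.tan(theta_f)

    pts: dict[str, tuple[float, float]] = {
        "medial_js_femur": (x_med, y0),
        "medial_js_tibia": (x_med, y0 + m.medial_js_mm),
        "lateral_js_femur": (x_lat, y0),
        "lateral_js_tibia": (x_lat, y0 + m.lateral_js_mm),
        "fossa_top": (cx, y0 - layout.fossa_offset_mm),
        "femur_margin_medial": (cx + ms * m.femur_width_mm / 2.0, y0 - layout.fossa_offset_mm),
        "femur_margin_lateral": (cx - ms * m.femur_width_mm / 2.0, y0 - layout.fossa_offset_mm),
    }
    for level, dist_mm, width in (
        ("1cm", 10.0, m.prox_tibia_width_mm),
        ("10cm", 100.0, m.dist_tibia_width_mm),
    ):
        xc = tib_axis_x(yp + dist_mm)
        pts[f"tibia_margin_medial_{level}"] = (xc + ms * width / 2.0, yp + dist_mm)
        pts[f"tibia_margin_lateral_{level}"] = (xc - ms * width / 2.0, yp + dist_mm)
    for level, above in (("1cm", a1), ("10cm", a2)):
        y = y0 - above
        xc = fem_axis_x(y)
        pts[f"femur_shaft_margin_medial_{level}"] = (xc + ms * layout.shaft_width_mm / 2.0, y)
        pts[f"femur_shaft_margin_lateral_{level}"] = (xc - ms * layout.shaft_width_mm / 2.0, y)

    # mirror about the joint center, then rotate about it
    names = list(pts)
    xy = np.array([pts[n] for n in names], dtype=float)
    center = np.array([cx, y0])
    rel = xy - center
    if layout.mirror:
        rel[:, 0] = -rel[:, 0]
    if phi != 0.0:
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        rel = rel @ rot.T
    xy = rel + center

    # shift into the positive quadrant with a safety margin
    shift = np.maximum(layout.edge_margin_mm - xy.min(axis=0), 0.0)
    xy = xy + shift

    px = xy / np.array([spacing.col_mm, spacing.row_mm])
    return LandmarkSet(
        knee_side=knee_side,
        spacing=spacing,
        points={n: (float(p[0]), float(p[1])) for n, p in zip(names, px)},
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for advanced radiographic OA at 8-year follow-up.

    ``log p/(1-p) = intercept + log_or * [asym >= threshold]
                    + age_coef * (age - 56) + bmi_coef * (BMI - 27.5)``

    where ``asym`` is the subject's measured baseline medial joint-space
    asymmetry (a fraction).
    """

    intercept: float = -2.4
    threshold: float = 0.10
    log_or: float = math.log(2.0)
    age_coef: float = 0.04
    bmi_coef: float = 0.06


@dataclass(frozen=True)
class ProgressionModel:
    """Mean (and sd) 8-year joint-space narrowing in mm per outcome group."""

    medial_narrowing: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"KL01": (0.15, 0.10), "KL2": (0.5, 0.2), "OA": (1.8, 0.4)}
    )
    lateral_narrowing: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"KL01": (0.10, 0.08), "KL2": (0.3, 0.15), "OA": (0.9, 0.3)}
    )
    vv_reduction: dict[str, float] = field(
        default_factory=lambda: {"KL01": 0.25, "KL2": 0.30, "OA": 0.45}
    )
    implant_prob_given_oa: float = 0.12


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of the synthetic cohort generator."""

    n_subjects: int = 1000
    seed: int = 0
    female_fraction: float = 0.68
    age_range: tuple[float, float] = (45.0, 67.0)
    height_mm_by_sex: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (1760.0, 70.0), "female": (1630.0, 65.0)}
    )
    weight_kg_by_sex: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (85.0, 13.0), "female": (72.0, 13.0)}
    )
    n_followup_years: int = 8
    weight_drift_sd_per_year: float = 0.8
    weight_visit_sd: float = 1.0
    population: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION)
    )
    noise_rel_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_REL_SD))
    noise_abs_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_ABS_SD))
    baseline_kl_probs: tuple[float, ...] = (0.42, 0.33, 0.22, 0.025, 0.005)
    kl_side_diff_probs: tuple[float, ...] = (0.015, 0.135, 0.70, 0.135, 0.015)  # delta -2..2
    injury_history_prob: float = 0.05
    limited_view_prob: float = 0.01
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    progression: ProgressionModel = field(default_factory=ProgressionModel)
    fu_kl_missing_prob: float = 0.12
    fu_radiograph_prob: float = 0.95
    nonoa_kl_progress_prob: float = 0.25

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        probs = [
            self.female_fraction,
            self.injury_history_prob,
            self.limited_view_prob,
            self.fu_kl_missing_prob,
            self.fu_radiograph_prob,
            self.nonoa_kl_progress_prob,
            self.progression.implant_prob_given_oa,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        for dist in (self.baseline_kl_probs, self.kl_side_diff_probs):
            if abs(sum(dist) - 1.0) > 1e-9 or any(p < 0 for p in dist):
                raise ConfigError("categorical probabilities must be non-negative and sum to 1")
        for name, (mean, sd, rho) in self.population.items():
            if sd < 0:
                raise ConfigError(f"population sd for {name} must be >= 0")
            if not -1.0 <= rho <= 1.0:
                raise ConfigError(f"left-right correlation for {name} must lie in [-1, 1]")
        if any(s < 0 for s in self.noise_rel_sd.values()):
            raise ConfigError("noise_rel_sd values must be >= 0")
        if any(s < 0 for s in self.noise_abs_sd.values()):
            raise ConfigError("noise_abs_sd values must be >= 0")
        for grp_map in (self.progression.medial_narrowing, self.progression.lateral_narrowing):
            for grp in ("KL01", "KL2", "OA"):
                if grp not in grp_map:
                    raise ConfigError(f"progression model missing group {grp!r}")


@dataclass
class SyntheticCohort:
    """Generated cohort tables plus the hidden truth ledger."""

    subjects: pd.DataFrame
    knees: pd.DataFrame
    measures: pd.DataFrame
    subject_truth: pd.DataFrame
    knee_truth: pd.DataFrame
    config: CohortConfig

    def write(self, outdir) -> None:
        """Write subjects.csv / knees.csv / measures.csv (+ truth.json)."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.knees.to_csv(out / "knees.csv", index=False)
        self.measures.to_csv(out / "measures.csv", index=False)
        truth = {
            "subject_truth": self.subject_truth.to_dict(orient="list"),
            "knee_truth": self.knee_truth.to_dict(orient="list"),
        }
        (out / "truth.json").write_text(json.dumps(truth, sort_keys=True))


def _bivariate(rng: np.random.Generator, mean: float, sd: float, rho: float, n: int):
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    left = mean + sd * z1
    right = mean + sd * (rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2)
    return left, right


def _apply_noise(rng: np.random.Generator, cfg: CohortConfig, true_vals: dict[str, np.ndarray]):
    """Measurement model: multiplicative log-normal for dimensions (positive,
    median-unbiased), additive normal for angles."""
    noisy = {}
    for name in _DIM_FIELDS:
        s = cfg.noise_rel_sd.get(name, 0.0)
        noisy[name] = true_vals[name] * np.exp(s * rng.standard_normal(true_vals[name].shape))
    for name in _ANGLE_FIELDS:
        s = cfg.noise_abs_sd.get(name, 0.0)
        noisy[name] = true_vals[name] + s * rng.standard_normal(true_vals[name].shape)
    return noisy


def _asym_arr(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    denom = np.abs((left + right) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(np.abs(left) - np.abs(right)) / denom
    out[denom == 0.0] = np.nan
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a bilateral cohort; deterministic given ``config.seed``."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    subject_id = np.array([f"S{i:05d}" for i in range(n)])
    sex = np.where(rng.random(n) < cfg.female_fraction, "female", "male")
    age = rng.uniform(*cfg.age_range, size=n)
    height = np.empty(n)
    weight0 = np.empty(n)
    for s in ("male", "female"):
        mask = sex == s
        hm, hs = cfg.height_mm_by_sex[s]
        wm, ws = cfg.weight_kg_by_sex[s]
        height[mask] = rng.normal(hm, hs, mask.sum())
        weight0[mask] = rng.normal(wm, ws, mask.sum())
    height = np.clip(height, 1350.0, 2100.0)
    weight0 = np.clip(weight0, 40.0, 180.0)
    bmi = weight0 / (height / 1000.0) ** 2

    drift = rng.normal(0.0, cfg.weight_drift_sd_per_year, n)
    steps = drift[:, None] + rng.normal(0.0, cfg.weight_visit_sd, (n, cfg.n_followup_years))
    weights = np.concatenate([weight0[:, None], weight0[:, None] + np.cumsum(steps, axis=1)], axis=1)
    weights = np.clip(weights, 35.0, 200.0)

    subjects = pd.DataFrame({"subject_id": subject_id, "sex": sex, "age_baseline": age, "height_mm": height})
    for t in range(cfg.n_followup_years + 1):
        subjects[f"weight_y{t}"] = weights[:, t]

    # true baseline geometry, bilateral
    true_l: dict[str, np.ndarray] = {}
    true_r: dict[str, np.ndarray] = {}
    for name in MEASURE_FIELDS:
        mean, sd, rho = cfg.population[name]
        left, right = _bivariate(rng, mean, sd, rho, n)
        if name in _DIM_FIELDS:
            left = np.clip(left, 0.05 * mean, None)
            right = np.clip(right, 0.05 * mean, None)
        true_l[name] = left
        true_r[name] = right

    meas_l = _apply_noise(rng, cfg, true_l)
    meas_r = _apply_noise(rng, cfg, true_r)

    # baseline KL grades, correlated between sides
    kl_a = rng.choice(len(cfg.baseline_kl_probs), size=n, p=cfg.baseline_kl_probs)
    delta = rng.choice(np.arange(-2, 3), size=n, p=cfg.kl_side_diff_probs)
    kl_b_side = np.clip(kl_a + delta, 0, 4)
    swap = rng.random(n) < 0.5
    kl_left = np.where(swap, kl_a, kl_b_side)
    kl_right = np.where(swap, kl_b_side, kl_a)

    injury = rng.random(n) < cfg.injury_history_prob
    limited = rng.random(n) < cfg.limited_view_prob

    # outcome model on the measured baseline medial JS asymmetry
    om = cfg.outcome
    true_asym = _asym_arr(true_l["medial_js_mm"], true_r["medial_js_mm"])
    meas_asym = _asym_arr(meas_l["medial_js_mm"], meas_r["medial_js_mm"])
    exposed = meas_asym >= om.threshold
    p_oa = expit(om.intercept + om.log_or * exposed + om.age_coef * (age - 56.0) + om.bmi_coef * (bmi - 27.5))
    oa = rng.random(n) < p_oa

    # which knee carries the OA outcome: the one with the smaller measured medial JS
    oa_knee_left = meas_l["medial_js_mm"] <= meas_r["medial_js_mm"]

    prog = cfg.progression
    surgery_u = rng.random(n)
    surgery_type_u = rng.random(n)
    surgery_year = rng.integers(3, cfg.n_followup_years + 1, n)
    oa_kl4_u = rng.random(n)
    kl_missing_u = rng.random((n, 2))
    progress_u = rng.random((n, 2))
    surgery_kl_missing_u = rng.random(n)
    fu_radiograph_u = rng.random((n, 2))

    knee_rows = []
    for j, side in enumerate(("right", "left")):
        kl_b = kl_right if side == "right" else kl_left
        is_oa_knee = oa & (oa_knee_left == (side == "left"))
        has_surgery = is_oa_knee & (surgery_u < prog.implant_prob_given_oa)
        surgery = np.where(has_surgery, np.where(surgery_type_u < 0.8, "TKA", "PKA"), "none")

        kl_fu = np.minimum(kl_b + (progress_u[:, j] < cfg.nonoa_kl_progress_prob), 2)
        kl_fu = np.maximum(kl_fu, kl_b)  # baseline-severe knees stay severe
        kl_fu = np.where(is_oa_knee & ~has_surgery, np.where(oa_kl4_u < 0.3, 4, 3), kl_fu)
        kl_fu = kl_fu.astype(float)
        missing = (kl_missing_u[:, j] < cfg.fu_kl_missing_prob) & ~has_surgery
        kl_fu[missing] = np.nan
        kl_fu[has_surgery & (surgery_kl_missing_u < 0.5)] = np.nan
        kl_fu[has_surgery & (surgery_kl_missing_u >= 0.5)] = 4.0

        has_fu = (fu_radiograph_u[:, j] < cfg.fu_radiograph_prob) | has_surgery
        knee_rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "side": side,
                    "kl_baseline": kl_b,
                    "kl_fu8": kl_fu,
                    "surgery": surgery,
                    "surgery_year": np.where(has_surgery, surgery_year, np.nan),
                    "injury_or_surgery_history": injury.astype(int),
                    "limited_tibia_view": limited.astype(int),
                    "has_fu_radiograph": has_fu.astype(int),
                    "_is_oa_knee": is_oa_knee,
                }
            )
        )
    knees = pd.concat(knee_rows, ignore_index=True)

    # follow-up true geometry and measured values
    def _fu_true(true_vals: dict[str, np.ndarray], side: str) -> dict[str, np.ndarray]:
        sub = knees[knees["side"] == side].set_index("subject_id").loc[subject_id]
        grp = np.where(
            sub["_is_oa_knee"].to_numpy() | (sub["kl_fu8"].to_numpy() >= 3),
            "OA",
            np.where(sub["kl_fu8"].to_numpy() == 2, "KL2", "KL01"),
        )
        fu = {}
        for name, table in (
            ("medial_js_mm", prog.medial_narrowing),
            ("lateral_js_mm", prog.lateral_narrowing),
        ):
            narrowing = np.zeros(n)
            for g, (mu, sd) in table.items():
                mask = grp == g
                narrowing[mask] = np.clip(rng.normal(mu, sd, mask.sum()), 0.0, None)
            fu[name] = np.clip(true_vals[name] - narrowing, 0.2, None)
        fu["intercondylar_mm"] = true_vals["intercondylar_mm"] * (1.0 + rng.normal(0.010, 0.005, n))
        fu["femur_width_mm"] = true_vals["femur_width_mm"] * (1.0 - rng.normal(0.010, 0.005, n))
        fu["prox_tibia_width_mm"] = true_vals["prox_tibia_width_mm"] * (1.0 - rng.normal(0.005, 0.004, n))
        fu["dist_tibia_width_mm"] = true_vals["dist_tibia_width_mm"] * (1.0 + rng.normal(0.005, 0.004, n))
        fu["ft_angle_deg"] = true_vals["ft_angle_deg"] + rng.normal(0.0, 0.3, n)
        red = np.array([prog.vv_reduction[g] for g in grp])
        fu["vv_angle_deg"] = true_vals["vv_angle_deg"] * (1.0 - red) + rng.normal(0.0, 0.3, n)
        return fu

    fu_true_r = _fu_true(true_r, "right")
    fu_true_l = _fu_true(true_l, "left")
    fu_meas_r = _apply_noise(rng, cfg, fu_true_r)
    fu_meas_l = _apply_noise(rng, cfg, fu_true_l)

    measure_rows = []
    for side, bl, fu in (("right", meas_r, fu_meas_r), ("left", meas_l, fu_meas_l)):
        base = pd.DataFrame({"subject_id": subject_id, "side": side, "timepoint": "baseline"})
        for name in MEASURE_FIELDS:
            base[name] = bl[name]
        measure_rows.append(base)
        has_fu = knees.loc[knees["side"] == side].set_index("subject_id").loc[subject_id, "has_fu_radiograph"].to_numpy().astype(bool)
        fu_df = pd.DataFrame({"subject_id": subject_id[has_fu], "side": side, "timepoint": "fu8"})
        for name in MEASURE_FIELDS:
            fu_df[name] = fu[name][has_fu]
        measure_rows.append(fu_df)
    measures = pd.concat(measure_rows, ignore_index=True)

    subject_truth = pd.DataFrame(
        {
            "subject_id": subject_id,
            "true_medial_js_asym": true_asym,
            "measured_medial_js_asym": meas_asym,
            "exposed": exposed,
            "p_oa": p_oa,
            "oa": oa,
            "bmi_baseline": bmi,
        }
    )
    kt_rows = []
    for side, tl, fu_t in (("right", true_r, fu_true_r), ("left", true_l, fu_true_l)):
        df = pd.DataFrame({"subject_id": subject_id, "side": side})
        for name in MEASURE_FIELDS:
            df[f"true_{name}"] = tl[name]
        df["true_fu_medial_js_mm"] = fu_t["medial_js_mm"]
        kt_rows.append(df)
    knee_truth = pd.concat(kt_rows, ignore_index=True)

    knees = knees.drop(columns=["_is_oa_knee"])
    return SyntheticCohort(
        subjects=subjects,
        knees=knees,
        measures=measures,
        subject_truth=subject_truth,
        knee_truth=knee_truth,
        config=cfg,
    )


def generate_repeat_measurements(
    cohort: SyntheticCohort,
    n_knees: int = 50,
    seed: int = 0,
    repeat_scale: float = 1.0 / math.sqrt(2.0),
) -> list[tuple[MorphometrySet, MorphometrySet]]:
    """Two independent re-measurements of a random subset of knees.

    Each replicate re-applies the measurement-noise model to the knee's true
    baseline geometry at ``repeat_scale`` times the configured sd, so that
    the *difference* of the two replicates has the configured sd (with the
    default scale 1/sqrt(2)).  For a per-replicate sd ``s`` the expected mean
    absolute difference is the folded-normal value ``2*s*mean/sqrt(pi)``.
    """
    cfg = cohort.config
    rng = np.random.default_rng(seed)
    kt = cohort.knee_truth
    idx = rng.choice(len(kt), size=min(n_knees, len(kt)), replace=False)
    sub = kt.iloc[idx]
    true_vals = {name: sub[f"true_{name}"].to_numpy() for name in MEASURE_FIELDS}
    scaled = replace(
        cfg,
        noise_rel_sd={k: v * repeat_scale for k, v in cfg.noise_rel_sd.items()},
        noise_abs_sd={k: v * repeat_scale for k, v in cfg.noise_abs_sd.items()},
    )
    rep1 = _apply_noise(rng, scaled, true_vals)
    rep2 = _apply_noise(rng, scaled, true_vals)
    pairs = []
    for i in range(len(sub)):
        m1 = MorphometrySet(**{name: float(rep1[name][i]) for name in MEASURE_FIELDS})
        m2 = MorphometrySet(**{name: float(rep2[name][i]) for name in MEASURE_FIELDS})
        pairs.append((m1, m2))
    return pairs
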