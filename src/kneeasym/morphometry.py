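"""Geometric morphometry of anterior-posterior knee radiographs.

Eight measures are computed per knee from named 2-D landmark coordinates:
medial/lateral joint-space width, intercondylar distance, femur width at the
top of the intercondylar fossa, proximal (1 cm) and distal (10 cm) tibia
widths, the femur-tibia (FT) angle and the varus-valgus (VV) angle.

Coordinate convention: image pixel coordinates, origin at the top-left
corner, ``x`` mediolateral (columns), ``y`` proximo-distal (rows), ``y``
increasing distally.  All physical quantities are computed after scaling by
the pixel spacing, so anisotropic spacing is handled explicitly (and changes
angles, as it does on a real detector).

The bilateral asymmetry statistic for a measure X is the relative left-right
difference

    X_diff = | |X_left| - |X_right| | / | (X_left + X_right) / 2 |

a dimensionless fraction; it is symmetric in the two sides, invariant under
positive rescaling, zero iff the magnitudes agree, and bounded by 2 for
same-sign inputs.  A zero denominator makes the statistic undefined and is
flagged rather than returned as infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvariantError, MeasurementError

__all__ = [
    "MEASURE_FIELDS",
    "LANDMARK_NAMES",
    "PixelSpacing",
    "LandmarkSet",
    "MorphometrySet",
    "AsymmetryVector",
    "RaterVariabilityReport",
    "joint_space",
    "intercondylar_distance",
    "femur_width",
    "tibia_width",
    "ft_angle",
    "vv_angle",
    "measure_knee",
    "asymmetry",
    "asymmetry_vector",
    "rater_variability",
]

#: Canonical measure order (lengths in mm, angles in signed degrees).
MEASURE_FIELDS = (
    "lateral_js_mm",
    "medial_js_mm",
    "intercondylar_mm",
    "femur_width_mm",
    "prox_tibia_width_mm",
    "dist_tibia_width_mm",
    "ft_angle_deg",
    "vv_angle_deg",
)

#: Landmark names required for a complete measurement of one knee.
LANDMARK_NAMES = (
    "medial_js_femur",
    "medial_js_tibia",
    "lateral_js_femur",
    "lateral_js_tibia",
    "fossa_top",
    "femur_margin_medial",
    "femur_margin_lateral",
    "tibia_margin_medial_1cm",
    "tibia_margin_lateral_1cm",
    "tibia_margin_medial_10cm",
    "tibia_margin_lateral_10cm",
    "femur_shaft_margin_medial_1cm",
    "femur_shaft_margin_lateral_1cm",
    "femur_shaft_margin_medial_10cm",
    "femur_shaft_margin_lateral_10cm",
)


@dataclass(frozen=True)
class PixelSpacing:
    """Physical size of one pixel step.

    Parameters
    ----------
    row_mm : float
        mm per pixel step in the proximo-distal (vertical, row) direction.
    col_mm : float
        mm per pixel step in the mediolateral (horizontal, column) direction.
    """

    row_mm: float
    col_mm: float

    def __post_init__(self) -> None:
        for name in ("row_mm", "col_mm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvariantError(f"PixelSpacing.{name} must be finite and > 0, got {v!r}")

    @property
    def isotropic(self) -> bool:
        return self.row_mm == self.col_mm


@dataclass
class LandmarkSet:
    """Named 2-D image coordinates of one knee plus its pixel spacing.

    ``points`` maps landmark names (see :data:`LANDMARK_NAMES`) to ``(x, y)``
    pixel coordinates (floats; sub-pixel positions are allowed).
    """

    knee_side: str
    spacing: PixelSpacing
    points: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.knee_side not in ("left", "right"):
            raise InvariantError(f"knee_side must be 'left' or 'right', got {self.knee_side!r}")

    # -- access helpers -----------------------------------------------------
    def point_mm(self, name: str) -> np.ndarray:
        """Landmark position in mm, as ``[x_mm, y_mm]``."""
        if name not in self.points:
            raise MeasurementError(f"landmark {name!r} missing from LandmarkSet")
        x, y = self.points[name]
        if not (math.isfinite(x) and math.isfinite(y)):
            raise MeasurementError(f"landmark {name!r} has non-finite coordinates")
        return np.array([x * self.spacing.col_mm, y * self.spacing.row_mm])

    @property
    def side_sign(self) -> float:
        """Sign factor mapping the geometric angle to the varus-positive convention."""
        return 1.0 if self.knee_side == "right" else -1.0

    def validate(self) -> None:
        """Check the structural invariants of a complete landmark set."""
        for name in LANDMARK_NAMES:
            if name not in self.points:
                raise MeasurementError(f"landmark {name!r} missing from LandmarkSet")
            x, y = self.points[name]
            if not (math.isfinite(x) and math.isfinite(y)):
                raise InvariantError(f"landmark {name!r} has non-finite coordinates")
            if x < 0 or y < 0:
                raise InvariantError(f"landmark {name!r} has negative coordinates ({x}, {y})")
        for comp in ("medial", "lateral"):
            if self.points[f"{comp}_js_femur"][1] >= self.points[f"{comp}_js_tibia"][1]:
                raise InvariantError(
                    f"{comp} joint-space pair inverted: femoral point must be proximal "
                    "(smaller y) to the tibial point"
                )
        for side in ("medial", "lateral"):
            if self.points[f"tibia_margin_{side}_10cm"][1] <= self.points[f"tibia_margin_{side}_1cm"][1]:
                raise InvariantError("tibial 10 cm margins must be strictly distal to the 1 cm margins")
            if self.points[f"femur_shaft_margin_{side}_10cm"][1] >= self.points[f"femur_shaft_margin_{side}_1cm"][1]:
                raise InvariantError("femoral 10 cm shaft margins must be strictly proximal to the 1 cm margins")
        for pair in (
            ("femur_margin_medial", "femur_margin_lateral"),
            ("tibia_margin_medial_1cm", "tibia_margin_lateral_1cm"),
            ("tibia_margin_medial_10cm", "tibia_margin_lateral_10cm"),
            ("femur_shaft_margin_medial_1cm", "femur_shaft_margin_lateral_1cm"),
            ("femur_shaft_margin_medial_10cm", "femur_shaft_margin_lateral_10cm"),
        ):
            if self.points[pair[0]][0] == self.points[pair[1]][0]:
                raise InvariantError(f"medial/lateral margins {pair} must be distinct in x")


@dataclass(frozen=True)
class MorphometrySet:
    """The eight dimensions/angles of one knee (mm and signed degrees).

    Angles follow a varus-positive sign convention: a positive value means
    the distal segment deviates medially, on either side.
    """

    lateral_js_mm: float
    medial_js_mm: float
    intercondylar_mm: float
    femur_width_mm: float
    prox_tibia_width_mm: float
    dist_tibia_width_mm: float
    ft_angle_deg: float
    vv_angle_deg: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_FIELDS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in MEASURE_FIELDS])

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "MorphometrySet":
        return cls(**{name: float(d[name]) for name in MEASURE_FIELDS})

    def validate(self) -> None:
        for name in MEASURE_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvariantError(f"{name} is not finite")
            if name.endswith("_mm") and v < 0:
                raise InvariantError(f"{name} must be >= 0, got {v}")
            if name.endswith("_deg") and not (-90.0 < v < 90.0):
                raise InvariantError(f"{name} must lie in (-90, 90), got {v}")
        if max(self.medial_js_mm, self.lateral_js_mm) >= self.femur_width_mm:
            raise InvariantError("joint spaces must be smaller than the femur width")


@dataclass(frozen=True)
class AsymmetryVector:
    """Relative left-right differences, one dimensionless fraction per measure.

    ``undefined[name]`` is True where the mean of the two sides is exactly
    zero (the statistic is then NaN in ``values``).
    """

    values: dict[str, float]
    undefined: dict[str, bool]

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in MEASURE_FIELDS})


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def _distance(landmarks: LandmarkSet, a: str, b: str) -> float:
    p, q = landmarks.point_mm(a), landmarks.point_mm(b)
    return float(np.hypot(*(p - q)))


def _signed_angle_deg(v_from: np.ndarray, v_to: np.ndarray) -> float:
    """Signed angle (degrees) rotating ``v_from`` onto ``v_to`` (ccw positive)."""
    cross = v_from[0] * v_to[1] - v_from[1] * v_to[0]
    dot = float(np.dot(v_from, v_to))
    return math.degrees(math.atan2(cross, dot))


def _tibial_axis(landmarks: LandmarkSet) -> np.ndarray:
    """Distally pointing tibial anatomic axis direction (mm space)."""
    m1 = 0.5 * (landmarks.point_mm("tibia_margin_medial_1cm") + landmarks.point_mm("tibia_margin_lateral_1cm"))
    m10 = 0.5 * (landmarks.point_mm("tibia_margin_medial_10cm") + landmarks.point_mm("tibia_margin_lateral_10cm"))
    axis = m10 - m1
    if np.hypot(*axis) == 0:
        raise MeasurementError("degenerate tibial axis: 1 cm and 10 cm midpoints coincide")
    return axis


def joint_space(landmarks: LandmarkSet, compartment: str) -> float:
    """Joint-space width (mm) of the medial or lateral compartment.

    Anisotropy-corrected Euclidean distance between the paired femoral and
    tibial points on the condyle centerline.
    """
    if compartment not in ("medial", "lateral"):
        raise ValueError(f"compartment must be 'medial' or 'lateral', got {compartment!r}")
    fem, tib = f"{compartment}_js_femur", f"{compartment}_js_tibia"
    for name in (fem, tib):
        if name not in landmarks.points:
            raise MeasurementError(f"joint_space({compartment}): landmark {name!r} missing")
    if landmarks.points[fem][1] > landmarks.points[tib][1]:
        raise InvariantError(
            f"joint_space({compartment}): femoral point must be proximal to the tibial point"
        )
    return _distance(landmarks, fem, tib)


def intercondylar_distance(landmarks: LandmarkSet) -> float:
    """Mediolateral distance (mm) between the medial and lateral condyle centerlines.

    Each centerline x is the mean x of the compartment's femoral and tibial
    joint-space points; the distance is taken along x only, because the
    centerlines are vertical lines.
    """
    xs = {}
    for comp in ("medial", "lateral"):
        for name in (f"{comp}_js_femur", f"{comp}_js_tibia"):
            if name not in landmarks.points:
                raise MeasurementError(f"intercondylar_distance: landmark {name!r} missing")
        xs[comp] = 0.5 * (
            landmarks.points[f"{comp}_js_femur"][0] + landmarks.points[f"{comp}_js_tibia"][0]
        )
    return abs(xs["medial"] - xs["lateral"]) * landmarks.spacing.col_mm


def femur_width(landmarks: LandmarkSet) -> float:
    """Total condylar width (mm) at the level of the top of the intercondylar fossa."""
    for name in ("femur_margin_medial", "femur_margin_lateral"):
        if name not in landmarks.points:
            raise MeasurementError(f"femur_width: landmark {name!r} missing")
    return _distance(landmarks, "femur_margin_medial", "femur_margin_lateral")


def tibia_width(landmarks: LandmarkSet, level: str) -> float:
    """Tibial width (mm) between the outer margins at 1 cm or 10 cm below the plateau."""
    if level not in ("1cm", "10cm"):
        raise ValueError(f"level must be '1cm' or '10cm', got {level!r}")
    a, b = f"tibia_margin_medial_{level}", f"tibia_margin_lateral_{level}"
    for name in (a, b):
        if name not in landmarks.points:
            raise MeasurementError(f"tibia_width({level}): landmark {name!r} missing")
    return _distance(landmarks, a, b)


def ft_angle(landmarks: LandmarkSet) -> float:
    """Femur-tibia angle (signed degrees, varus positive).

    The tibial axis joins the midpoints of the 1 cm and 10 cm tibial margin
    pairs; the femoral axis is the distally pointing perpendicular of the
    condylar tangent through the two femoral joint-space points.  Both axes
    live in mm space, so anisotropic spacing changes the angle.
    """
    for name in ("medial_js_femur", "lateral_js_femur"):
        if name not in landmarks.points:
            raise MeasurementError(f"ft_angle: landmark {name!r} missing")
    tangent = landmarks.point_mm("lateral_js_femur") - landmarks.point_mm("medial_js_femur")
    if np.hypot(*tangent) == 0:
        raise MeasurementError("ft_angle: degenerate condylar tangent (femoral JS points coincide)")
    femoral = np.array([-tangent[1], tangent[0]])
    if femoral[1] < 0 or (femoral[1] == 0 and femoral[0] < 0):
        femoral = -femoral  # point distally
    tibial = _tibial_axis(landmarks)
    return _signed_angle_deg(femoral, tibial) * landmarks.side_sign


def vv_angle(landmarks: LandmarkSet) -> float:
    """Varus-valgus angle (signed degrees, varus positive).

    Angle between the femoral and tibial anatomic axes; the femoral anatomic
    axis joins the midpoints of the two femoral shaft margin pairs.
    """
    mids = []
    for level in ("1cm", "10cm"):
        for side in ("medial", "lateral"):
            name = f"femur_shaft_margin_{side}_{level}"
            if name not in landmarks.points:
                raise MeasurementError(f"vv_angle: landmark {name!r} missing")
        mids.append(
            0.5
            * (
                landmarks.point_mm(f"femur_shaft_margin_medial_{level}")
                + landmarks.point_mm(f"femur_shaft_margin_lateral_{level}")
            )
        )
    femoral = mids[0] - mids[1]  # distal (1 cm) minus proximal (10 cm) -> points distally
    if np.hypot(*femoral) == 0:
        raise MeasurementError("vv_angle: degenerate femoral anatomic axis")
    tibial = _tibial_axis(landmarks)
    return _signed_angle_deg(femoral, tibial) * landmarks.side_sign


def measure_knee(landmarks: LandmarkSet) -> MorphometrySet:
    """All eight measures of one knee; deterministic given the landmark set.

    The landmark set is validated first, so a missing or inconsistent point
    is reported by name before any measure is computed.
    """
    landmarks.validate()
    m = MorphometrySet(
        lateral_js_mm=joint_space(landmarks, "lateral"),
        medial_js_mm=joint_space(landmarks, "medial"),
        intercondylar_mm=intercondylar_distance(landmarks),
        femur_width_mm=femur_width(landmarks),
        prox_tibia_width_mm=tibia_width(landmarks, "1cm"),
        dist_tibia_width_mm=tibia_width(landmarks, "10cm"),
        ft_angle_deg=ft_angle(landmarks),
        vv_angle_deg=vv_angle(landmarks),
    )
    m.validate()
    return m


# ---------------------------------------------------------------------------
# asymmetry statistic
# ---------------------------------------------------------------------------

def asymmetry(x_left: float, x_right: float) -> float:
    """Relative left-right difference of a single measure.

    Returns ``||x_left| - |x_right|| / |(x_left + x_right)/2|``; NaN when the
    denominator is exactly zero (undefined asymmetry).
    """
    if not (math.isfinite(x_left) and math.isfinite(x_right)):
        raise ValueError("asymmetry requires finite inputs")
    denom = abs((x_left + x_right) / 2.0)
    if denom == 0.0:
        return math.nan
    return abs(abs(x_left) - abs(x_right)) / denom


def asymmetry_vector(left: MorphometrySet, right: MorphometrySet) -> AsymmetryVector:
    """Element-wise asymmetry over all eight measures.

    Angles enter through their absolute values (the numerator's ``|X|``);
    zero-mean entries are flagged as undefined rather than infinite.
    """
    values: dict[str, float] = {}
    undefined: dict[str, bool] = {}
    for name in MEASURE_FIELDS:
        v = asymmetry(getattr(left, name), getattr(right, name))
        values[name] = v
        undefined[name] = math.isnan(v)
    return AsymmetryVector(values=values, undefined=undefined)


# ---------------------------------------------------------------------------
# intra-rater variability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RaterVariabilityReport:
    """Per-measure repeatability of duplicate measurements of the same knees.

    ``relative_pct`` is the mean absolute difference between repeats divided
    by the grand mean of the measured magnitudes, times 100; ``mean_abs_diff``
    is in the measure's native unit (mm or degrees).
    """

    relative_pct: dict[str, float]
    mean_abs_diff: dict[str, float]
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relative_pct": pd.Series(self.relative_pct),
                "mean_abs_diff": pd.Series(self.mean_abs_diff),
            }
        ).loc[list(MEASURE_FIELDS)]


def rater_variability(
    repeated_measures: Sequence[tuple[MorphometrySet, MorphometrySet]],
) -> RaterVariabilityReport:
    """Repeatability report from paired repeat measurements.

    Each element of ``repeated_measures`` holds two measurements of the same
    knee.  For every measure the mean absolute difference across pairs is
    reported, and the relative variability is that difference divided by the
    mean magnitude of all measured values (x100 to a percentage); magnitudes
    are used so signed angles cannot produce a near-zero or negative
    denominator.
    """
    if len(repeated_measures) < 2:
        raise InsufficientDataError("rater_variability needs at least 2 measurement pairs")
    rel: dict[str, float] = {}
    mad: dict[str, float] = {}
    for name in MEASURE_FIELDS:
        a = np.array([getattr(p[0], name) for p in repeated_measures])
        b = np.array([getattr(p[1], name) for p in repeated_measures])
        diff = float(np.mean(np.abs(a - b)))
        grand = float(np.mean(np.abs(np.concatenate([a, b]))))
        mad[name] = diff
        rel[name] = 0.0 if diff == 0.0 else 100.0 * diff / grand
    return RaterVariabilityReport(relative_pct=rel, mean_abs_diff=mad, n_pairs=len(repeated_measures))
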