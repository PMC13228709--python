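"""Schematic knee-radiograph phantoms and rough landmark detection.

The renderer draws two simplified legs (femoral shaft + condylar blobs,
tibial shaft + plateau) whose geometry realizes a prescribed
:class:`~kneeasym.morphometry.MorphometrySet` per knee, with an
anti-aliased (area-coverage) rasterization so that bone boundaries can be
localized to sub-pixel precision from the intensity profiles.  Anatomical
realism is a non-goal; only the measurement geometry is exact.

The detection stage mirrors a profile-based automation: it recognizes the
two legs from the column-intensity profile, finds the joint-space line as
the darkest band of the row profile, and proposes rough landmark locations
from lateral intensity profiles at the prescribed measurement offsets
(joint line, 1 cm and 10 cm below the plateau, and the femoral shaft
levels).  All thresholds are derived from a two-class split of the
intensity histogram; the midpoint of the background and bone levels is the
edge-crossing level used for sub-pixel interpolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DetectionError, RenderError
from .morphometry import LandmarkSet, MorphometrySet, PixelSpacing
from .synthetic import LayoutConfig, construct_landmarks

__all__ = [
    "RenderConfig",
    "DetectConfig",
    "PhantomImage",
    "LegBox",
    "LegBoxes",
    "render_phantom",
    "detect_legs",
    "detect_joint_line",
    "propose_landmarks",
    "save_phantom",
    "load_phantom",
]


@dataclass(frozen=True)
class RenderConfig:
    """Geometry and intensity configuration of the phantom renderer.

    The canvas default is 1024x1024 px at 0.2 mm isotropic spacing
    (204.8 mm square), the smallest square that holds two anatomically
    sized legs together with the 10 cm tibial level and a femoral shaft
    segment.  ``femoral_axis_levels_mm`` are measured above the condylar
    tangent and are shared with the ground-truth landmark constructor.
    """

    shape: tuple[int, int] = (1024, 1024)  # rows, cols
    spacing: PixelSpacing = field(default_factory=lambda: PixelSpacing(0.2, 0.2))
    background: float = 0.15
    bone: float = 0.85
    noise_sd: float = 0.0
    tangent_y_mm: float = 90.0
    leg_center_frac: tuple[float, float] = (0.27, 0.73)  # right knee, left knee
    fossa_offset_mm: float = 20.0
    femoral_axis_levels_mm: tuple[float, float] = (25.0, 85.0)
    shaft_width_mm: float = 30.0
    shaft_top_above_mm: float = 88.0
    tibia_below_plateau_mm: float = 103.0
    min_notch_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.bone - self.background < 0.2:
            raise RenderError("bone/background contrast must be at least 0.2")


@dataclass(frozen=True)
class DetectConfig:
    """Prescribed measurement offsets used by the landmark proposer.

    These are the a-priori measurement levels (1 cm / 10 cm below the
    plateau, the configured femoral shaft levels), not ground-truth values.
    """

    condyle_slab_above_mm: tuple[float, float] = (4.0, 12.0)
    tibial_levels_mm: tuple[float, float] = (10.0, 100.0)
    femoral_axis_levels_mm: tuple[float, float] = (25.0, 85.0)
    femur_probe_below_fossa_mm: float = 3.0
    dominant_run_frac: float = 0.4
    box_pad_px: int = 6
    min_leg_rows_px: int = 20


@dataclass
class PhantomImage:
    """Rendered phantom with its ground truth.

    ``image`` holds intensities in [0, 1] (higher = more radio-opaque);
    ``ground_truth`` maps knee side to the landmark set the renderer
    realized; ``joint_line_y`` maps side to the reference joint-line row
    (px), midway between the condylar tangent and the mean plateau level.
    """

    image: np.ndarray
    spacing: PixelSpacing
    ground_truth: dict[str, LandmarkSet]
    joint_line_y: dict[str, float]
    config: RenderConfig


@dataclass(frozen=True)
class LegBox:
    """Axis-aligned pixel rectangle, half-open: [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass(frozen=True)
class LegBoxes:
    """The two leg boxes, ordered by x: first = patient's right knee."""

    right: LegBox
    left: LegBox

    def __post_init__(self) -> None:
        if self.right.x1 > self.left.x0:
            raise DetectionError("leg boxes must be disjoint and ordered by x")

    def by_side(self) -> dict[str, LegBox]:
        return {"right": self.right, "left": self.left}


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _paint(
    cov: np.ndarray,
    spacing: PixelSpacing,
    y_top: float,
    y_bot: float,
    xc_fn,
    w_fn,
    ytop_fn=None,
) -> None:
    """Accumulate area-coverage of a vertical band shape into ``cov``.

    The shape occupies, at height y, the x-interval ``xc(y) +/- w(y)/2``,
    between ``max(y_top, ytop(x))`` and ``y_bot`` (mm).  Coverage per pixel
    is the product of the vertical and horizontal overlap fractions, an
    accurate model for near-axis-aligned boundaries.
    """
    dy, dx = spacing.row_mm, spacing.col_mm
    nrows, ncols = cov.shape
    r0 = max(0, int(math.floor(y_top / dy)) - 1)
    r1 = min(nrows, int(math.ceil(y_bot / dy)) + 1)
    if r1 <= r0:
        return
    rows = np.arange(r0, r1)
    ys = (rows + 0.5) * dy
    xc = np.asarray(xc_fn(ys), dtype=float)
    w = np.asarray(w_fn(ys), dtype=float)
    left = xc - w / 2.0
    right = xc + w / 2.0
    c0 = max(0, int(math.floor(left.min() / dx)) - 1)
    c1 = min(ncols, int(math.ceil(right.max() / dx)) + 1)
    if c1 <= c0:
        return
    cols = np.arange(c0, c1)
    xlo = cols * dx
    xhi = xlo + dx
    hcov = np.clip(
        (np.minimum(right[:, None], xhi[None, :]) - np.maximum(left[:, None], xlo[None, :])) / dx,
        0.0,
        1.0,
    )
    ylo = rows * dy
    yhi = ylo + dy
    if ytop_fn is None:
        ytop = np.full(len(cols), y_top)
    else:
        xs = (cols + 0.5) * dx
        ytop = np.maximum(np.asarray(ytop_fn(xs), dtype=float), y_top)
    vcov = np.clip(
        (np.minimum(y_bot, yhi[:, None]) - np.maximum(ytop[None, :], ylo[:, None])) / dy,
        0.0,
        1.0,
    )
    region = cov[r0:r1, c0:c1]
    np.maximum(region, hcov * vcov, out=region)


def render_phantom(
    left: MorphometrySet,
    right: MorphometrySet,
    config: RenderConfig | None = None,
    seed: int | None = None,
) -> PhantomImage:
    """Render a two-leg phantom realizing the given per-knee measures.

    Deterministic given (measures, config, seed); ``seed`` is only used for
    the optional additive Gaussian noise (``config.noise_sd``).
    """
    cfg = config or RenderConfig()
    if cfg.noise_sd > 0 and seed is None:
        raise RenderError("a seed is required when noise_sd > 0")
    nrows, ncols = cfg.shape
    sp = cfg.spacing
    height_mm = nrows * sp.row_mm
    width_mm = ncols * sp.col_mm
    cov = np.zeros(cfg.shape)
    ground_truth: dict[str, LandmarkSet] = {}
    joint_line_y: dict[str, float] = {}

    for m, side, frac in ((right, "right", cfg.leg_center_frac[0]), (left, "left", cfg.leg_center_frac[1])):
        m.validate()
        cx = frac * width_mm
        y0 = cfg.tangent_y_mm
        ms = 1.0 if side == "right" else -1.0
        cw = m.femur_width_mm - m.intercondylar_mm
        notch = 2.0 * m.intercondylar_mm - m.femur_width_mm
        if cw <= 0 or notch < cfg.min_notch_mm:
            raise RenderError(
                f"{side} knee: femur width {m.femur_width_mm:.1f} and intercondylar distance "
                f"{m.intercondylar_mm:.1f} leave no intercondylar notch to render"
            )
        theta_t = -math.radians(m.ft_angle_deg) * ms
        theta_f = theta_t + math.radians(m.vv_angle_deg) * ms
        x_med = cx + ms * m.intercondylar_mm / 2.0
        x_lat = cx - ms * m.intercondylar_mm / 2.0
        yp = y0 + (m.medial_js_mm + m.lateral_js_mm) / 2.0
        y_fossa = y0 - cfg.fossa_offset_mm
        y_shaft_top = y0 - cfg.shaft_top_above_mm
        y_tibia_bot = yp + cfg.tibia_below_plateau_mm
        half_w = max(m.femur_width_mm, m.prox_tibia_width_mm) / 2.0
        if (
            y_shaft_top < 2.0
            or y_tibia_bot > height_mm - 2.0
            or cx - half_w < 2.0
            or cx + half_w > width_mm - 2.0
        ):
            raise RenderError(f"{side} knee geometry does not fit the {nrows}x{ncols} canvas")

        # femoral shaft along the femoral anatomic axis
        _paint(
            cov, sp, y_shaft_top, y_fossa,
            xc_fn=lambda ys, cx=cx, y0=y0, t=theta_f: cx + (ys - y0) * math.tan(t),
            w_fn=lambda ys: np.full(ys.shape, cfg.shaft_width_mm),
        )
        # condyles: flat bottoms on the condylar tangent
        for xcond in (x_med, x_lat):
            _paint(
                cov, sp, y_fossa, y0,
                xc_fn=lambda ys, x=xcond: np.full(ys.shape, x),
                w_fn=lambda ys, w=cw: np.full(ys.shape, w),
            )
        # tibia: plateau line through the two tibial joint-space points,
        # width tapering from the 1 cm to the 10 cm level
        slope = (m.lateral_js_mm - m.medial_js_mm) / (x_lat - x_med)

        def tib_w(ys, yp=yp, pw=m.prox_tibia_width_mm, dw=m.dist_tibia_width_mm):
            t = np.clip((ys - (yp + 10.0)) / 90.0, 0.0, 1.0)
            return pw + (dw - pw) * t

        _paint(
            cov, sp, y0 + min(m.medial_js_mm, m.lateral_js_mm) - 0.5, y_tibia_bot,
            xc_fn=lambda ys, cx=cx, yp=yp, t=theta_t: cx + (ys - (yp + 10.0)) * math.tan(t),
            w_fn=tib_w,
            ytop_fn=lambda xs, x_med=x_med, mjs=m.medial_js_mm, y0=y0, s=slope: y0 + mjs + s * (xs - x_med),
        )

        layout = LayoutConfig(
            joint_center_mm=(cx, y0),
            fossa_offset_mm=cfg.fossa_offset_mm,
            femoral_axis_levels_mm=cfg.femoral_axis_levels_mm,
            shaft_width_mm=cfg.shaft_width_mm,
            edge_margin_mm=0.0,
        )
        gt = construct_landmarks(m, knee_side=side, layout=layout, spacing=sp)
        for name, (x, y) in gt.points.items():
            if not (0 <= x < ncols and 0 <= y < nrows):
                raise RenderError(f"{side} knee: landmark {name} falls outside the canvas")
        ground_truth[side] = gt
        joint_line_y[side] = (y0 + (m.medial_js_mm + m.lateral_js_mm) / 4.0) / sp.row_mm

    img = cfg.background + (cfg.bone - cfg.background) * cov
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return PhantomImage(
        image=img, spacing=sp, ground_truth=ground_truth, joint_line_y=joint_line_y, config=cfg
    )


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _levels(img: np.ndarray) -> tuple[float, float, float]:
    """(background level, bone level, midpoint threshold) from a 2-class split."""
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-6:
        raise DetectionError("image has no intensity contrast")
    otsu = float(threshold_otsu(img))
    bg = float(np.median(img[img < otsu]))
    bone = float(np.median(img[img >= otsu]))
    return bg, bone, (bg + bone) / 2.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_legs(image: PhantomImage, config: DetectConfig | None = None) -> LegBoxes:
    """Recognize the two legs from the column-intensity profile."""
    cfg = config or DetectConfig()
    img = image.image
    nrows, ncols = img.shape
    _, _, th = _levels(img)
    above = img >= th
    col_counts = above.sum(axis=0)
    col_is_leg = col_counts >= cfg.min_leg_rows_px
    runs = _runs(col_is_leg)
    if not runs:
        raise DetectionError("no above-threshold column runs found")
    max_len = max(b - a for a, b in runs)
    dominant = [r for r in runs if r[1] - r[0] >= max(cfg.dominant_run_frac * max_len, 10)]
    if len(dominant) != 2:
        raise DetectionError(
            f"expected two dominant leg runs in the column profile, found {len(dominant)}"
        )
    boxes = []
    for a, b in dominant:
        rows_any = np.flatnonzero(above[:, a:b].any(axis=1))
        y0, y1 = int(rows_any[0]), int(rows_any[-1]) + 1
        boxes.append(
            LegBox(
                x0=int(max(0, a - cfg.box_pad_px)),
                y0=int(max(0, y0 - cfg.box_pad_px)),
                x1=int(min(ncols, b + cfg.box_pad_px)),
                y1=int(min(nrows, y1 + cfg.box_pad_px)),
            )
        )
    return LegBoxes(right=boxes[0], left=boxes[1])


def detect_joint_line(image: PhantomImage, box: LegBox) -> float:
    """Joint-line y (px) from the row-mean intensity profile inside the box.

    The joint gap is the darkest band of the profile within the central half
    of the box.  Both edges of the band are localized at the half-rise
    between the gap level and the neighbouring bone shoulders (sub-pixel
    interpolated) and their midpoint is returned, which makes the estimate
    translation-equivariant and centers it between the condylar tangent and
    the mean plateau level.
    """
    sub = image.image[box.y0 : box.y1, box.x0 : box.x1]
    prof = sub.mean(axis=1)
    if float(prof.max() - prof.min()) < 1e-6:
        raise DetectionError("uniform intensity in box: no joint-line minimum")
    h = len(prof)
    c0, c1 = h // 4, h - h // 4
    i_min = c0 + int(np.argmin(prof[c0:c1]))
    gap = prof[i_min]
    w = max(3, int(round(15.0 / image.spacing.row_mm)))
    up_max = float(prof[max(0, i_min - w) : i_min + 1].max())
    down_max = float(prof[i_min : min(h, i_min + w)].max())
    if min(up_max, down_max) - gap < 1e-6:
        raise DetectionError("no joint-gap band found in the row profile")

    def cross(direction: int, shoulder: float) -> float:
        thr = (gap + shoulder) / 2.0
        j = i_min
        while 0 <= j < h:
            if prof[j] >= thr:
                prev = j - direction
                frac = (thr - prof[prev]) / (prof[j] - prof[prev])
                return prev + direction * frac + 0.5
            j += direction
        raise DetectionError("joint-gap edge not found in box")

    y_up = cross(-1, up_max)
    y_down = cross(+1, down_max)
    return box.y0 + (y_up + y_down) / 2.0


def _cross_up(col: np.ndarray, start: int, th: float) -> float:
    """Scan upward (decreasing index) from ``start`` for the first bone pixel;
    return the sub-pixel y of the boundary (crossing of ``th``)."""
    for j in range(start, -1, -1):
        if col[j] >= th:
            if j == start:
                return j + 0.5
            denom = col[j] - col[j + 1]
            frac = (col[j] - th) / denom if denom > 0 else 0.0
            return j + 0.5 + frac
    raise DetectionError("no bone boundary found scanning upward")


def _cross_down(col: np.ndarray, start: int, th: float) -> float:
    for j in range(start, len(col)):
        if col[j] >= th:
            if j == start:
                return j + 0.5
            denom = col[j] - col[j - 1]
            frac = (col[j] - th) / denom if denom > 0 else 0.0
            return j + 0.5 - frac
    raise DetectionError("no bone boundary found scanning downward")


def _row_edges(img: np.ndarray, row: int, x0: int, x1: int, th: float, what: str) -> tuple[float, float]:
    """Outermost sub-pixel bone-edge crossings of one image row within [x0, x1)."""
    v = img[row, x0:x1]
    above = np.flatnonzero(v >= th)
    if len(above) == 0:
        raise DetectionError(f"no bone edges in row {row} for {what}")
    i, k = int(above[0]), int(above[-1])
    if i == 0 or k == len(v) - 1:
        raise DetectionError(f"bone touches the box edge in row {row} for {what}")
    frac_l = (th - v[i - 1]) / (v[i] - v[i - 1])
    left = x0 + i - 0.5 + frac_l
    frac_r = (th - v[k + 1]) / (v[k] - v[k + 1])
    right = x0 + k + 0.5 + frac_r
    return left, right


def propose_landmarks(
    image: PhantomImage,
    boxes: LegBoxes,
    config: DetectConfig | None = None,
) -> dict[str, LandmarkSet]:
    """Rough landmark proposals for both knees, keyed by side.

    Works from the joint line and lateral intensity profiles at the
    prescribed offsets; bone edges are the outermost threshold crossings per
    row (sub-pixel interpolated) and condyle centerlines are the
    intensity-weighted peaks of the two condylar blobs.
    """
    cfg = config or DetectConfig()
    img = image.image
    sp = image.spacing
    dy, dx = sp.row_mm, sp.col_mm
    bg, _, th = _levels(img)
    out: dict[str, LandmarkSet] = {}

    for side, box in boxes.by_side().items():
        y_joint = detect_joint_line(image, box)
        jrow = int(round(y_joint - 0.5))

        # condyle centerlines from the column profile of a slab above the joint
        s_lo = int(round(y_joint - cfg.condyle_slab_above_mm[1] / dy))
        s_hi = int(round(y_joint - cfg.condyle_slab_above_mm[0] / dy))
        if s_lo < box.y0 or s_hi <= s_lo:
            raise DetectionError(f"{side}: condyle slab outside box")
        slab = img[s_lo:s_hi, box.x0 : box.x1]
        prof = slab.mean(axis=0)
        runs = [r for r in _runs(prof >= th)]
        if len(runs) < 2:
            raise DetectionError(f"{side}: expected two condylar blobs, found {len(runs)}")
        runs.sort(key=lambda r: r[0] - r[1])  # longest first
        runs = sorted(runs[:2])
        centers = []
        for a, b in runs:
            w = np.clip(prof[a:b] - bg, 0.0, None)
            xs = np.arange(a, b) + 0.5
            centers.append(box.x0 + float((xs * w).sum() / w.sum()))
        x_low, x_high = centers
        x_med, x_lat = (x_high, x_low) if side == "right" else (x_low, x_high)

        pts: dict[str, tuple[float, float]] = {}
        plateau_ys = {}
        tangent_ys = {}
        for comp, xcl in (("medial", x_med), ("lateral", x_lat)):
            colj = int(round(xcl - 0.5))
            col = img[box.y0 : box.y1, colj]
            yf = box.y0 + _cross_up(col, jrow - box.y0, th)
            yt = box.y0 + _cross_down(col, jrow - box.y0, th)
            pts[f"{comp}_js_femur"] = (xcl, yf)
            pts[f"{comp}_js_tibia"] = (xcl, yt)
            tangent_ys[comp] = yf
            plateau_ys[comp] = yt

        # fossa top: first bone crossing scanning up the midline notch
        x_mid = (x_med + x_lat) / 2.0
        midcol = img[box.y0 : box.y1, int(round(x_mid - 0.5))]
        y_tan = (tangent_ys["medial"] + tangent_ys["lateral"]) / 2.0
        start = int(round(y_tan - 0.5)) - box.y0 - 2
        y_fossa = box.y0 + _cross_up(midcol, start, th)
        pts["fossa_top"] = (x_mid, y_fossa)

        probe = int(round(y_fossa + cfg.femur_probe_below_fossa_mm / dy))
        lo, hi = _row_edges(img, probe, box.x0, box.x1, th, "femur margins")
        xm, xl = (hi, lo) if side == "right" else (lo, hi)
        pts["femur_margin_medial"] = (xm, y_fossa)
        pts["femur_margin_lateral"] = (xl, y_fossa)

        y_plateau = (plateau_ys["medial"] + plateau_ys["lateral"]) / 2.0
        for level, off in zip(("1cm", "10cm"), cfg.tibial_levels_mm):
            row = int(round(y_plateau + off / dy))
            if not box.y0 <= row < box.y1:
                raise DetectionError(f"{side}: tibial {level} level outside box")
            lo, hi = _row_edges(img, row, box.x0, box.x1, th, f"tibia margins {level}")
            xm, xl = (hi, lo) if side == "right" else (lo, hi)
            pts[f"tibia_margin_medial_{level}"] = (xm, row + 0.5)
            pts[f"tibia_margin_lateral_{level}"] = (xl, row + 0.5)

        for level, off in zip(("1cm", "10cm"), cfg.femoral_axis_levels_mm):
            row = int(round(y_tan - off / dy))
            if not box.y0 <= row < box.y1:
                raise DetectionError(f"{side}: femoral shaft level {level} outside box")
            lo, hi = _row_edges(img, row, box.x0, box.x1, th, f"femur shaft margins {level}")
            xm, xl = (hi, lo) if side == "right" else (lo, hi)
            pts[f"femur_shaft_margin_medial_{level}"] = (xm, row + 0.5)
            pts[f"femur_shaft_margin_lateral_{level}"] = (xl, row + 0.5)

        out[side] = LandmarkSet(knee_side=side, spacing=sp, points=pts)
    return out


# ---------------------------------------------------------------------------
# PNG + JSON sidecar persistence
# ---------------------------------------------------------------------------

def save_phantom(phantom: PhantomImage, prefix) -> tuple[Path, Path]:
    """Write a 16-bit PNG and a JSON sidecar (spacing + ground truth)."""
    import imageio.v3 as iio

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    png = prefix.with_suffix(".png")
    sidecar = prefix.with_suffix(".json")
    iio.imwrite(png, np.round(phantom.image * 65535.0).astype(np.uint16))
    meta = {
        "spacing": {"row_mm": phantom.spacing.row_mm, "col_mm": phantom.spacing.col_mm},
        "joint_line_y": phantom.joint_line_y,
        "ground_truth": {
            side: {"knee_side": ls.knee_side, "points": {k: list(v) for k, v in ls.points.items()}}
            for side, ls in phantom.ground_truth.items()
        },
    }
    sidecar.write_text(json.dumps(meta, sort_keys=True, indent=1))
    return png, sidecar


def load_phantom(prefix) -> PhantomImage:
    import imageio.v3 as iio

    prefix = Path(prefix)
    img = iio.imread(prefix.with_suffix(".png")).astype(float) / 65535.0
    meta = json.loads(prefix.with_suffix(".json").read_text())
    spacing = PixelSpacing(**meta["spacing"])
    gt = {
        side: LandmarkSet(
            knee_side=d["knee_side"],
            spacing=spacing,
            points={k: (float(v[0]), float(v[1])) for k, v in d["points"].items()},
        )
        for side, d in meta["ground_truth"].items()
    }
    return PhantomImage(
        image=img,
        spacing=spacing,
        ground_truth=gt,
        joint_line_y={k: float(v) for k, v in meta["joint_line_y"].items()},
        config=RenderConfig(shape=img.shape, spacing=spacing),
    )
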