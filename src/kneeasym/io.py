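"""File interfaces: landmark tables, morphometry output, DICOM spacing.

Landmark files come in two lossless, round-trippable dialects:

* CSV — one row per landmark: ``subject_id, side, timepoint, point_name,
  x_px, y_px, row_mm, col_mm``;
* JSON — nested: ``{"subjects": [{"subject_id", "knees": [{"side",
  "timepoint", "spacing": {"row_mm", "col_mm"}, "points": {name: [x, y]}}]}]}``.

Morphometry output is a CSV with one row per knee per timepoint; units are
carried in the column names (``*_mm`` / ``*_deg``).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .morphometry import MEASURE_FIELDS, LandmarkSet, MorphometrySet, PixelSpacing

__all__ = [
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_landmarks_json",
    "write_landmarks_json",
    "write_morphometry_csv",
    "read_morphometry_csv",
    "read_dicom_pixel_spacing",
]

LandmarkKey = tuple[str, str, str]  # (subject_id, side, timepoint)

_CSV_COLS = ["subject_id", "side", "timepoint", "point_name", "x_px", "y_px", "row_mm", "col_mm"]


def read_landmarks_csv(path) -> dict[LandmarkKey, LandmarkSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"landmark CSV {path} is missing columns {missing}")
    out: dict[LandmarkKey, LandmarkSet] = {}
    for (sid, side, tp), grp in df.groupby(["subject_id", "side", "timepoint"], sort=True):
        spacings = grp[["row_mm", "col_mm"]].drop_duplicates()
        if len(spacings) != 1:
            raise SchemaError(f"subject {sid!r} {side} {tp}: inconsistent pixel spacing")
        spacing = PixelSpacing(float(spacings.iloc[0, 0]), float(spacings.iloc[0, 1]))
        points = {
            str(r.point_name): (float(r.x_px), float(r.y_px)) for r in grp.itertuples()
        }
        out[(str(sid), str(side), str(tp))] = LandmarkSet(
            knee_side=str(side), spacing=spacing, points=points
        )
    return out


def write_landmarks_csv(landmarks: dict[LandmarkKey, LandmarkSet], path) -> None:
    rows = []
    for (sid, side, tp), ls in sorted(landmarks.items()):
        for name, (x, y) in sorted(ls.points.items()):
            rows.append(
                {
                    "subject_id": sid, "side": side, "timepoint": tp, "point_name": name,
                    "x_px": x, "y_px": y,
                    "row_mm": ls.spacing.row_mm, "col_mm": ls.spacing.col_mm,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)


def read_landmarks_json(path) -> dict[LandmarkKey, LandmarkSet]:
    data = json.loads(Path(path).read_text())
    out: dict[LandmarkKey, LandmarkSet] = {}
    try:
        for subj in data["subjects"]:
            sid = str(subj["subject_id"])
            for knee in subj["knees"]:
                spacing = PixelSpacing(**knee["spacing"])
                out[(sid, str(knee["side"]), str(knee["timepoint"]))] = LandmarkSet(
                    knee_side=str(knee["side"]),
                    spacing=spacing,
                    points={k: (float(v[0]), float(v[1])) for k, v in knee["points"].items()},
                )
    except KeyError as exc:
        raise SchemaError(f"landmark JSON {path}: missing key {exc}") from exc
    return out


def write_landmarks_json(landmarks: dict[LandmarkKey, LandmarkSet], path) -> None:
    subjects: dict[str, list] = {}
    for (sid, side, tp), ls in sorted(landmarks.items()):
        subjects.setdefault(sid, []).append(
            {
                "side": side,
                "timepoint": tp,
                "spacing": {"row_mm": ls.spacing.row_mm, "col_mm": ls.spacing.col_mm},
                "points": {k: list(v) for k, v in sorted(ls.points.items())},
            }
        )
    payload = {"subjects": [{"subject_id": sid, "knees": knees} for sid, knees in subjects.items()]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_morphometry_csv(measures: dict[LandmarkKey, MorphometrySet], path) -> None:
    """One row per knee per timepoint; units in the column names."""
    rows = []
    for (sid, side, tp), m in sorted(measures.items()):
        row = {"subject_id": sid, "side": side, "timepoint": tp}
        row.update(m.as_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=["subject_id", "side", "timepoint", *MEASURE_FIELDS]).to_csv(
        path, index=False
    )


def read_morphometry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("subject_id", "side", "timepoint", *MEASURE_FIELDS) if c not in df.columns]
    if missing:
        raise SchemaError(f"morphometry CSV {path} is missing columns {missing}")
    return df


def read_dicom_pixel_spacing(
    path,
    precedence: tuple[str, ...] = ("ImagerPixelSpacing", "PixelSpacing"),
) -> PixelSpacing:
    """Pixel spacing from a DICOM radiograph header.

    DICOM stores spacing as (row spacing, column spacing) in mm.  For
    projection radiographs, Imager Pixel Spacing (0018,1164) is the spacing
    at the detector and is preferred by default over Pixel Spacing
    (0028,0030), which may be calibrated to some other plane; the precedence
    order is configurable.
    """
    import pydicom

    ds = pydicom.dcmread(path, stop_before_pixels=True, force=True)
    for attr in precedence:
        value = getattr(ds, attr, None)
        if value is not None:
            row, col = (float(v) for v in value)
            return PixelSpacing(row_mm=row, col_mm=col)
    raise SchemaError(f"{path}: none of {precedence} present in the DICOM header")
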