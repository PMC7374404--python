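"""Annotation and detection file I/O.

Three annotation dialects are supported:

* ``generic_csv`` — ``image,left_x,left_y,right_x,right_y`` with 0-based
  pixel coordinates; an absent eye leaves both of its columns empty.
* ``bioid_eye`` — one sidecar text file per image whose data line holds
  four whitespace-separated integers ``LX LY RX RY``; lines starting
  with ``#`` are headers.
* ``json`` — a list of record objects.

Internally everything is 0-based; dialects declaring 1-based coordinates
are converted at the boundary and the original convention is recorded on
the record, since a silent off-by-one in annotations is a real and
documented source of evaluation error at these eye-frame sizes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from .errors import ParseError, ValidationError

Point = Tuple[float, float]

DIALECTS = ("generic_csv", "bioid_eye", "json")


@dataclass(frozen=True)
class AnnotationRecord:
    """Ground-truth eye centres for one image (either eye may be absent)."""

    image: str
    left: Optional[Point] = None
    right: Optional[Point] = None
    convention: str = "0-based"

    def __post_init__(self):
        for p in (self.left, self.right):
            if p is not None and (p[0] < 0 or p[1] < 0):
                raise ValidationError(f"negative coordinate in record {self.image!r}")


@dataclass(frozen=True)
class DetectionRecord:
    """Per-image detection output; invalid frames carry no estimates."""

    image: str
    valid: bool
    reason: str = ""
    left: Optional[Point] = None
    right: Optional[Point] = None
    # eye-frame geometry (x0, y0, width, height) per eye, for S_ED
    left_frame: Optional[Tuple[int, int, int, int]] = None
    right_frame: Optional[Tuple[int, int, int, int]] = None


def _parse_float(token: str, path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: not a number: {token!r}")


def _point_or_none(xs: str, ys: str, path, lineno: int) -> Optional[Point]:
    xs, ys = xs.strip(), ys.strip()
    if xs == "" and ys == "":
        return None
    if xs == "" or ys == "":
        raise ParseError(f"{path}:{lineno}: half-specified coordinate pair")
    return (_parse_float(xs, path, lineno), _parse_float(ys, path, lineno))


def read_annotations(path: str | Path, dialect: str = "generic_csv") -> List[AnnotationRecord]:
    """Parse annotations, normalised to the internal 0-based convention.

    For ``bioid_eye``, ``path`` may be a single sidecar file or a
    directory of ``*.eye`` files (image id = file stem).
    """
    path = Path(path)
    if dialect == "generic_csv":
        return _read_generic_csv(path)
    if dialect == "json":
        return _read_json(path)
    if dialect == "bioid_eye":
        if path.is_dir():
            return [_read_bioid_eye(p) for p in sorted(path.glob("*.eye"))]
        return [_read_bioid_eye(path)]
    raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _read_generic_csv(path: Path) -> List[AnnotationRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1 and row and row[0].strip().lower() == "image":
                continue  # header
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            records.append(
                AnnotationRecord(
                    image=row[0].strip(),
                    left=_point_or_none(row[1], row[2], path, lineno),
                    right=_point_or_none(row[3], row[4], path, lineno),
                )
            )
    return records


def _read_bioid_eye(path: Path) -> AnnotationRecord:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 values LX LY RX RY")
            lx, ly, rx, ry = (_parse_float(t, path, lineno) for t in tokens)
            return AnnotationRecord(image=path.stem, left=(lx, ly), right=(rx, ry))
    raise ParseError(f"{path}: no data line found")


def _read_json(path: Path) -> List[AnnotationRecord]:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}")
    records = []
    for i, obj in enumerate(data):
        offset = 1 if obj.get("convention") == "1-based" else 0
        def pt(key):
            v = obj.get(key)
            return None if v is None else (float(v[0]) - offset, float(v[1]) - offset)
        records.append(AnnotationRecord(image=obj["image"], left=pt("left"), right=pt("right")))
    return records


def write_annotations(
    records: Sequence[AnnotationRecord], path: str | Path, dialect: str = "generic_csv"
) -> None:
    """Write annotations in the given dialect (bioid_eye: one file per record
    into the directory ``path``)."""
    path = Path(path)
    if dialect == "generic_csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", "left_x", "left_y", "right_x", "right_y"])
            for r in records:
                l = r.left or ("", "")
                rt = r.right or ("", "")
                writer.writerow([r.image, l[0], l[1], rt[0], rt[1]])
    elif dialect == "json":
        payload = [
            {"image": r.image, "left": r.left, "right": r.right, "convention": r.convention}
            for r in records
        ]
        Path(path).write_text(json.dumps(payload, indent=2))
    elif dialect == "bioid_eye":
        path.mkdir(parents=True, exist_ok=True)
        for r in records:
            if r.left is None or r.right is None:
                raise ValidationError("bioid_eye dialect requires both eyes")
            (path / f"{r.image}.eye").write_text(
                "#LX LY RX RY\n"
                f"{int(r.left[0])} {int(r.left[1])} {int(r.right[0])} {int(r.right[1])}\n"
            )
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


def read_landmarks(path: str | Path):
    """Read facial landmarks from a JSON file.

    Format: a list of objects ``{"image": id, "n_faces": 1,
    "face_rectangle": [x, y, w, h], "left": [[x, y], ...],
    "right": [[x, y], ...]}``; ``n_faces`` defaults to 1.  Returns a
    mapping from image id to ``(FaceLandmarks | None, n_faces, n_eyes)``.
    """
    from .eye_region import FaceLandmarks

    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}")
    out = {}
    for obj in data:
        eyes = {s: obj[s] for s in ("left", "right") if obj.get(s)}
        lm = None
        if len(eyes) == 2:
            lm = FaceLandmarks(face_rectangle=tuple(obj["face_rectangle"]), eye_points=eyes)
        out[obj["image"]] = (lm, int(obj.get("n_faces", 1)), len(eyes))
    return out


_DET_COLUMNS = [
    "image", "valid", "reason",
    "left_x", "left_y", "right_x", "right_y",
    "left_frame_x", "left_frame_y", "left_frame_w", "left_frame_h",
    "right_frame_x", "right_frame_y", "right_frame_w", "right_frame_h",
]


def write_detections(records: Sequence[DetectionRecord], path: str | Path, format: str = "csv") -> None:
    """Serialise detections with a deterministic column order."""
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_DET_COLUMNS)
            for r in records:
                l = r.left or ("", "")
                rt = r.right or ("", "")
                lf = r.left_frame or ("", "", "", "")
                rf = r.right_frame or ("", "", "", "")
                writer.writerow([r.image, str(r.valid).lower(), r.reason, *l, *rt, *lf, *rf])
    elif format == "json":
        Path(path).write_text(json.dumps([asdict(r) for r in records], indent=2))
    else:
        raise ValidationError(f"unknown detection format {format!r}")


def read_detections(path: str | Path, format: str = "csv") -> List[DetectionRecord]:
    path = Path(path)
    if format == "json":
        data = json.loads(path.read_text())
        return [
            DetectionRecord(
                image=o["image"], valid=o["valid"], reason=o.get("reason", ""),
                left=tuple(o["left"]) if o.get("left") else None,
                right=tuple(o["right"]) if o.get("right") else None,
                left_frame=tuple(o["left_frame"]) if o.get("left_frame") else None,
                right_frame=tuple(o["right_frame"]) if o.get("right_frame") else None,
            )
            for o in data
        ]
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:
                if row != _DET_COLUMNS:
                    raise ParseError(f"{path}:1: unexpected detection header")
                continue
            if not row:
                continue
            def pt(i):
                return _point_or_none(row[i], row[i + 1], path, lineno)
            def frame(i):
                if all(row[j].strip() == "" for j in range(i, i + 4)):
                    return None
                return tuple(int(float(row[j])) for j in range(i, i + 4))
            records.append(
                DetectionRecord(
                    image=row[0], valid=row[1].strip().lower() == "true", reason=row[2],
                    left=pt(3), right=pt(5), left_frame=frame(7), right_frame=frame(11),
                )
            )
    return records
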