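"""End-to-end detection and evaluation plumbing shared by CLI and scripts.

Two detection modes exist: pre-cropped eye-frame images (each file is a
single eye frame; the detection coordinates are frame-local) and full
face images with supplied landmarks (eye frames are cropped first and
estimates mapped back to parent-image coordinates).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from PIL import Image

from .errors import PupillocError, ValidationError
from .eye_region import EyeFrame, FaceLandmarks, crop_eye_frames, to_greyscale, validate_frame
from .io import AnnotationRecord, DetectionRecord
from .kernel_bank import Kernel
from .localiser import DEFAULT_CONFIG, LocaliserConfig, locate_pupil
from .metrics import DEFAULT_THRESHOLDS, EvalReport, FrameGeometry, evaluate

IMAGE_SUFFIXES = (".png", ".pgm", ".jpg", ".jpeg")


def load_image(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode not in ("L", "RGB"):
        img = img.convert("RGB")
    return np.asarray(img)


def detect_eye_frame_image(
    path: str | Path,
    kernel: Optional[Kernel] = None,
    config: LocaliserConfig = DEFAULT_CONFIG,
) -> DetectionRecord:
    """Treat one image file as a single (left) eye frame and localise."""
    path = Path(path)
    arr = to_greyscale(load_image(path))
    h, w = arr.shape
    try:
        est = locate_pupil(EyeFrame(pixels=arr), kernel=kernel, config=config)
    except PupillocError as exc:
        return DetectionRecord(image=path.name, valid=False, reason=exc.reason)
    return DetectionRecord(
        image=path.name,
        valid=True,
        left=(float(est.centre[0]), float(est.centre[1])),
        left_frame=(0, 0, w, h),
    )


def detect_eye_frame_dir(
    images_dir: str | Path,
    kernel: Optional[Kernel] = None,
    config: LocaliserConfig = DEFAULT_CONFIG,
) -> List[DetectionRecord]:
    images_dir = Path(images_dir)
    paths = sorted(p for p in images_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise ValidationError(f"no images found in {images_dir}")
    return [detect_eye_frame_image(p, kernel, config) for p in paths]


def detect_face_dir(
    images_dir: str | Path,
    landmarks_path: str | Path,
    kernel: Optional[Kernel] = None,
    config: LocaliserConfig = DEFAULT_CONFIG,
) -> List[DetectionRecord]:
    """Detect pupils in face images using a JSON landmark file.

    Every image in the landmark file must exist in ``images_dir``;
    images without landmarks are recorded as invalid.
    """
    from .io import read_landmarks

    images_dir = Path(images_dir)
    landmarks = read_landmarks(landmarks_path)
    records = []
    for path in sorted(p for p in images_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES):
        if path.name not in landmarks:
            records.append(DetectionRecord(image=path.name, valid=False, reason="no-landmarks"))
            continue
        lm, n_faces, n_eyes = landmarks[path.name]
        image = load_image(path)
        if lm is None:
            gate = validate_frame(n_faces, n_eyes)
            records.append(DetectionRecord(image=path.name, valid=False, reason=gate.reason))
            continue
        records.append(detect_face(image, lm, image_id=path.name, n_faces=n_faces,
                                   kernel=kernel, config=config))
    return records


def detect_face(
    image: np.ndarray,
    landmarks: Optional[FaceLandmarks],
    image_id: str = "",
    n_faces: int = 1,
    kernel: Optional[Kernel] = None,
    config: LocaliserConfig = DEFAULT_CONFIG,
) -> DetectionRecord:
    """Gate, crop both eye frames, and localise each pupil."""
    n_eyes = len(landmarks.eye_points) if landmarks is not None else 0
    gate = validate_frame(n_faces, n_eyes)
    if not gate.valid:
        return DetectionRecord(image=image_id, valid=False, reason=gate.reason)
    left, right = crop_eye_frames(image, landmarks)
    out: Dict[str, tuple] = {}
    frames: Dict[str, tuple] = {}
    for frame in (left, right):
        try:
            est = locate_pupil(frame, kernel=kernel, config=config)
        except PupillocError as exc:
            return DetectionRecord(image=image_id, valid=False, reason=exc.reason)
        out[frame.side] = (float(est.centre_parent[0]), float(est.centre_parent[1]))
        frames[frame.side] = (frame.offset[0], frame.offset[1], frame.width, frame.height)
    return DetectionRecord(
        image=image_id,
        valid=True,
        left=out["left"],
        right=out["right"],
        left_frame=frames["left"],
        right_frame=frames["right"],
    )


def _geometry(frame: Optional[tuple]) -> Optional[FrameGeometry]:
    if frame is None:
        return None
    x0, y0, w, h = frame
    return FrameGeometry(x_min=x0, y_min=y0, x_max=x0 + w - 1, y_max=y0 + h - 1)


def evaluate_detections(
    detections: Sequence[DetectionRecord],
    annotations: Sequence[AnnotationRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> EvalReport:
    """Join detections with ground truth by image id and score them.

    Fails closed: any annotated image without a detection (or vice
    versa) raises, so a partial report can never look complete.
    """
    ann = {a.image: a for a in annotations}
    det = {d.image: d for d in detections}
    missing = sorted(set(ann) ^ set(det))
    if missing:
        raise ValidationError(f"identifier mismatch between detections and annotations: {missing[:5]}")
    frames = []
    for image in sorted(ann):
        a, d = ann[image], det[image]
        if not d.valid:
            frames.append({"image": image})
            continue
        row: dict = {"image": image}
        for side in ("left", "right"):
            actual = getattr(a, side)
            estimate = getattr(d, side)
            if actual is None or estimate is None:
                continue
            row[f"actual_{side}"] = actual
            row[f"estimate_{side}"] = estimate
            geom = _geometry(getattr(d, f"{side}_frame"))
            if geom is not None:
                row[f"geometry_{side}"] = geom
        frames.append(row)
    return evaluate(frames, thresholds)
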