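"""Frame validity gating and eye-frame extraction from facial landmarks.

A frame is processed only if a landmark backend found exactly one face
and exactly two eyes inside it; the gate is a pure count check scored
0-2.  Eye frames are the axis-aligned bounding boxes of each eye's
landmark points (68-point convention: corners plus eyelid points),
optionally expanded by a margin and clipped to the face rectangle.

Coordinate convention throughout the package: 0-based, x = column
(rightwards), y = row (downwards), pixel-centre addressing.

The landmark detector itself is a pluggable backend: landmarks may come
from a pre-trained external detector, from annotation files, or from the
synthetic generator.  ``side`` labels follow image position for
synthetic data; for real photographs the anatomical left eye appears on
the image right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np

from .errors import ExtractionError, FormatError, ValidationError

#: ITU-R BT.601 luma weights for RGB -> greyscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FaceLandmarks:
    """Facial landmark set for one face.

    ``face_rectangle`` is ``(x, y, width, height)``; ``eye_points`` maps
    side ('left'/'right') to an ``(n, 2)`` array of (x, y) points.
    """

    face_rectangle: Tuple[int, int, int, int]
    eye_points: Mapping[str, np.ndarray]

    def __post_init__(self):
        pts = {k: np.asarray(v, dtype=np.float64).reshape(-1, 2) for k, v in self.eye_points.items()}
        for side, p in pts.items():
            if p.shape[0] == 0:
                raise ValidationError(f"{side} eye has no landmark points")
        object.__setattr__(self, "eye_points", pts)


@dataclass(frozen=True)
class EyeFrame:
    """A greyscale crop around one eye.

    ``pixels``: (h_e, w_e) intensity matrix; ``offset``: (x, y) of the
    crop's top-left corner in the parent image; ``side``: which eye.
    """

    pixels: np.ndarray
    offset: Tuple[int, int] = (0, 0)
    side: str = "left"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("eye frame must be a non-empty 2-D matrix")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def to_parent(self, x: float, y: float) -> Tuple[float, float]:
        """Map an eye-frame coordinate to parent-image coordinates."""
        return x + self.offset[0], y + self.offset[1]


@dataclass(frozen=True)
class ValidityResult:
    score: int
    valid: bool
    reason: str = ""


def validate_frame(faces: int, eyes: int) -> ValidityResult:
    """Score a frame: +1 for exactly one face, +1 more for exactly two eyes.

    Valid iff both hold (score 2).  Invalidity is a result, never an error.
    """
    if faces < 0 or eyes < 0:
        raise ValidationError("counts must be non-negative")
    score = 0
    if faces == 1:
        score += 1
        if eyes == 2:
            score += 1
            return ValidityResult(score=2, valid=True, reason="one face, two eyes")
        return ValidityResult(score=1, valid=False, reason=f"expected 2 eyes, found {eyes}")
    return ValidityResult(score=0, valid=False, reason=f"expected 1 face, found {faces}")


def to_greyscale(image: np.ndarray) -> np.ndarray:
    """Convert an image to a single-channel intensity matrix.

    3-channel input is combined with BT.601 luma weights
    (0.299 R + 0.587 G + 0.114 B) and rounded; 2-D input passes through.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.float64)
    if image.ndim == 3 and image.shape[2] == 3:
        return np.floor(image.astype(np.float64) @ _LUMA + 0.5)
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0].astype(np.float64)
    raise FormatError(f"unsupported image shape {image.shape}; expected HxW or HxWx3")


def crop_eye_frames(
    image: np.ndarray,
    landmarks: FaceLandmarks,
    margin: int = 0,
) -> Tuple[EyeFrame, EyeFrame]:
    """Crop the left and right eye frames from the parent image.

    Each frame is the inclusive bounding box of that eye's landmark
    points, expanded by ``margin`` on all sides and clipped to the face
    rectangle (and the image).  Offsets are recorded so estimates can be
    mapped back to parent-image coordinates.
    """
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    grey = to_greyscale(image)
    h, w = grey.shape
    fx, fy, fw, fh = landmarks.face_rectangle
    # clip window: intersection of face rectangle and image, inclusive bounds
    cx0, cy0 = max(0, fx), max(0, fy)
    cx1, cy1 = min(w - 1, fx + fw - 1), min(h - 1, fy + fh - 1)

    frames = {}
    for side in ("left", "right"):
        pts = landmarks.eye_points[side]
        x0 = int(np.floor(pts[:, 0].min())) - margin
        x1 = int(np.ceil(pts[:, 0].max())) + margin
        y0 = int(np.floor(pts[:, 1].min())) - margin
        y1 = int(np.ceil(pts[:, 1].max())) + margin
        x0, y0 = max(x0, cx0), max(y0, cy0)
        x1, y1 = min(x1, cx1), min(y1, cy1)
        if x1 < x0 or y1 < y0:
            raise ExtractionError(f"{side} eye bounding box is empty after clipping")
        frames[side] = EyeFrame(
            pixels=grey[y0 : y1 + 1, x0 : x1 + 1],
            offset=(x0, y0),
            side=side,
        )
    return frames["left"], frames["right"]
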