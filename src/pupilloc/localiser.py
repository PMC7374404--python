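"""Coarse-to-fine pupil localisation by two-pass template matching.

The eye frame is padded with a rim of white pixels so the iris template
can reach matches at the frame edges (extreme left/right gaze).  A
horizontal pass slides the full-height template one pixel at a time in x
and scores each overlap with the normalized correlation coefficient

    S = sum(K' * E') / sqrt(sum(K'^2) * sum(E'^2))

where K' and E' are the mean-centred template and patch.  Positions
scoring strictly above the 90th percentile of the pass's scores form the
candidate set; their mean x gives the iris-rectangle left edge R_x.  A
second, vertical pass inside that rectangle (template height shrunk to
0.4 of the rectangle height) locates R_y the same way, and the pupil
centre is C = (R_x + w_k // 2, R_y + h_k // 2).

Averaging the above-quantile candidates instead of taking the single
argmax suppresses local maxima in low-resolution frames; the quantile
threshold adapts to illumination because it is relative to the current
frame's own score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from ._util import is_constant, round_half_even
from .errors import LocalisationError, SizingError, ValidationError
from .eye_region import EyeFrame, to_greyscale
from .kernel_bank import (
    DEFAULT_FRACTION,
    Kernel,
    adapt_kernel_horizontal,
    adapt_kernel_vertical,
    default_disc_kernel,
)

WHITE = 255.0


@dataclass(frozen=True)
class LocaliserConfig:
    """Tunable parameters of the matching cascade.

    width_fraction / height_fraction: adaptive template size as a
    fraction of the eye-frame width / iris-rectangle height.
    quantile: percentile (0-100) of the score distribution above which
    stride positions become candidates.
    centred: mean-centre template and patch before correlating (the
    textbook correlation coefficient); ``False`` uses the un-centred
    normalized product.
    pad: pad the frame with a white rim of half the template extent
    before each pass.
    """

    width_fraction: float = DEFAULT_FRACTION
    height_fraction: float = DEFAULT_FRACTION
    quantile: float = 90.0
    centred: bool = True
    pad: bool = True


DEFAULT_CONFIG = LocaliserConfig()


@dataclass(frozen=True)
class MatchScores:
    """Scores of one sliding pass, in unpadded frame coordinates.

    ``positions[i]`` is the template's top-left x (horizontal pass) or
    y (vertical pass) for ``scores[i]``; rim positions are negative or
    beyond ``extent - template`` when the frame was padded.
    """

    scores: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.float64)
        p = np.asarray(self.positions, dtype=np.int64)
        if s.shape != p.shape or s.ndim != 1 or s.size == 0:
            raise ValidationError("scores and positions must be equal-length 1-D")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "positions", p)


@dataclass(frozen=True)
class CandidateSet:
    """Stride positions whose score crossed the quantile threshold."""

    coordinates: np.ndarray
    threshold: float

    @property
    def m_or_n(self) -> int:
        return int(self.coordinates.size)


@dataclass(frozen=True)
class PupilEstimate:
    """Iris rectangle and pupil centre, in eye-frame and parent coords."""

    iris_rect: Tuple[int, int, int, int]  # (R_x, R_y, w_k, h_k_vertical)
    centre: Tuple[int, int]
    centre_parent: Tuple[int, int]
    side: str = "left"


def pad_white(frame: np.ndarray, pad_x: int, pad_y: int) -> np.ndarray:
    """Surround a frame with a rim of white (255) pixels."""
    if pad_x < 0 or pad_y < 0:
        raise ValidationError("padding must be >= 0")
    return np.pad(
        np.asarray(frame, dtype=np.float64),
        ((pad_y, pad_y), (pad_x, pad_x)),
        mode="constant",
        constant_values=WHITE,
    )


def match_score(kernel: Kernel | np.ndarray, patch: np.ndarray, centred: bool = True) -> float:
    """Normalized correlation coefficient between template and patch.

    Returns 0.0 for a zero-variance patch or template (degenerate rule)
    rather than raising, so flat regions never abort a pass.
    """
    k = np.asarray(kernel.pixels if isinstance(kernel, Kernel) else kernel, dtype=np.float64)
    p = np.asarray(patch, dtype=np.float64)
    if k.shape != p.shape:
        raise ValidationError(f"patch shape {p.shape} != kernel shape {k.shape}")
    if centred:
        k = k - k.mean()
        p = p - p.mean()
    denom = np.sqrt((k * k).sum() * (p * p).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((k * p).sum() / denom, -1.0, 1.0))


def _slide(
    frame: np.ndarray, kernel: Kernel, axis: int, pad: bool, centred: bool
) -> MatchScores:
    """One-axis sliding match.  ``axis`` 1 = horizontal (x), 0 = vertical (y)."""
    frame = np.asarray(frame, dtype=np.float64)
    k = kernel.pixels
    if axis == 1:
        if k.shape[0] != frame.shape[0]:
            raise SizingError("horizontal pass needs kernel height == frame height")
        rim = k.shape[1] // 2 if pad else 0
        padded = pad_white(frame, rim, 0)
        span = padded.shape[1] - k.shape[1]
    else:
        if k.shape[1] != frame.shape[1]:
            raise SizingError("vertical pass needs kernel width == frame width")
        rim = k.shape[0] // 2 if pad else 0
        padded = pad_white(frame, 0, rim)
        span = padded.shape[0] - k.shape[0]
    if span < 0:
        raise SizingError("kernel larger than the padded frame")
    positions = np.arange(span + 1) - rim
    scores = np.empty(span + 1, dtype=np.float64)
    for i in range(span + 1):
        if axis == 1:
            patch = padded[:, i : i + k.shape[1]]
        else:
            patch = padded[i : i + k.shape[0], :]
        scores[i] = match_score(kernel, patch, centred=centred)
    return MatchScores(scores=scores, positions=positions)


def horizontal_pass(
    eye: EyeFrame | np.ndarray, kernel: Kernel, config: LocaliserConfig = DEFAULT_CONFIG
) -> MatchScores:
    """Slide the full-height template across the eye frame in x only."""
    px = eye.pixels if isinstance(eye, EyeFrame) else np.asarray(eye, dtype=np.float64)
    return _slide(px, kernel, axis=1, pad=config.pad, centred=config.centred)


def vertical_pass(
    iris: np.ndarray, kernel: Kernel, config: LocaliserConfig = DEFAULT_CONFIG
) -> MatchScores:
    """Slide the shrunk template down the iris rectangle in y only."""
    return _slide(np.asarray(iris, dtype=np.float64), kernel, axis=0, pad=config.pad, centred=config.centred)


def select_candidates(scores: MatchScores, quantile: float = 90.0) -> CandidateSet:
    """Positions scoring strictly above the q-th percentile of the pass.

    The percentile uses linear interpolation between order statistics.
    If no score is strictly greater (all-tie pathologies), fall back to
    every position attaining the maximum score, so the set is never empty.
    """
    thr = float(np.percentile(scores.scores, quantile))
    mask = scores.scores > thr
    if not mask.any():
        mask = scores.scores == scores.scores.max()
    return CandidateSet(coordinates=scores.positions[mask], threshold=thr)


def aggregate_position(candidates: CandidateSet) -> int:
    """Mean candidate coordinate, rounded half-to-even to a pixel."""
    if candidates.m_or_n == 0:
        raise ValidationError("candidate set is empty")
    return round_half_even(float(candidates.coordinates.mean()))


def iris_rectangle(
    r_x: int, eye: EyeFrame | np.ndarray, kernel: Kernel
) -> Tuple[np.ndarray, int]:
    """Columns [R_x, R_x + w_k) over the full frame height, clipped.

    Returns ``(sub_frame, x0)`` where ``x0`` is the clipped left column.
    """
    px = eye.pixels if isinstance(eye, EyeFrame) else np.asarray(eye, dtype=np.float64)
    w_e = px.shape[1]
    x0 = max(0, r_x)
    x1 = min(w_e, r_x + kernel.width)
    if x1 <= x0:
        raise LocalisationError(
            f"iris rectangle [{r_x}, {r_x + kernel.width}) lies outside the frame",
            reason="iris-out-of-bounds",
        )
    return px[:, x0:x1], x0


def centre_from_rect(r_x: int, r_y: int, w_k: int, h_k_vertical: int) -> Tuple[int, int]:
    """Pupil centre from the matched rectangle: C = R + (k // 2)."""
    return r_x + w_k // 2, r_y + h_k_vertical // 2


def locate_pupil(
    eye: EyeFrame | np.ndarray,
    kernel: Kernel | None = None,
    config: LocaliserConfig = DEFAULT_CONFIG,
) -> PupilEstimate:
    """Run the full cascade on one eye frame.

    Steps: greyscale -> adapt template (height = frame height, width =
    0.4 x frame width) -> white-padded horizontal pass -> quantile
    candidates -> mean x = R_x -> iris rectangle -> adapt template
    (height = 0.4 x rectangle height) -> white-padded vertical pass ->
    mean y = R_y -> centre.  Deterministic for fixed inputs and config.
    """
    if not isinstance(eye, EyeFrame):
        eye = EyeFrame(pixels=to_greyscale(np.asarray(eye)))
    if is_constant(eye.pixels):
        raise LocalisationError(
            "eye frame has constant intensity; no structure to match",
            reason="degenerate-frame",
        )
    if kernel is None:
        kernel = default_disc_kernel()

    k_h = adapt_kernel_horizontal(kernel, eye, config.width_fraction)
    sc_h = horizontal_pass(eye, k_h, config)
    r_x = aggregate_position(select_candidates(sc_h, config.quantile))

    iris, x0 = iris_rectangle(r_x, eye, k_h)
    k_h_pixels = k_h.pixels
    if iris.shape[1] != k_h.width:
        # edge-clipped rectangle: keep the template columns that actually
        # aligned with it at stride R_x, preserving the disc's position
        c0 = x0 - r_x
        k_h_pixels = k_h_pixels[:, c0 : c0 + iris.shape[1]]
    k_v = adapt_kernel_vertical(Kernel(k_h_pixels), iris.shape[0], config.height_fraction)
    sc_v = vertical_pass(iris, k_v, config)
    r_y = aggregate_position(select_candidates(sc_v, config.quantile))

    c_x, c_y = centre_from_rect(r_x, r_y, k_h.width, k_v.height)
    c_x = int(np.clip(c_x, 0, eye.width - 1))
    c_y = int(np.clip(c_y, 0, eye.height - 1))
    px_parent, py_parent = eye.to_parent(c_x, c_y)
    return PupilEstimate(
        iris_rect=(r_x, r_y, k_h.width, k_v.height),
        centre=(c_x, c_y),
        centre_parent=(int(px_parent), int(py_parent)),
        side=eye.side,
    )
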