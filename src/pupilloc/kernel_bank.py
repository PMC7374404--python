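"""Iris template (kernel) construction and adaptive resizing.

The matcher slides a greyscale iris template over the eye frame.  The
template can be built from example iris patches (pixel-wise mean after
resizing every patch to the median patch size) or fall back to an
analytic dark disc on a light field — the geometric prior being that the
iris is approximately circular and dark against the lighter sclera.

Before each matching pass the kernel is resized adaptively: for the
horizontal pass its height is set to the eye-frame height and its width
to a fraction (default 0.4) of the eye-frame width; for the vertical
pass its height becomes the same fraction of the iris-rectangle height
while the width is kept.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TYPE_CHECKING

import numpy as np
from PIL import Image

from ._util import bilinear_resize, is_constant, round_half_up
from .errors import DegenerateKernelError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .eye_region import EyeFrame

#: Default width/height fraction of the adaptive resizing rule.
DEFAULT_FRACTION = 0.4

_DISC_DARK = 20
_DISC_LIGHT = 235


@dataclass(frozen=True)
class Kernel:
    """A greyscale iris template.

    ``pixels`` is a float64 ``(h_k, w_k)`` matrix in [0, 255].  A kernel
    must be non-constant: normalized matching divides by its variance.
    """

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("kernel must be a non-empty 2-D matrix")
        if is_constant(px):
            raise DegenerateKernelError(
                "kernel has zero variance; normalized matching is undefined"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def build_custom_kernel(iris_patches: Sequence[np.ndarray]) -> Kernel:
    """Average example iris patches into a single template.

    Patches are resized to the element-wise median patch dimensions,
    averaged pixel-wise, and rounded half-up to integer intensities.
    """
    if len(iris_patches) == 0:
        raise ValidationError("need at least one iris patch")
    mats = [np.asarray(p, dtype=np.float64) for p in iris_patches]
    for i, m in enumerate(mats):
        if m.ndim != 2 or m.size == 0:
            raise ValidationError(f"patch {i} is empty or not 2-D")
    heights = [m.shape[0] for m in mats]
    widths = [m.shape[1] for m in mats]
    h = round_half_up(float(np.median(heights)))
    w = round_half_up(float(np.median(widths)))
    acc = np.zeros((h, w), dtype=np.float64)
    for m in mats:
        acc += bilinear_resize(m, h, w)
    mean = acc / len(mats)
    rounded = np.floor(mean + 0.5)
    if is_constant(rounded):
        raise DegenerateKernelError("averaged patches produced a constant kernel")
    return Kernel(rounded)


def default_disc_kernel(width: int = 25, height: int = 25) -> Kernel:
    """Analytic fallback template: a dark disc centred on a light field.

    Disc diameter is 0.9 x min(width, height); intensities 20 (disc) and
    235 (field).  Used when no example iris patches are supplied.
    """
    if width < 3 or height < 3:
        raise ValidationError("disc kernel needs width and height >= 3")
    r = 0.45 * min(width, height)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    px = np.full((height, width), float(_DISC_LIGHT))
    px[disc] = float(_DISC_DARK)
    return Kernel(px)


def adapt_kernel_horizontal(
    kernel: Kernel, eye: "EyeFrame | np.ndarray", width_fraction: float = DEFAULT_FRACTION
) -> Kernel:
    """Resize the kernel for the horizontal pass.

    Height becomes the eye-frame height; width becomes
    ``max(1, round(width_fraction * eye width))`` (round half-up).
    """
    if not (0.0 < width_fraction < 1.0):
        raise ValidationError("width_fraction must be in (0, 1)")
    px = eye.pixels if hasattr(eye, "pixels") else np.asarray(eye)
    h_e, w_e = px.shape
    if h_e < 1 or w_e < 1:
        raise ValidationError("eye frame is empty")
    w_k = max(1, round_half_up(width_fraction * w_e))
    return Kernel(bilinear_resize(kernel.pixels, h_e, w_k))


def adapt_kernel_vertical(
    kernel: Kernel, iris_rect_height: int, height_fraction: float = DEFAULT_FRACTION
) -> Kernel:
    """Resize the kernel for the vertical pass.

    Height becomes ``max(1, round(height_fraction * iris_rect_height))``;
    width is unchanged from the horizontal-pass kernel.
    """
    if iris_rect_height < 1:
        raise ValidationError("iris rectangle height must be >= 1")
    h_k = max(1, round_half_up(height_fraction * iris_rect_height))
    return Kernel(bilinear_resize(kernel.pixels, h_k, kernel.width))


def save_kernel(kernel: Kernel, path: str | Path, provenance: dict | None = None) -> None:
    """Write a kernel as PNG/PGM plus a JSON sidecar with provenance."""
    path = Path(path)
    img = np.clip(np.floor(kernel.pixels + 0.5), 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)
    meta = dict(provenance or {})
    meta.setdefault("shape", [kernel.height, kernel.width])
    meta["sha256"] = hashlib.sha256(img.tobytes()).hexdigest()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_kernel(path: str | Path) -> Kernel:
    """Read a kernel image saved by :func:`save_kernel` (sidecar optional)."""
    img = Image.open(path).convert("L")
    return Kernel(np.asarray(img, dtype=np.float64))
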