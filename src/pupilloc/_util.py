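"""Small numeric helpers shared across modules.

Rounding conventions (stated once, used everywhere):

* adapted kernel dimensions use round-half-up, then clamp to >= 1;
* aggregated candidate coordinates use round-half-to-even (bias-free ties);
* Eq.-style centre halves use integer floor division.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero upwards (2.5 -> 3)."""
    return int(np.floor(x + 0.5))


def round_half_even(x: float) -> int:
    """Round to nearest integer, ties to even (10.5 -> 10, 11.5 -> 12)."""
    return int(np.rint(x))


def bilinear_resize(pixels: np.ndarray, height: int, width: int) -> np.ndarray:
    """Resample a 2-D intensity matrix to ``height x width`` bilinearly.

    Resizing to the input's own shape is the identity.  Output is float64
    in the input's intensity range (no rescaling to [0, 1]).
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.shape == (height, width):
        return pixels.copy()
    # prefilter when shrinking so strong downscales keep the template's
    # structure instead of point-sampling a single region
    shrinking = height < pixels.shape[0] or width < pixels.shape[1]
    return _sk_resize(
        pixels,
        (height, width),
        order=1,
        mode="edge",
        anti_aliasing=shrinking,
        preserve_range=True,
    ).astype(np.float64)


def is_constant(pixels: np.ndarray) -> bool:
    pixels = np.asarray(pixels)
    return bool(pixels.size == 0 or np.all(pixels == pixels.flat[0]))
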