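import numpy as np
import pytest

from pupilloc import EyeFrame, SyntheticEyeSpec, render_eye


@pytest.fixture
def clean_eye():
    """A noiseless 60x24 eye frame with the pupil at (30, 12)."""
    sample = render_eye(SyntheticEyeSpec(noise_sigma=0.0, gradient_amplitude=0.0))
    return EyeFrame(pixels=sample.image.astype(float)), sample


def ncc_oracle(kernel: np.ndarray, patch: np.ndarray) -> float:
    """Literal scalar evaluation of the normalized correlation coefficient.

    Independent of the package's matcher: explicit per-pixel loops over
    the mean-centred kernel and patch.
    """
    kh, kw = kernel.shape
    k_mean = sum(float(kernel[i, j]) for i in range(kh) for j in range(kw)) / (kh * kw)
    p_mean = sum(float(patch[i, j]) for i in range(kh) for j in range(kw)) / (kh * kw)
    num = kk = pp = 0.0
    for i in range(kh):
        for j in range(kw):
            kc = float(kernel[i, j]) - k_mean
            pc = float(patch[i, j]) - p_mean
            num += kc * pc
            kk += kc * kc
            pp += pc * pc
    denom = (kk * pp) ** 0.5
    return 0.0 if denom == 0.0 else num / denom


def pass_oracle(frame: np.ndarray, kernel: np.ndarray, axis: int) -> tuple:
    """Brute-force sliding evaluation at every stride of one axis.

    Pads with a white rim of half the kernel extent, then scores each
    overlap with a direct mean-centred correlation (numpy arithmetic,
    but structured as an explicit per-stride double loop independent of
    the package's pass implementation).
    """
    frame = np.asarray(frame, dtype=float)
    kh, kw = kernel.shape
    if axis == 1:
        rim = kw // 2
        padded = np.full((frame.shape[0], frame.shape[1] + 2 * rim), 255.0)
        padded[:, rim : rim + frame.shape[1]] = frame
        n = padded.shape[1] - kw + 1
    else:
        rim = kh // 2
        padded = np.full((frame.shape[0] + 2 * rim, frame.shape[1]), 255.0)
        padded[rim : rim + frame.shape[0], :] = frame
        n = padded.shape[0] - kh + 1
    kc = kernel - kernel.mean()
    scores, positions = [], []
    for s in range(n):
        patch = padded[:, s : s + kw] if axis == 1 else padded[s : s + kh, :]
        pc = patch - patch.mean()
        denom = float(np.sqrt((kc * kc).sum() * (pc * pc).sum()))
        scores.append(0.0 if denom == 0.0 else float((kc * pc).sum()) / denom)
        positions.append(s - rim)
    return np.array(scores), np.array(positions)
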