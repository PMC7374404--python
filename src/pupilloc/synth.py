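"""Synthetic eye-frame rendering with exact ground truth.

Eye frames are drawn as a dark, approximately circular iris with a
darker concentric pupil on a lighter sclera field — the intensity
ordering (pupil <= iris < sclera) the matcher exploits.  The renderer
adds the nuisance factors typical of low-resolution webcam eye crops:
a top eyelid band covering a fraction of the iris, a horizontal
illumination gradient, and additive Gaussian sensor noise clipped to
[0, 255].  Every sample carries its true pupil centre, so the whole
localisation pipeline is testable without any external dataset.

The default sampling distribution spans the low-resolution regime of
benchmark face datasets: frame widths of 24-80 px at a 2.5:1 aspect
ratio, iris radii of 0.12-0.22 x frame width, and gaze offsets uniform
over the span where the iris stays visible.

Discs are rasterised by centre-of-pixel inclusion: a pixel belongs to a
disc iff its centre lies within the radius.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Tuple

import numpy as np
from PIL import Image

from .errors import ValidationError
from .eye_region import FaceLandmarks


@dataclass(frozen=True)
class SyntheticEyeSpec:
    """Full parameterisation of one rendered eye frame.

    Intensities are 8-bit greyscale levels; the invariant
    ``pupil_intensity <= iris_intensity < sclera_intensity`` keeps the
    pupil the darkest region.  ``eyelid_occlusion`` covers that fraction
    of the iris height from the top; ``gradient_amplitude`` is the
    intensity rise across the frame left-to-right; ``noise_sigma`` the
    Gaussian sensor-noise standard deviation.
    """

    frame_width: int = 60
    frame_height: int = 24
    iris_radius: float = 9.0
    pupil_radius: float = 3.6
    centre_x: float = 30.0
    centre_y: float = 12.0
    sclera_intensity: int = 200
    iris_intensity: int = 80
    pupil_intensity: int = 30
    eyelid_occlusion: float = 0.0
    gradient_amplitude: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.frame_width < 1 or self.frame_height < 1:
            raise ValidationError("frame dimensions must be >= 1")
        if not (0 < self.pupil_radius <= self.iris_radius):
            raise ValidationError("need 0 < pupil_radius <= iris_radius")
        if not (self.pupil_intensity <= self.iris_intensity < self.sclera_intensity):
            raise ValidationError(
                "intensity ordering violated: need pupil <= iris < sclera"
            )
        if not (0 <= self.centre_x < self.frame_width and 0 <= self.centre_y < self.frame_height):
            raise ValidationError("pupil centre must lie inside the frame")
        if not (0.0 <= self.eyelid_occlusion <= 1.0):
            raise ValidationError("eyelid_occlusion must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class SyntheticSample:
    """A rendered eye frame with its exact ground-truth pupil centre."""

    image: np.ndarray
    truth_centre: Tuple[float, float]
    spec: SyntheticEyeSpec


def render_eye(spec: SyntheticEyeSpec) -> SyntheticSample:
    """Rasterise one eye frame; deterministic for a fixed spec/seed.

    Layer order: sclera field, iris disc, pupil disc, eyelid band,
    additive horizontal gradient, Gaussian noise, clip to [0, 255].
    """
    spec.validate()
    h, w = spec.frame_height, spec.frame_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    img = np.full((h, w), float(spec.sclera_intensity))

    d2 = (xx - spec.centre_x) ** 2 + (yy - spec.centre_y) ** 2
    img[d2 <= spec.iris_radius**2] = float(spec.iris_intensity)
    img[d2 <= spec.pupil_radius**2] = float(spec.pupil_intensity)

    if spec.eyelid_occlusion > 0:
        # band from the frame top down through the covered iris fraction
        lid_intensity = float(np.clip(spec.sclera_intensity - 25, 0, 255))
        iris_top = spec.centre_y - spec.iris_radius
        cover = iris_top + spec.eyelid_occlusion * (2.0 * spec.iris_radius + 1.0)
        img[yy < cover] = lid_intensity

    if spec.gradient_amplitude != 0 and w > 1:
        img += spec.gradient_amplitude * (xx / (w - 1.0))

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return SyntheticSample(image=img, truth_centre=(spec.centre_x, spec.centre_y), spec=spec)


@dataclass(frozen=True)
class SpecDistribution:
    """Sampling ranges for :func:`generate_dataset` (uniform unless noted).

    Defaults emulate low-resolution benchmark eye crops; gaze offset is
    uniform over the horizontal span where the iris remains visible.
    """

    frame_width: Tuple[int, int] = (24, 80)
    aspect_ratio: float = 2.5  # width : height
    iris_radius_fraction: Tuple[float, float] = (0.12, 0.22)
    pupil_radius_fraction: float = 0.4  # of iris radius
    sclera_intensity: Tuple[int, int] = (170, 230)
    iris_intensity: Tuple[int, int] = (60, 110)
    pupil_offset: Tuple[int, int] = (30, 50)  # iris minus pupil intensity
    eyelid_occlusion: Tuple[float, float] = (0.0, 0.0)
    gradient_amplitude: Tuple[float, float] = (0.0, 20.0)
    noise_sigma: Tuple[float, float] = (0.0, 10.0)
    extreme_gaze: bool = False  # restrict centres to within one iris radius of the l/r edges

    def sample_spec(self, rng: np.random.Generator) -> SyntheticEyeSpec:
        w = int(rng.integers(self.frame_width[0], self.frame_width[1] + 1))
        h = max(4, int(round(w / self.aspect_ratio)))
        r = float(rng.uniform(*self.iris_radius_fraction)) * w
        r = min(r, (h - 1) / 2.0)  # keep the iris visible in short frames
        pr = max(1.0, self.pupil_radius_fraction * r)
        if self.extreme_gaze:
            d = float(rng.uniform(0.0, r))  # distance of centre from an edge
            cx = d if rng.random() < 0.5 else (w - 1) - d
        else:
            cx = float(rng.uniform(r, w - 1 - r))
        cy_lo, cy_hi = r, h - 1 - r
        cy = float(rng.uniform(cy_lo, cy_hi)) if cy_hi > cy_lo else (h - 1) / 2.0
        sclera = int(rng.integers(*self.sclera_intensity))
        iris = int(rng.integers(*self.iris_intensity))
        pupil = max(0, iris - int(rng.integers(*self.pupil_offset)))
        return SyntheticEyeSpec(
            frame_width=w,
            frame_height=h,
            iris_radius=r,
            pupil_radius=pr,
            centre_x=cx,
            centre_y=cy,
            sclera_intensity=sclera,
            iris_intensity=iris,
            pupil_intensity=pupil,
            eyelid_occlusion=float(rng.uniform(*self.eyelid_occlusion)),
            gradient_amplitude=float(rng.uniform(*self.gradient_amplitude)),
            noise_sigma=float(rng.uniform(*self.noise_sigma)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )


DEFAULT_DISTRIBUTION = SpecDistribution()

#: Higher-resolution variant for the CLI ``--profile hires``.
HIRES_DISTRIBUTION = SpecDistribution(frame_width=(80, 200))


def generate_dataset(
    n: int,
    spec_distribution: SpecDistribution = DEFAULT_DISTRIBUTION,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> List[SyntheticSample]:
    """Draw ``n`` independently perturbed eye frames.

    With ``out_dir`` set, writes one PNG per sample plus an
    ``annotations.csv`` ground-truth file in the generic dialect
    (single-eye rows: right-eye columns left empty).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [render_eye(spec_distribution.sample_spec(rng)) for _ in range(n)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "annotations.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", "left_x", "left_y", "right_x", "right_y"])
            for i, s in enumerate(samples):
                name = f"eye_{i:04d}.png"
                Image.fromarray(s.image, mode="L").save(out_dir / name)
                writer.writerow([name, s.truth_centre[0], s.truth_centre[1], "", ""])
    return samples


@dataclass(frozen=True)
class FaceMock:
    """A two-eye (or fewer) face mock-up with landmark ground truth."""

    image: np.ndarray
    landmarks: FaceLandmarks | None
    truth_centres: dict  # side -> (x, y) in parent-image coordinates
    n_faces: int
    n_eyes: int


_EYE_W, _EYE_H = 50, 20
# anthropometric layout: the gap between inner eye corners equals one eye
# width, so the interocular distance is about twice the eye-frame width
_EYE_OFFSETS = {"left": (20, 45), "right": (120, 45)}  # top-left corners


def render_face_mock(
    n_eyes: int = 2,
    seed: int = 0,
    spec_distribution: SpecDistribution | None = None,
) -> FaceMock:
    """Render a simple face-sized frame containing 0, 1 or 2 eye regions.

    Eye regions are 50x20 crops rendered at fixed offsets; landmark
    points are the bounding-box extremes of each eye region, and the
    face counts feed the validity gate (one face whenever any eye is
    present).  Gaze and appearance are perturbed per seed.
    """
    if n_eyes not in (0, 1, 2):
        raise ValidationError("n_eyes must be 0, 1 or 2")
    rng = np.random.default_rng(seed)
    img = np.full((120, 200), 160, dtype=np.uint8)  # skin-tone field
    sides = ["left", "right"][:n_eyes]
    truth = {}
    eye_points = {}
    # each eye is one draw from the default study distribution, fixed at
    # the mock's eye-frame width
    eye_dist = (spec_distribution or DEFAULT_DISTRIBUTION)
    eye_dist = replace(eye_dist, frame_width=(_EYE_W, _EYE_W))
    for side in sides:
        spec = eye_dist.sample_spec(rng)
        cx, cy = spec.centre_x, spec.centre_y
        sample = render_eye(spec)
        ox, oy = _EYE_OFFSETS[side]
        img[oy : oy + _EYE_H, ox : ox + _EYE_W] = sample.image
        truth[side] = (cx + ox, cy + oy)
        eye_points[side] = np.array(
            [
                (ox, oy + _EYE_H // 2),  # left corner
                (ox + _EYE_W - 1, oy + _EYE_H // 2),  # right corner
                (ox + _EYE_W // 2, oy),  # upper eyelid
                (ox + _EYE_W // 2, oy + _EYE_H - 1),  # lower eyelid
            ],
            dtype=np.float64,
        )
    landmarks = None
    if n_eyes == 2:
        landmarks = FaceLandmarks(face_rectangle=(5, 5, 190, 110), eye_points=eye_points)
    return FaceMock(
        image=img,
        landmarks=landmarks,
        truth_centres=truth,
        n_faces=1 if n_eyes >= 1 else 0,
        n_eyes=n_eyes,
    )
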