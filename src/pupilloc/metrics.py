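"""Localisation-error metrics.

Two families of measures are provided:

* Interocular-normalized errors.  With actual centres C_l, C_r and
  estimates C~_l, C~_r, the worst-eye-centre error is

      wec = max(||C~_l - C_l||, ||C~_r - C_r||) / ||C_l - C_r||

  and bec is the analogous minimum.  wec <= 0.05 roughly corresponds to
  an estimate within the pupil diameter; wec <= 0.1 within the iris.

* The standardized Euclidean distance S_ED, which expresses the centre
  error of a single eye as a percentage of its own eye-frame diagonal:

      S_ED = 100 * ||estimate - actual|| / ||(x_max, y_max) - (x_min, y_min)||

  making it independent of image resolution and of the second eye.

Accuracy-vs-threshold curves count the fraction of frames whose error
is <= t for each threshold t, and per-axis summaries report the mean
absolute error and the coefficient of determination R^2 of estimated
against actual coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import hypot
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ValidationError

Point = Tuple[float, float]


@dataclass(frozen=True)
class EyePairTruth:
    """Actual left/right eye centres in parent-image coordinates."""

    left: Point
    right: Point

    def __post_init__(self):
        if self.left == self.right:
            raise ValidationError("interocular distance is zero")

    @property
    def interocular(self) -> float:
        return hypot(self.left[0] - self.right[0], self.left[1] - self.right[1])


@dataclass(frozen=True)
class EyePairEstimate:
    left: Point
    right: Point


@dataclass(frozen=True)
class FrameGeometry:
    """Corners of one eye frame: nearest (x_min, y_min), farthest (x_max, y_max)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValidationError("degenerate frame geometry")

    @property
    def diagonal(self) -> float:
        return hypot(self.x_max - self.x_min, self.y_max - self.y_min)


def _per_eye_distances(truth: EyePairTruth, est: EyePairEstimate) -> Tuple[float, float]:
    dl = hypot(est.left[0] - truth.left[0], est.left[1] - truth.left[1])
    dr = hypot(est.right[0] - truth.right[0], est.right[1] - truth.right[1])
    return dl, dr


def wec(truth: EyePairTruth, est: EyePairEstimate) -> float:
    """Worst-eye-centre relative error (max of the two, interocular-normalized)."""
    dl, dr = _per_eye_distances(truth, est)
    return max(dl, dr) / truth.interocular


def bec(truth: EyePairTruth, est: EyePairEstimate) -> float:
    """Best-eye-centre relative error (min of the two, interocular-normalized)."""
    dl, dr = _per_eye_distances(truth, est)
    return min(dl, dr) / truth.interocular


def s_ed(actual: Point, estimate: Point, geometry: FrameGeometry) -> float:
    """Standardized Euclidean distance: centre error as % of the frame diagonal."""
    err = hypot(estimate[0] - actual[0], estimate[1] - actual[1])
    return 100.0 * err / geometry.diagonal


def accuracy_at_thresholds(
    errors: Sequence[float], thresholds: Sequence[float]
) -> Dict[float, float]:
    """Percent of frames with error <= t, for each threshold t (inclusive)."""
    errs = np.asarray(errors, dtype=np.float64)
    if errs.size == 0:
        raise ValidationError("error list is empty")
    return {float(t): float(100.0 * np.mean(errs <= t)) for t in thresholds}


def regression_fit_stats(
    actual: Sequence[float], estimated: Sequence[float]
) -> Dict[str, float | None]:
    """Per-axis agreement summary: mean absolute error and R^2.

    R^2 = 1 - SS_res / SS_tot of the estimates against the actuals; it
    is reported as None when the actual series has zero variance.
    """
    a = np.asarray(actual, dtype=np.float64)
    e = np.asarray(estimated, dtype=np.float64)
    if a.shape != e.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("need two equal-length series with n >= 2")
    mae = float(np.mean(np.abs(a - e)))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        return {"mae": mae, "r2": None}
    ss_res = float(np.sum((a - e) ** 2))
    return {"mae": mae, "r2": 1.0 - ss_res / ss_tot}


#: Default threshold grid for accuracy curves (0.01 .. 0.25 step 0.01).
DEFAULT_THRESHOLDS = tuple(round(0.01 * k, 2) for k in range(1, 26))


@dataclass
class EvalReport:
    """Per-frame and aggregate evaluation results.

    ``per_frame`` rows hold wec/bec per frame and S_ED/ED per eye;
    aggregates pool both eyes for the per-axis statistics and use the
    per-frame wec/bec for threshold accuracies (pooling choice recorded
    in ``metadata``).
    """

    per_frame: List[dict] = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"metadata": self.metadata, "aggregates": self.aggregates, "per_frame": self.per_frame},
                fh,
                indent=2,
            )

    def to_csv(self, path) -> None:
        import csv as _csv

        cols = sorted({k for row in self.per_frame for k in row})
        with open(path, "w", newline="") as fh:
            writer = _csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            writer.writerows(self.per_frame)


def evaluate(
    frames: Sequence[dict],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> EvalReport:
    """Build an :class:`EvalReport` from per-frame evaluation inputs.

    Each element of ``frames`` is a dict with keys ``image``, and per
    present eye ``actual_<side>``, ``estimate_<side>`` (points) and
    optionally ``geometry_<side>`` (:class:`FrameGeometry`) for S_ED.
    wec/bec are computed only for frames where both eyes are present.
    """
    per_frame: List[dict] = []
    wecs: List[float] = []
    becs: List[float] = []
    ax_actual = {"x": [], "y": []}
    ax_est = {"x": [], "y": []}
    s_eds: List[float] = []
    eds: List[float] = []

    for fr in frames:
        row: dict = {"image": fr.get("image", "")}
        present = [s for s in ("left", "right") if f"actual_{s}" in fr and f"estimate_{s}" in fr]
        for side in present:
            a, e = fr[f"actual_{side}"], fr[f"estimate_{side}"]
            ed = hypot(e[0] - a[0], e[1] - a[1])
            row[f"ed_{side}"] = ed
            eds.append(ed)
            ax_actual["x"].append(a[0])
            ax_actual["y"].append(a[1])
            ax_est["x"].append(e[0])
            ax_est["y"].append(e[1])
            geom = fr.get(f"geometry_{side}")
            if geom is not None:
                val = s_ed(a, e, geom)
                row[f"s_ed_{side}"] = val
                s_eds.append(val)
        if len(present) == 2:
            truth = EyePairTruth(left=tuple(fr["actual_left"]), right=tuple(fr["actual_right"]))
            est = EyePairEstimate(left=tuple(fr["estimate_left"]), right=tuple(fr["estimate_right"]))
            row["wec"] = wec(truth, est)
            row["bec"] = bec(truth, est)
            wecs.append(row["wec"])
            becs.append(row["bec"])
        per_frame.append(row)

    aggregates: dict = {"n_frames": len(per_frame), "n_eyes": len(eds)}
    if eds:
        aggregates["mean_ed"] = float(np.mean(eds))
        for axis in ("x", "y"):
            stats = regression_fit_stats(ax_actual[axis], ax_est[axis]) if len(eds) >= 2 else {"mae": None, "r2": None}
            aggregates[f"mae_{axis}"] = stats["mae"]
            aggregates[f"r2_{axis}"] = stats["r2"]
    if s_eds:
        aggregates["mean_s_ed"] = float(np.mean(s_eds))
    if wecs:
        aggregates["wec_accuracy"] = accuracy_at_thresholds(wecs, thresholds)
        aggregates["bec_accuracy"] = accuracy_at_thresholds(becs, thresholds)
        aggregates["mean_wec"] = float(np.mean(wecs))
        aggregates["mean_bec"] = float(np.mean(becs))
    return EvalReport(
        per_frame=per_frame,
        aggregates=aggregates,
        metadata={
            "pooling": "per-axis stats pool both eyes; wec/bec are per frame",
            "threshold_comparison": "inclusive (error <= t)",
        },
    )
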