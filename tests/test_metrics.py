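"""Evaluation metrics: wec, bec, S_ED, accuracy curves, per-axis stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilloc import (
    EyePairEstimate,
    EyePairTruth,
    FrameGeometry,
    ValidationError,
    accuracy_at_thresholds,
    bec,
    evaluate,
    regression_fit_stats,
    s_ed,
    wec,
)

TRUTH = EyePairTruth(left=(0.0, 0.0), right=(100.0, 0.0))


class TestWecBec:
    def test_perfect_estimates_are_zero(self):
        est = EyePairEstimate(left=(0.0, 0.0), right=(100.0, 0.0))
        assert wec(TRUTH, est) == 0.0
        assert bec(TRUTH, est) == 0.0

    def test_hand_derived_single_eye_error(self):
        est = EyePairEstimate(left=(3.0, 4.0), right=(100.0, 0.0))
        assert wec(TRUTH, est) == pytest.approx(0.05, abs=1e-9)
        assert bec(TRUTH, est) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_under_eye_swap(self):
        est_l = EyePairEstimate(left=(3.0, 4.0), right=(100.0, 0.0))
        est_r = EyePairEstimate(left=(0.0, 0.0), right=(103.0, 4.0))
        assert wec(TRUTH, est_l) == pytest.approx(wec(TRUTH, est_r))

    def test_zero_interocular_distance_rejected(self):
        with pytest.raises(ValidationError):
            EyePairTruth(left=(5.0, 5.0), right=(5.0, 5.0))

    @given(st.integers(0, 10_000))
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_bec_never_exceeds_wec(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-50, 50, size=(4, 2))
        if np.allclose(pts[0], pts[1]):
            pts[1] += 1.0
        truth = EyePairTruth(left=tuple(pts[0]), right=tuple(pts[1]))
        est = EyePairEstimate(left=tuple(pts[2]), right=tuple(pts[3]))
        assert bec(truth, est) <= wec(truth, est) + 1e-12

    def test_invariant_under_rigid_motion(self):
        est = EyePairEstimate(left=(3.0, 4.0), right=(99.0, 1.0))
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)

        def move(p):
            return (c * p[0] - s * p[1] + 11.0, s * p[0] + c * p[1] - 4.0)

        truth2 = EyePairTruth(left=move(TRUTH.left), right=move(TRUTH.right))
        est2 = EyePairEstimate(left=move(est.left), right=move(est.right))
        assert wec(truth2, est2) == pytest.approx(wec(TRUTH, est))
        assert bec(truth2, est2) == pytest.approx(bec(TRUTH, est))


class TestStandardizedDistance:
    GEOM = FrameGeometry(x_min=0, y_min=0, x_max=99, y_max=99)

    def test_exact_estimate_is_zero(self):
        assert s_ed((50, 50), (50, 50), self.GEOM) == 0.0

    def test_hand_derived_percentage(self):
        # 3-4-5 triangle error over a 99*sqrt(2) diagonal
        assert s_ed((50, 50), (53, 54), self.GEOM) == pytest.approx(3.571, abs=1e-3)

    @given(st.floats(0.01, 1000.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_invariant_under_uniform_scaling(self, scale):
        base = s_ed((50, 50), (53, 54), self.GEOM)
        geom = FrameGeometry(0, 0, 99 * scale, 99 * scale)
        scaled = s_ed((50 * scale, 50 * scale), (53 * scale, 54 * scale), geom)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_invariant_under_translation(self):
        base = s_ed((50, 50), (53, 54), self.GEOM)
        geom = FrameGeometry(10, 20, 109, 119)
        assert s_ed((60, 70), (63, 74), geom) == pytest.approx(base)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValidationError):
            FrameGeometry(5, 5, 5, 10)


class TestAccuracyCurve:
    def test_counting(self):
        acc = accuracy_at_thresholds([0.01, 0.04, 0.2], [0.05, 0.25])
        assert acc[0.05] == pytest.approx(100 * 2 / 3, abs=1e-9)
        assert acc[0.25] == 100.0

    def test_threshold_comparison_is_inclusive(self):
        acc = accuracy_at_thresholds([0.05, 0.1], [0.05, 0.1])
        assert acc[0.05] == 50.0
        assert acc[0.1] == 100.0

    def test_curve_is_monotone_and_saturates(self):
        rng = np.random.default_rng(3)
        errors = rng.uniform(0, 0.3, 50)
        ts = np.linspace(0.01, 1.0, 40)
        acc = accuracy_at_thresholds(errors, ts)
        values = [acc[float(t)] for t in ts]
        assert all(a <= b for a, b in zip(values, values[1:]))
        assert values[-1] == 100.0

    def test_wec_below_five_percent_counts_the_frame(self):
        # both per-eye errors under 0.05 x interocular => frame counted at 0.05
        est = EyePairEstimate(left=(2.0, 0.0), right=(101.0, 2.0))
        err = wec(TRUTH, est)
        assert err <= 0.05
        assert accuracy_at_thresholds([err], [0.05])[0.05] == 100.0


class TestRegressionFitStats:
    def test_perfect_agreement(self):
        stats = regression_fit_stats([1, 2, 3, 4], [1, 2, 3, 4])
        assert stats == {"mae": 0.0, "r2": 1.0}

    def test_constant_offset_gives_its_mae(self):
        stats = regression_fit_stats([1, 2, 3, 4], [3, 4, 5, 6])
        assert stats["mae"] == pytest.approx(2.0)

    def test_five_point_hand_computed_decomposition(self):
        actual = [1.0, 2.0, 3.0, 4.0, 5.0]
        estimated = [1.1, 1.9, 3.2, 3.8, 5.1]
        # independent arithmetic: ss_res = sum of squared residuals,
        # ss_tot = sum of squared deviations from the mean (3.0)
        ss_res = sum((a - e) ** 2 for a, e in zip(actual, estimated))
        ss_tot = sum((a - 3.0) ** 2 for a in actual)
        stats = regression_fit_stats(actual, estimated)
        assert stats["mae"] == pytest.approx(sum(abs(a - e) for a, e in zip(actual, estimated)) / 5)
        assert stats["r2"] == pytest.approx(1 - ss_res / ss_tot)

    def test_zero_variance_actuals_report_missing_r2(self):
        stats = regression_fit_stats([2, 2, 2], [1, 2, 3])
        assert stats["r2"] is None


class TestEvaluate:
    def test_report_fields_and_bec_wec_ordering(self):
        geom = FrameGeometry(0, 0, 49, 19)
        frames = [
            {
                "image": f"f{i}",
                "actual_left": (10.0, 10.0),
                "estimate_left": (10.0 + i, 10.0),
                "actual_right": (60.0, 10.0),
                "estimate_right": (60.0, 10.0),
                "geometry_left": geom,
            }
            for i in range(4)
        ]
        report = evaluate(frames, thresholds=[0.05, 0.1])
        assert report.aggregates["n_frames"] == 4
        for row in report.per_frame:
            assert row["bec"] <= row["wec"]
        assert "mean_s_ed" in report.aggregates
        assert report.aggregates["wec_accuracy"][0.05] >= report.aggregates["wec_accuracy"][0.05]
        assert report.metadata["threshold_comparison"].startswith("inclusive")
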