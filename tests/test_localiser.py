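"""The matching cascade: scores, candidate selection, centre recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilloc import (
    EyeFrame,
    LocaliserConfig,
    LocalisationError,
    MatchScores,
    SizingError,
    SyntheticEyeSpec,
    aggregate_position,
    adapt_kernel_horizontal,
    centre_from_rect,
    default_disc_kernel,
    horizontal_pass,
    iris_rectangle,
    locate_pupil,
    match_score,
    pad_white,
    render_eye,
    select_candidates,
    vertical_pass,
)
from pupilloc.kernel_bank import Kernel, adapt_kernel_vertical

from conftest import ncc_oracle, pass_oracle


class TestPadWhite:
    def test_border_is_white_interior_preserved(self):
        frame = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = pad_white(frame, 1, 1)
        assert out.shape == (4, 4)
        assert np.array_equal(out[1:3, 1:3], frame)
        border = out.copy()
        border[1:3, 1:3] = 255
        assert np.all(border == 255)

    def test_zero_padding_is_identity(self):
        frame = np.arange(6.0).reshape(2, 3)
        assert np.array_equal(pad_white(frame, 0, 0), frame)

    def test_mean_never_decreases(self):
        frame = np.random.default_rng(0).uniform(0, 255, (5, 8))
        assert pad_white(frame, 2, 3).mean() >= frame.mean()


class TestMatchScore:
    def test_perfect_self_match(self):
        k = default_disc_kernel(7, 7)
        assert match_score(k, k.pixels) == pytest.approx(1.0)

    def test_affine_invariance_of_patch(self):
        k = default_disc_kernel(7, 7)
        assert match_score(k, 0.5 * k.pixels + 40.0) == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        score = match_score(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[1.0, 0.0], [0.0, 0.0]]))
        assert score == pytest.approx(0.5774, abs=1e-4)
        assert score == pytest.approx(
            ncc_oracle(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[1.0, 0.0], [0.0, 0.0]]))
        )

    def test_degenerate_patch_scores_zero(self):
        k = default_disc_kernel(5, 5)
        assert match_score(k, np.full((5, 5), 255.0)) == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_score_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.uniform(0, 255, (4, 6))
        p = rng.uniform(0, 255, (4, 6))
        assert -1.0 <= match_score(k, p) <= 1.0


class TestPasses:
    def test_horizontal_argmax_near_true_disc_position(self, clean_eye):
        eye, sample = clean_eye
        k = adapt_kernel_horizontal(default_disc_kernel(), eye)
        sc = horizontal_pass(eye, k)
        best = sc.positions[np.argmax(sc.scores)]
        assert abs(best - (30 - k.width / 2)) <= 1.0

    def test_horizontal_scores_match_brute_force_oracle(self, clean_eye):
        eye, _ = clean_eye
        k = adapt_kernel_horizontal(default_disc_kernel(), eye)
        sc = horizontal_pass(eye, k)
        exp_scores, exp_pos = pass_oracle(eye.pixels, k.pixels, axis=1)
        assert np.array_equal(sc.positions, exp_pos)
        assert np.max(np.abs(sc.scores - exp_scores)) < 1e-6

    def test_vertical_scores_match_brute_force_oracle(self, clean_eye):
        eye, _ = clean_eye
        kh = adapt_kernel_horizontal(default_disc_kernel(), eye)
        iris, x0 = iris_rectangle(20, eye, kh)
        kv = adapt_kernel_vertical(kh, iris.shape[0])
        sc = vertical_pass(iris, kv)
        exp_scores, exp_pos = pass_oracle(iris, kv.pixels, axis=0)
        assert np.array_equal(sc.positions, exp_pos)
        assert np.max(np.abs(sc.scores - exp_scores)) < 1e-6

    def test_uniform_frame_scores_all_zero(self):
        eye = EyeFrame(pixels=np.full((10, 30), 255.0))
        k = adapt_kernel_horizontal(default_disc_kernel(), eye)
        sc = horizontal_pass(eye, k)
        assert np.all(sc.scores == 0.0)

    def test_mismatched_kernel_height_raises(self, clean_eye):
        eye, _ = clean_eye
        with pytest.raises(SizingError):
            horizontal_pass(eye, default_disc_kernel(9, 9))


class TestCandidates:
    def test_single_top_score_above_90th_percentile(self):
        sc = MatchScores(scores=np.arange(1, 11) / 10.0, positions=np.arange(10))
        cand = select_candidates(sc, 90)
        assert cand.threshold == pytest.approx(0.91)
        assert list(cand.coordinates) == [9]
        assert cand.m_or_n == 1

    def test_top_decile_of_hundred_scores(self):
        sc = MatchScores(scores=np.arange(100) / 100.0, positions=np.arange(100))
        cand = select_candidates(sc, 90)
        assert list(cand.coordinates) == list(range(90, 100))

    def test_all_equal_scores_fall_back_to_every_position(self):
        sc = MatchScores(scores=np.zeros(7), positions=np.arange(7))
        assert select_candidates(sc, 90).m_or_n == 7

    @pytest.mark.parametrize("coords,expected", [([10, 12, 14], 12), ([7], 7), ([10, 11], 10)])
    def test_aggregate_mean_rounds_half_to_even(self, coords, expected):
        sc = MatchScores(scores=np.ones(len(coords)), positions=np.array(coords))
        assert aggregate_position(select_candidates(sc, 90)) == expected


class TestIrisRectangle:
    def test_plain_slice(self, clean_eye):
        eye, _ = clean_eye
        k = adapt_kernel_horizontal(default_disc_kernel(), eye)  # width 24
        iris, x0 = iris_rectangle(10, eye, k)
        assert x0 == 10
        assert iris.shape == (24, 24)

    def test_rim_match_clips_to_frame(self, clean_eye):
        eye, _ = clean_eye
        k = Kernel(default_disc_kernel(20, 24).pixels)
        iris, x0 = iris_rectangle(-3, eye, k)
        assert x0 == 0
        assert iris.shape[1] == 17  # columns 0..16

    def test_fully_out_of_bounds_raises(self, clean_eye):
        eye, _ = clean_eye
        k = default_disc_kernel(20, 24)
        with pytest.raises(LocalisationError):
            iris_rectangle(200, eye, k)


class TestCentre:
    @pytest.mark.parametrize("r,wk,hk,expected", [((10, 5), 20, 8, (20, 9)), ((3, 4), 1, 1, (3, 4))])
    def test_centre_from_rect(self, r, wk, hk, expected):
        assert centre_from_rect(r[0], r[1], wk, hk) == expected


class TestLocatePupil:
    def test_recovers_clean_centre_within_one_pixel(self, clean_eye):
        eye, sample = clean_eye
        est = locate_pupil(eye)
        assert np.hypot(est.centre[0] - 30, est.centre[1] - 12) <= np.sqrt(2) + 1e-9

    def test_extreme_left_disc_recovered_within_two_pixels(self):
        spec = SyntheticEyeSpec(centre_x=9.0, iris_radius=9.0, noise_sigma=0.0)
        sample = render_eye(spec)
        est = locate_pupil(EyeFrame(pixels=sample.image.astype(float)))
        assert np.hypot(est.centre[0] - 9.0, est.centre[1] - 12.0) <= 2.0

    def test_translation_equivariance_within_rounding(self):
        base = SyntheticEyeSpec(centre_x=22.0, centre_y=10.0, noise_sigma=0.0)
        shifted = SyntheticEyeSpec(centre_x=27.0, centre_y=13.0, noise_sigma=0.0)
        e1 = locate_pupil(EyeFrame(pixels=render_eye(base).image.astype(float)))
        e2 = locate_pupil(EyeFrame(pixels=render_eye(shifted).image.astype(float)))
        assert abs((e2.centre[0] - e1.centre[0]) - 5) <= 1
        assert abs((e2.centre[1] - e1.centre[1]) - 3) <= 1

    def test_intensity_affine_invariance(self, clean_eye):
        eye, _ = clean_eye
        est1 = locate_pupil(eye)
        est2 = locate_pupil(EyeFrame(pixels=0.5 * eye.pixels + 30.0))
        assert est1.centre == est2.centre

    def test_estimate_lies_inside_the_frame(self):
        for seed in range(5):
            spec = SyntheticEyeSpec(centre_x=2.0, iris_radius=8.0, noise_sigma=6.0, seed=seed)
            est = locate_pupil(EyeFrame(pixels=render_eye(spec).image.astype(float)))
            assert 0 <= est.centre[0] < spec.frame_width
            assert 0 <= est.centre[1] < spec.frame_height

    def test_constant_frame_raises_with_reason(self):
        with pytest.raises(LocalisationError) as exc:
            locate_pupil(EyeFrame(pixels=np.full((20, 50), 128.0)))
        assert exc.value.reason == "degenerate-frame"

    def test_offset_maps_centre_to_parent_coordinates(self, clean_eye):
        eye, _ = clean_eye
        moved = EyeFrame(pixels=eye.pixels, offset=(100, 40))
        est = locate_pupil(moved)
        assert est.centre_parent == (est.centre[0] + 100, est.centre[1] + 40)

    def test_deterministic(self, clean_eye):
        eye, _ = clean_eye
        assert locate_pupil(eye) == locate_pupil(eye)

    def test_uncentred_variant_still_recovers_clean_centre(self, clean_eye):
        eye, _ = clean_eye
        est = locate_pupil(eye, config=LocaliserConfig(centred=False))
        assert np.hypot(est.centre[0] - 30, est.centre[1] - 12) <= 2.0
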