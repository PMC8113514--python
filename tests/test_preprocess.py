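"""Motion estimation, the velocity gate, SAD arithmetic and CLAHE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microflow as mf
from microflow.preprocess import MotionEstimate


def _stack(frames, fps=32.5):
    return mf.VideoStack(frames=np.asarray(frames), frame_rate_hz=fps)


def _textured_frame(shape=(64, 64), seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 4000, shape).astype(np.uint16)


class TestEstimateMotion:
    def test_static_stack_zero_everything(self):
        f = _textured_frame()
        m = mf.estimate_motion(_stack([f, f, f]), block_size=16, search_radius=4)
        np.testing.assert_array_equal(m.displacement_px, 0)
        np.testing.assert_array_equal(m.velocity_px_per_s, 0)

    @pytest.mark.parametrize("shift", [(0, 3), (2, 0), (-1, 2)])
    def test_recovers_known_integer_shift(self, shift):
        """Brute-force MAD over the search window is minimized at the true
        shift for a noiseless translated frame."""
        f = _textured_frame((96, 96), seed=1)
        g = np.roll(f, shift, axis=(0, 1))
        m = mf.estimate_motion(_stack([f, g]), block_size=24, search_radius=4)
        np.testing.assert_array_equal(m.displacement_px[1], shift)

    def test_velocity_is_displacement_change_times_fps(self):
        f = _textured_frame((96, 96), seed=2)
        g = np.roll(f, (0, 1), axis=(0, 1))
        m = mf.estimate_motion(_stack([f, g, g], fps=32.5), block_size=24, search_radius=3)
        assert m.velocity_px_per_s[1] == pytest.approx(32.5)
        assert m.velocity_px_per_s[2] == pytest.approx(0.0)

    def test_block_larger_than_frame_rejected(self):
        f = _textured_frame((16, 16))
        with pytest.raises(ValueError, match="block_size"):
            mf.estimate_motion(_stack([f, f]), block_size=32, search_radius=2)


class TestStabilize:
    def _motion(self, velocities):
        n = len(velocities)
        return MotionEstimate(
            displacement_px=np.zeros((n, 2)),
            velocity_px_per_s=np.asarray(velocities, dtype=float),
        )

    def test_static_stack_keeps_all(self):
        f = _textured_frame()
        stack = _stack([f] * 5)
        out, kept = mf.stabilize(stack, self._motion([0] * 5))
        assert out.n_frames == 5
        assert kept == [0, 1, 2, 3, 4]

    def test_drops_exactly_the_fast_frames(self):
        frames = [_textured_frame(seed=i) for i in range(12)]
        vel = [0.0] * 12
        for i in (5, 6, 7, 8):
            vel[i] = 1.0
        out, kept = mf.stabilize(_stack(frames), self._motion(vel), 0.3)
        assert out.n_frames == 8
        assert kept == [0, 1, 2, 3, 4, 9, 10, 11]
        np.testing.assert_array_equal(out.frames[5], frames[9])

    def test_infinite_threshold_is_identity(self):
        frames = [_textured_frame(seed=i) for i in range(4)]
        out, kept = mf.stabilize(_stack(frames), self._motion([0, 5, 9, 2]), np.inf)
        assert kept == [0, 1, 2, 3]
        np.testing.assert_array_equal(out.frames, np.asarray(frames))

    def test_too_few_survivors_is_an_error(self):
        frames = [_textured_frame(seed=i) for i in range(3)]
        with pytest.raises(ValueError, match="threshold"):
            mf.stabilize(_stack(frames), self._motion([0, 9, 9]), 0.3)


class TestComputeSAD:
    def test_constant_video_zero(self):
        sad = mf.compute_sad(_stack(np.full((7, 8, 8), 100, dtype=np.uint16)))
        assert sad.values.max() == 0
        assert sad.n_frames_used == 7

    def test_alternating_pixel_definition(self):
        frames = np.full((4, 4, 4), 10, dtype=np.uint16)
        frames[1, 2, 2] = 20
        frames[3, 2, 2] = 20
        # pixel sequence 10,20,10,20 -> |10|*3
        sad = mf.compute_sad(_stack(frames))
        assert sad.values[2, 2] == 30

    def test_no_unsigned_wraparound(self):
        frames = np.zeros((2, 2, 2), dtype=np.uint16)
        frames[1] = 60000
        sad = mf.compute_sad(_stack(frames))
        assert sad.values[0, 0] == 60000

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 8))
    def test_reversal_invariance_and_split_additivity(self, seed, n):
        rng = np.random.default_rng(seed)
        frames = rng.integers(0, 1000, (n, 6, 6)).astype(np.uint16)
        sad = mf.compute_sad(_stack(frames))
        rev = mf.compute_sad(_stack(frames[::-1]))
        np.testing.assert_array_equal(sad.values, rev.values)
        k = n // 2
        left = mf.compute_sad(_stack(frames[: k + 1]))
        right = mf.compute_sad(_stack(frames[k:]))
        np.testing.assert_allclose(left.values + right.values, sad.values)


class TestEnhanceCLAHE:
    def _sad(self, values):
        return mf.SADImage(values=values, n_frames_used=2, kept_frame_indices=[0, 1])

    def test_constant_image_maps_to_constant(self):
        out = mf.enhance_clahe(self._sad(np.full((64, 64), 7.0)))
        assert out.values.min() == out.values.max()

    def test_output_in_unit_range(self):
        rng = np.random.default_rng(0)
        out = mf.enhance_clahe(self._sad(rng.random((64, 64)) * 1e6))
        assert out.values.min() >= 0.0
        assert out.values.max() <= 1.0

    def test_ridge_contrast_does_not_decrease(self):
        """CLAHE must not wash out a faint ridge on a dark background."""
        values = np.zeros((128, 128))
        values[60:64, :] = 30.0  # low-contrast ridge in a 16-bit-scale image
        values += np.linspace(0, 5, 128)[None, :]
        sad = self._sad(values)
        ridge = np.zeros_like(values, dtype=bool)
        ridge[60:64, :] = True

        def contrast(img):
            return img[ridge].mean() - img[~ridge].mean()

        norm = (values - values.min()) / (values.max() - values.min())
        out = mf.enhance_clahe(sad)
        assert contrast(out.values) >= contrast(norm)

    def test_nonpositive_clip_limit_rejected(self):
        with pytest.raises(ValueError, match="clip"):
            mf.enhance_clahe(self._sad(np.ones((8, 8))), clip_limit=0.0)
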