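"""Parametric image derivation: closed forms, wrap rules, equivariance."""

import numpy as np
import pytest

from polaristroma.polarimetry import (
    ACQUISITION_ANGLES,
    OrientationImage,
    PolarimetricStack,
    abundance_image,
    alignment_image,
    flood_field_correct,
    intensity_image,
    orientation_image,
)

from conftest import model_signal, pixel_stack


class TestStackValidation:
    def test_angle_count_mismatch(self):
        with pytest.raises(ValueError, match="angles"):
            PolarimetricStack(frames=np.zeros((5, 2, 2)))

    def test_zero_area(self):
        with pytest.raises(ValueError, match="zero-area"):
            PolarimetricStack(frames=np.zeros((18, 0, 3)))

    def test_nonuniform_angles(self):
        with pytest.raises(ValueError, match="uniform"):
            PolarimetricStack(
                frames=np.zeros((3, 2, 2)), angles=np.array([0.0, 5.0, 20.0])
            )

    def test_negative_brightness(self):
        frames = np.zeros((18, 2, 2))
        frames[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            PolarimetricStack(frames=frames)


class TestIntensity:
    def test_constant_pixel_is_zero(self):
        assert intensity_image(pixel_stack(np.full(18, 7.0))).mir[0, 0] == 0.0

    def test_closed_form_harmonic_sum(self):
        # sum of squared deviations of sin^2(2 theta) over the 18 angles
        # is exactly 9/4 (mean 1/2, sum of cos^2(4 theta) = 9)
        mir = intensity_image(pixel_stack(model_signal(0.0))).mir[0, 0]
        assert mir == pytest.approx(np.sqrt(2.25 / 17.0), abs=1e-12)

    @pytest.mark.parametrize("c", [0.0, 0.5, 3.0])
    def test_homogeneity(self, c):
        base = model_signal(20.0, amplitude=0.8, offset=0.1)
        assert intensity_image(pixel_stack(c * base)).mir[0, 0] == pytest.approx(
            c * intensity_image(pixel_stack(base)).mir[0, 0], abs=1e-12
        )

    def test_needs_two_frames(self):
        stack = PolarimetricStack(frames=np.zeros((1, 2, 2)), angles=[0.0])
        with pytest.raises(ValueError, match="2 frames"):
            intensity_image(stack)


class TestOrientation:
    @pytest.mark.parametrize("phi,expected", [(45.0, 0.0), (30.0, 75.0), (0.0, 45.0)])
    def test_peak_angle_of_model_pixel(self, phi, expected):
        # the signal peaks where theta - phi = +-45 degrees
        b = orientation_image(pixel_stack(model_signal(phi))).b[0, 0]
        assert b == expected

    def test_all_tie_takes_smallest_angle(self):
        assert orientation_image(pixel_stack(np.full(18, 3.0))).b[0, 0] == 0.0

    def test_matches_exhaustive_argmax_for_random_phases(self, rng):
        for phi in rng.uniform(0, 90, size=25):
            signal = model_signal(phi, amplitude=rng.uniform(0.1, 2.0))
            expected = ACQUISITION_ANGLES[np.argmax(signal)]
            assert orientation_image(pixel_stack(signal)).b[0, 0] == expected


class TestAlignment:
    def test_uniform_field_gives_zero(self):
        ai = alignment_image(OrientationImage(b=np.full((9, 9), 40.0)), 5)
        assert np.all(ai.mad[ai.valid_mask] == 0.0)
        assert not ai.valid_mask[0, 0] and ai.valid_mask[4, 4]

    def test_two_population_window(self):
        field = np.full((5, 5), 10.0)
        field.flat[12:] = 30.0  # 12 pixels at 10, 13 at 30
        mad = alignment_image(OrientationImage(b=field), 5).mad[2, 2]
        assert mad == pytest.approx(12 * 13 * 20 / 300.0, abs=1e-12)

    def test_wraparound_difference(self):
        field = np.full((5, 5), 85.0)
        field.flat[13:] = 5.0  # wrapped difference is 10, not 80
        mad = alignment_image(OrientationImage(b=field), 5).mad[2, 2]
        assert mad == pytest.approx(13 * 12 * 10 / 300.0, abs=1e-12)

    @pytest.mark.parametrize("window", [4, 2, 11])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            alignment_image(OrientationImage(b=np.zeros((9, 9))), window)

    def test_range_bounded_by_45(self, rng):
        field = rng.uniform(0, 90, size=(12, 12))
        ai = alignment_image(OrientationImage(b=field), 5)
        vals = ai.mad[ai.valid_mask]
        assert np.all((vals >= 0) & (vals <= 45))


class TestAbundance:
    @pytest.mark.parametrize("phi,amp,off", [(0, 1, 0), (37.3, 0.4, 0.2), (89, 2, 1)])
    def test_noise_free_model_pixel_fits_perfectly(self, phi, amp, off):
        ab = abundance_image(pixel_stack(model_signal(phi, amp, off)))
        assert ab.r2[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert ab.mask[0, 0]

    def test_constant_pixel_scores_zero(self):
        ab = abundance_image(pixel_stack(np.full(18, 4.0)))
        assert ab.r2[0, 0] == 0.0
        assert not ab.mask[0, 0]

    def test_noisy_model_pixels_mostly_pass_threshold(self, rng):
        n = 1000
        phis = rng.uniform(0, 90, size=n)
        y = np.stack([model_signal(p) for p in phis], axis=1)
        y = y + rng.normal(0, 0.05, size=y.shape)
        stack = PolarimetricStack(frames=np.clip(y, 0, None).reshape(18, n, 1))
        ab = abundance_image(stack)
        assert ab.r2.mean() > 0.9
        assert ab.mask.mean() > 0.99


class TestGeometryIndependence:
    def test_cyclic_angle_relabeling(self, rng):
        """Cyclically shifting the acquisition start leaves MIR and R^2
        unchanged and shifts the orientation by the same constant mod 90."""
        n = 40
        phis = rng.uniform(0, 90, size=n)
        amps = rng.uniform(0.2, 1.0, size=n)
        y = np.stack([model_signal(p, a, 0.05) for p, a in zip(phis, amps)], axis=1)
        stack = PolarimetricStack(frames=y.reshape(18, n, 1))
        shift = 4  # 20 degrees
        rolled = PolarimetricStack(frames=np.roll(y, -shift, axis=0).reshape(18, n, 1))

        np.testing.assert_allclose(
            intensity_image(stack).mir, intensity_image(rolled).mir, atol=1e-12
        )
        np.testing.assert_allclose(
            abundance_image(stack).r2, abundance_image(rolled).r2, atol=1e-9
        )
        b0 = orientation_image(stack).b
        b1 = orientation_image(rolled).b
        np.testing.assert_allclose((b0 - b1) % 90.0, 5.0 * shift)


class TestFloodField:
    def _stack(self, frames):
        return PolarimetricStack(frames=frames)

    def test_uniform_reference_is_identity(self, rng):
        frames = rng.uniform(0.1, 1.0, size=(18, 6, 6))
        stack = self._stack(frames)
        ref = self._stack(np.full((18, 6, 6), 3.7))
        np.testing.assert_allclose(
            flood_field_correct(stack, ref).frames, frames, atol=1e-12
        )

    def test_zero_reference_pixel_reported(self, rng):
        frames = rng.uniform(0.1, 1.0, size=(18, 4, 4))
        ref = np.full((18, 4, 4), 2.0)
        ref[0, 1, 1] = 0.0
        with pytest.raises(ValueError, match="1 pixel"):
            flood_field_correct(self._stack(frames), self._stack(ref))

    def test_shape_mismatch(self, rng):
        a = self._stack(rng.uniform(0.1, 1, (18, 4, 4)))
        b = self._stack(rng.uniform(0.1, 1, (18, 5, 5)))
        with pytest.raises(ValueError, match="shape"):
            flood_field_correct(a, b)

    def test_gain_round_trip(self):
        """Dividing truth*gain by a flat-signal reference with the same
        gain recovers the truth up to the reference's mean."""
        from polaristroma.phantom import PhantomSpec, generate_stack

        spec = PhantomSpec(
            width=64, height=64, fiber_count=15, noise_sd=0.0,
            gain_map_sd=0.15, dark_offset=0.05, seed=7,
        )
        stack, truth = generate_stack(spec)
        ref = self._stack(np.broadcast_to(truth.gain_map, (18, 64, 64)).copy())
        corrected = flood_field_correct(stack, ref)
        ideal = stack.frames / truth.gain_map  # noise-free truth signal
        scale = truth.gain_map.mean()
        np.testing.assert_allclose(corrected.frames, ideal * scale, rtol=1e-6)


class TestWrappedDifferenceMetric:
    """Property tests of the mod-90 angular distance underlying MAD."""

    from hypothesis import given, settings, strategies as st

    angles = st.floats(min_value=0.0, max_value=90.0, exclude_max=True)

    @given(a=angles, b=angles)
    @settings(derandomize=True, max_examples=100, database=None)
    def test_symmetric_and_bounded(self, a, b):
        from polaristroma.polarimetry import wrapped_angle_difference as wd

        d = wd(a, b)
        assert 0.0 <= d <= 45.0
        assert d == wd(b, a)
        assert wd(a, a) == 0.0

    @given(a=angles, b=angles, shift=st.floats(0.0, 360.0))
    @settings(derandomize=True, max_examples=100, database=None)
    def test_invariant_to_common_rotation(self, a, b, shift):
        from polaristroma.polarimetry import wrapped_angle_difference as wd

        assert wd((a + shift) % 90.0, (b + shift) % 90.0) == pytest.approx(
            wd(a, b), abs=1e-9
        )
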