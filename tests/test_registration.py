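"""Translation/rotation recovery, channel subtraction, averaging, stitching."""

import numpy as np
import pytest
from scipy import ndimage

from gerikit import registration, synthetic
from gerikit.registration import RegistrationError
from gerikit.types import ImageStack


class TestRegisterTranslation:
    def test_identity(self, smooth_volume):
        t = registration.register_translation(ImageStack(smooth_volume),
                                              ImageStack(smooth_volume))
        assert np.allclose(t.translation, 0, atol=0.2)

    @pytest.mark.parametrize("shift", [(0, 3, 5), (1, -4, 2), (0, 0, -7)])
    def test_planted_roll_recovered(self, smooth_volume, shift):
        mov = ImageStack(np.roll(smooth_volume, shift, axis=(0, 1, 2)))
        t = registration.register_translation(mov, ImageStack(smooth_volume))
        assert np.allclose(t.translation, [-s for s in shift], atol=0.3)

    def test_exhaustive_shift_oracle_on_crop(self, smooth_volume):
        """The phase-correlation shift matches brute-force NCC maximization."""
        ref = smooth_volume[:4, :32, :32]
        mov = np.roll(ref, (0, 2, -3), axis=(0, 1, 2))
        best, best_c = None, -2
        for dy in range(-4, 5):
            for dx in range(-4, 5):
                cand = np.roll(mov, (dy, dx), axis=(1, 2))
                a = cand - cand.mean()
                b = ref - ref.mean()
                c = (a * b).sum() / (np.linalg.norm(a) * np.linalg.norm(b))
                if c > best_c:
                    best, best_c = (dy, dx), c
        t = registration.register_translation(mov, ref)
        assert best == (-2, 3)
        assert np.allclose(t.translation[1:], best, atol=0.3)

    def test_flat_image_raises(self):
        flat = np.zeros((4, 16, 16))
        with pytest.raises(RegistrationError, match="no structure"):
            registration.register_translation(ImageStack(flat), ImageStack(flat))

    def test_pure_noise_pair_flagged(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((4, 32, 32)), rng.random((4, 32, 32))
        with pytest.raises(RegistrationError, match="confidence floor"):
            registration.register_translation(ImageStack(a), ImageStack(b),
                                              min_correlation=0.3)

    def test_inverse_property(self, smooth_volume):
        """register(apply(T, X), X) ~ -T for planted T."""
        planted = (0.0, 2.0, -3.0)
        from gerikit.types import RigidTransform
        moved = registration.apply_transform(
            ImageStack(smooth_volume), RigidTransform(0.0, planted))
        t = registration.register_translation(moved, ImageStack(smooth_volume))
        assert np.allclose(t.translation, [-s for s in planted], atol=0.5)


class TestAlignSessions:
    def test_identical_volumes(self, smooth_volume):
        t = registration.align_sessions(ImageStack(smooth_volume),
                                        ImageStack(smooth_volume))
        assert t.rotation_deg == 0.0
        assert np.allclose(t.translation, 0, atol=0.3)

    def test_planted_rotation_and_shift(self):
        from gerikit.types import RigidTransform
        rng = np.random.default_rng(2)
        sharp = ndimage.gaussian_filter(rng.random((4, 128, 128)), 1.0) * 100
        day1 = ImageStack(sharp)
        # day2 = inverse-transformed day1, so aligning recovers (2 deg, 4, -2)
        day2 = registration.apply_transform(
            registration.apply_transform(day1, RigidTransform(0.0, (0, -4, 2))),
            RigidTransform(-2.0, (0, 0, 0)))
        t = registration.align_sessions(day2, day1)
        assert t.rotation_deg == pytest.approx(2.0, abs=0.3)
        assert np.allclose(t.translation[1:], (4, -2), atol=1.0)

    def test_disjoint_fields_fail(self):
        rng = np.random.default_rng(1)
        a = ndimage.gaussian_filter(rng.random((4, 32, 32)), 2) * 100
        b = ndimage.gaussian_filter(rng.random((4, 32, 32)), 2) * 100
        with pytest.raises(RegistrationError, match="alignment failed"):
            registration.align_sessions(ImageStack(a), ImageStack(b),
                                        min_correlation=0.6)


class TestSubtractAutofluorescence:
    def test_proportional_channels_cancel(self, smooth_volume):
        g = ImageStack(smooth_volume * 3.0)
        r = ImageStack(smooth_volume.copy())
        out = registration.subtract_autofluorescence(g, r)
        assert np.allclose(out.voxels, 0, atol=1e-9)

    def test_empty_red_returns_green(self, smooth_volume):
        g = ImageStack(smooth_volume)
        r = ImageStack(np.zeros_like(smooth_volume))
        with pytest.warns(UserWarning, match="red channel is empty"):
            out = registration.subtract_autofluorescence(g, r)
        np.testing.assert_array_equal(out.voxels, g.voxels)

    def test_generator_autofluorescence_removed_ts_kept(self, small_scene_config):
        green, red, truth = synthetic.gen_twophoton_stack(small_scene_config)
        out = registration.subtract_autofluorescence(green, red)
        vsz = np.asarray(green.voxel_size)
        # residual at autofluorescence-only voxels ~ 0: bright red voxels
        # away from nuclei should vanish in the subtracted image
        af_mask = red.voxels > 0.5 * red.voxels.max()
        nuc_dist = np.ones_like(red.voxels, dtype=bool)
        for pos, rad in zip(truth.nucleus_centroids_um, truth.nucleus_radius_um):
            idx = np.round(pos / vsz).astype(int)
            lo = np.maximum(idx - int(2 * rad), 0)
            hi = np.minimum(idx + int(2 * rad), red.voxels.shape)
            nuc_dist[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = False
        pure_af = af_mask & nuc_dist
        if pure_af.any():
            assert out.voxels[pure_af].max() < 0.02 * green.voxels.max()
        # TS peaks survive
        for pos in truth.ts_coordinates_um:
            idx = tuple(np.round(pos / vsz).astype(int))
            assert out.voxels[idx] > 0.2 * out.voxels.max()

    def test_idempotent_on_own_output(self, smooth_volume):
        # spatially disjoint signal and autofluorescence: once the red
        # structures are removed, a second pass must change nothing
        signal = np.zeros((8, 64, 64))
        signal[:, :, :30] = smooth_volume[:, :, :30]
        af = np.zeros_like(signal)
        af[:, :, 34:] = smooth_volume[:, :, 34:]
        # matched normalization: the first pass cancels af exactly
        green = ImageStack(signal + (signal.max() / af.max()) * af)
        red = ImageStack(af)
        once = registration.subtract_autofluorescence(green, red)
        assert once.voxels[:, :, 34:].max() <= 1e-9 * green.voxels.max()
        twice = registration.subtract_autofluorescence(once, red)
        assert np.abs(twice.voxels - once.voxels).max() <= 1e-6 * once.voxels.max()


class TestAverageFrames:
    def test_identical_frames_unchanged(self, smooth_volume):
        frame = smooth_volume[0]
        avg = registration.average_frames([frame] * 45)
        np.testing.assert_allclose(avg, frame)

    def test_noise_reduction_scales_sqrt_n(self, smooth_volume):
        base = smooth_volume[0]
        frames, _ = synthetic.gen_frame_series(base, 45, 0.0, 5.0, seed=4)
        avg = registration.average_frames(frames, register=False)
        resid_sd = (avg - base).std()
        assert resid_sd == pytest.approx(5.0 / np.sqrt(45), rel=0.15)

    def test_registration_keeps_image_sharp(self, smooth_volume):
        base = smooth_volume[0]
        frames, _ = synthetic.gen_frame_series(base, 20, 1.5, 0.5, seed=3)
        avg = registration.average_frames(frames)
        blurry = registration.average_frames(frames, register=False)
        inner = (slice(8, -8),) * 2
        err_reg = np.abs(avg - base)[inner].max()
        err_unreg = np.abs(blurry - base)[inner].max()
        assert err_reg < 0.5 * err_unreg

    def test_commutes_with_scaling(self, smooth_volume):
        frames, _ = synthetic.gen_frame_series(smooth_volume[0], 10, 1.0, 1.0, seed=5)
        a = registration.average_frames([3.0 * f for f in frames])
        b = 3.0 * registration.average_frames(frames)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            registration.average_frames([])


class TestStitchRois:
    def test_full_overlap_is_identity(self, smooth_volume):
        a = ImageStack(smooth_volume)
        out = registration.stitch_rois(a, a)
        np.testing.assert_allclose(out.voxels, a.voxels, atol=1e-9)

    def test_planted_offset_recovered(self):
        rng = np.random.default_rng(0)
        big = ndimage.gaussian_filter(rng.random((6, 40, 100)), 2) * 100
        a = ImageStack(big[:, :, :60].copy())
        b = ImageStack(big[:, :, 40:].copy())
        out = registration.stitch_rois(a, b)
        assert out.shape == (6, 40, 100)
        np.testing.assert_allclose(out.voxels, big, atol=1e-9)

    def test_zero_overlap_raises(self):
        rng = np.random.default_rng(1)
        a = ndimage.gaussian_filter(rng.random((4, 48, 48)), 1.0) * 100
        b = ndimage.gaussian_filter(rng.random((4, 48, 48)), 1.0) * 100
        with pytest.raises(RegistrationError):
            registration.stitch_rois(ImageStack(a), ImageStack(b))
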