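"""Nucleus circle finding, TS detection rules, cell calling, thresholding,
and time-lapse linking."""

import numpy as np
import pytest
from scipy import stats

from gerikit import registration, segmentation, synthetic
from gerikit.types import (ARC_NEG, ARC_POS, ND, ImageStack, NucleusROI,
                           TSDetection)


def _subtracted_scene(cfg):
    green, red, truth = synthetic.gen_twophoton_stack(cfg)
    return registration.subtract_autofluorescence(green, red), truth


def _match_counts(nuclei, truth, tol_um=2.0):
    found = 0
    for c in truth.nucleus_centroids_um:
        d = [np.linalg.norm(np.asarray(n.centroid_um) - c) for n in nuclei]
        if d and min(d) < tol_um:
            found += 1
    return found


class TestFindNuclei:
    def test_planted_nuclei_found_with_subvoxel_centroids(self, small_scene_config):
        vol, truth = _subtracted_scene(small_scene_config)
        nuclei = segmentation.find_nuclei(vol, radius_range_um=(3.0, 5.0))
        assert len(nuclei) == small_scene_config.n_nuclei
        errs = []
        for n in nuclei:
            d = np.linalg.norm(truth.nucleus_centroids_um
                               - np.asarray(n.centroid_um), axis=1)
            errs.append(d.min())
        assert max(errs) < 1.5  # within ~1 in-plane voxel + z discretization

    def test_pure_noise_yields_empty_list(self):
        rng = np.random.default_rng(0)
        vol = ImageStack(rng.random((10, 96, 96)), (1.0, 0.5, 0.5))
        nuclei = segmentation.find_nuclei(vol, radius_range_um=(3.0, 5.0),
                                          vote_threshold=0.9)
        assert nuclei == []

    def test_empty_volume(self):
        vol = ImageStack(np.zeros((5, 32, 32)), (1.0, 0.5, 0.5))
        assert segmentation.find_nuclei(vol) == []


def _ball_volume(centers_um, radius_um, shape=(20, 96, 96),
                 vsz=(1.0, 0.5, 0.5), level=100.0):
    from scipy import ndimage
    v = np.zeros(shape)
    zz, yy, xx = np.meshgrid(*(np.arange(s) * w for s, w in zip(shape, vsz)),
                             indexing="ij")
    for c in centers_um:
        m = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius_um ** 2
        v[m] = level
    return ImageStack(ndimage.gaussian_filter(v, 1.0), vsz)


def _add_spot(stack, pos_um, amp, sigma_um=(1.0, 0.25, 0.25)):
    vsz = np.asarray(stack.voxel_size)
    synthetic._add_gaussian_spot(stack.voxels, np.asarray(pos_um) / vsz,
                                 np.asarray(sigma_um) / vsz, amp)


class TestDetectTS:
    def setup_method(self):
        self.center = (10.0, 24.0, 24.0)
        self.vol = _ball_volume([self.center], 4.0)
        self.roi = NucleusROI(0, self.center, 4.0, 4.0, 100.0, "ok")

    def test_spot_spanning_three_slices_detected(self):
        _add_spot(self.vol, (10.0, 25.0, 23.0), 400.0)
        dets = segmentation.detect_ts(self.vol, [self.roi])
        assert len(dets) == 1
        assert dets[0].z_extent >= 3
        assert np.allclose(dets[0].position_um, (10.0, 25.0, 23.0), atol=1.0)

    def test_single_slice_spot_rejected(self):
        # sigma_z much smaller than slice spacing: bright in one slice only
        _add_spot(self.vol, (10.0, 25.0, 23.0), 400.0, sigma_um=(0.2, 0.25, 0.25))
        dets = segmentation.detect_ts(self.vol, [self.roi])
        assert dets == []

    def test_three_spots_keep_brightest_two(self):
        for amp, pos in [(400.0, (10.0, 22.0, 24.0)),
                         (350.0, (10.0, 26.0, 24.0)),
                         (300.0, (10.0, 24.0, 21.0))]:
            _add_spot(self.vol, pos, amp)
        dets = segmentation.detect_ts(self.vol, [self.roi])
        assert len(dets) == 2
        assert min(d.peak_intensity for d in dets) >= 300

    def test_cropped_nucleus_skipped(self):
        _add_spot(self.vol, (10.0, 25.0, 23.0), 400.0)
        self.roi.status = "cropped"
        assert segmentation.detect_ts(self.vol, [self.roi]) == []


class TestDetectionQuality:
    @pytest.mark.parametrize("noise_sd", [0.0, 2.0])
    def test_high_snr_recall_and_precision(self, noise_sd):
        tp = fp = n_true = 0
        for seed in range(3):
            cfg = synthetic.SceneConfig(
                volume_shape=(20, 160, 160), voxel_size=(1.0, 0.5, 0.5),
                n_nuclei=12, ts_fraction=0.5, autofluorescence_density=5,
                read_noise_sd=noise_sd, seed=seed)
            vol, truth = _subtracted_scene(cfg)
            nuclei = segmentation.find_nuclei(vol, radius_range_um=(3.0, 5.0))
            dets = segmentation.detect_ts(vol, nuclei)
            n_true += len(truth.ts_coordinates_um)
            for d in dets:
                dist = np.linalg.norm(truth.ts_coordinates_um
                                      - np.asarray(d.position_um), axis=1)
                if dist.size and dist.min() < 2.0:
                    tp += 1
                else:
                    fp += 1
        recall = tp / n_true
        precision = tp / (tp + fp)
        assert recall >= 0.95
        assert precision >= 0.95


class TestClassifyCells:
    def test_detection_means_positive(self):
        roi = NucleusROI(0, (5, 5, 5), 4, 4, 100.0, "ok")
        det = TSDetection(0, 0, (5, 5, 5), 500.0, 3, 10.0)
        calls = segmentation.classify_cells([roi], [det],
                                            gfp_bounds=(0, 1000))
        assert calls[0].call == ARC_POS and calls[0].n_ts == 1

    def test_cropped_with_detection_is_nd(self):
        roi = NucleusROI(0, (5, 5, 5), 4, 4, 100.0, "cropped")
        det = TSDetection(0, 0, (5, 5, 5), 500.0, 3, 10.0)
        calls = segmentation.classify_cells([roi], [det], gfp_bounds=(0, 1000))
        assert calls[0].call == ND

    def test_gfp_out_of_bounds_is_nd(self):
        rois = [NucleusROI(i, (5, 5, 5), 4, 4, g, "ok")
                for i, g in enumerate([100.0, 5000.0])]
        calls = segmentation.classify_cells(rois, [], gfp_bounds=(10, 1000))
        assert [c.call for c in calls] == [ARC_NEG, ND]

    def test_fraction_recovers_planted_ts_fraction(self):
        """Full pipeline: Arc+ fraction within binomial CI of planted 0.23."""
        p = 0.23
        k = n = 0
        for seed in range(4):
            cfg = synthetic.SceneConfig(
                volume_shape=(20, 160, 160), voxel_size=(1.0, 0.5, 0.5),
                n_nuclei=12, ts_fraction=p, autofluorescence_density=3,
                seed=100 + seed)
            vol, _truth = _subtracted_scene(cfg)
            nuclei = segmentation.find_nuclei(vol, radius_range_um=(3.0, 5.0))
            dets = segmentation.detect_ts(vol, nuclei)
            calls = segmentation.classify_cells(nuclei, dets,
                                                gfp_bounds=(0, np.inf))
            usable = [c for c in calls if c.call != ND]
            k += sum(c.call == ARC_POS for c in usable)
            n += len(usable)
        lo, hi = stats.binom.interval(0.95, n, p)
        assert lo <= k <= hi

    def test_never_positive_without_ts(self):
        rois = [NucleusROI(i, (5, 5, 5), 4, 4, 100.0, "ok") for i in range(5)]
        calls = segmentation.classify_cells(rois, [], gfp_bounds=(0, 1000))
        assert all(c.call == ARC_NEG and c.n_ts == 0 for c in calls)


class TestTwoGaussianThreshold:
    def test_equal_variance_midpoint(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(20, 1, 5000)
        neg = rng.normal(10, 1, 5000)
        th = segmentation.two_gaussian_threshold(pos, neg)
        assert th == pytest.approx(15.0, abs=0.1)

    def test_unequal_variance_matches_quadratic_root(self):
        rng = np.random.default_rng(1)
        neg = rng.normal(0, 1, 20000)
        pos = rng.normal(6, 2, 20000)
        th = segmentation.two_gaussian_threshold(pos, neg)
        # analytic intersection of the two fitted densities
        m1, s1 = neg.mean(), neg.std(ddof=1)
        m2, s2 = pos.mean(), pos.std(ddof=1)
        a = 1 / (2 * s1 ** 2) - 1 / (2 * s2 ** 2)
        b = m2 / s2 ** 2 - m1 / s1 ** 2
        c = m1 ** 2 / (2 * s1 ** 2) - m2 ** 2 / (2 * s2 ** 2) + np.log(s2 / s1)
        roots = np.roots([a, b, c])
        root = [r.real for r in roots if m1 < r.real < m2][0]
        assert th == pytest.approx(root, abs=1e-9)

    def test_identical_distributions_raise(self):
        x = np.ones(50) * 5 + np.linspace(-0.01, 0.01, 50)
        with pytest.raises(ValueError, match="inseparable"):
            segmentation.two_gaussian_threshold(x, x)


def _det(frame_pos, intensity=100.0):
    return TSDetection(0, 0, tuple(frame_pos), intensity, 3, 10.0)


class TestLinkTimelapse:
    def test_single_stationary_ts(self):
        frames = [[_det((5, 5, 5))] for _ in range(20)]
        tracks = segmentation.link_ts_timelapse(frames, max_jump_um=1.0)
        assert len(tracks) == 1
        assert len(tracks[0]["frames"]) == 20

    def test_two_distant_ts_no_swaps(self):
        frames = [[_det((5, 5, 5)), _det((5, 15, 5))] for _ in range(10)]
        tracks = segmentation.link_ts_timelapse(frames, max_jump_um=2.0)
        assert len(tracks) == 2
        for tr in tracks:
            ys = {p[1] for p in tr["positions_um"]}
            assert len(ys) == 1  # never jumps between the two sites

    def test_gap_bridging_keeps_one_track(self):
        frames = [[_det((5, 5, 5))]] * 5 + [[]] + [[_det((5, 5.2, 5))]] * 5
        tracks = segmentation.link_ts_timelapse(frames, max_jump_um=1.0,
                                                max_gap_frames=1)
        assert len(tracks) == 1
        assert np.isnan(tracks[0]["trace"][5])
        no_bridge = segmentation.link_ts_timelapse(frames, max_jump_um=1.0,
                                                   max_gap_frames=0)
        assert len(no_bridge) == 2
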