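"""Segmentation chain: denoise, thresholds, cleanup, cavity localization."""

import numpy as np
import pytest

import kernelct as kc
from kernelct.segmentation import SegmentationConfig
from kernelct.volume import (
    BACKGROUND,
    CAVITY_EMBRYO,
    CAVITY_ENDOSPERM,
    CAVITY_GENERIC,
    CAVITY_SUBCUTANEOUS,
    EMBRYO,
    ENDOSPERM,
    SEED_COAT,
    LabelVolume,
    VoxelVolume,
)
from conftest import make_segmenter


class TestDenoise:
    def test_constant_volume_is_a_fixed_point(self):
        vol = VoxelVolume(np.full((8, 8, 8), 77, dtype=np.uint8), 100.0)
        out = kc.denoise(vol, SegmentationConfig(denoise_radius_vox=2))
        assert np.array_equal(out.data, vol.data)

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        vol = VoxelVolume(rng.integers(0, 255, (8, 8, 8), dtype=np.uint8), 100.0)
        out = kc.denoise(vol, SegmentationConfig(denoise_radius_vox=0))
        assert np.array_equal(out.data, vol.data)

    def test_negative_radius_rejected(self):
        vol = VoxelVolume(np.zeros((4, 4, 4), dtype=np.uint8), 100.0)
        with pytest.raises(ValueError):
            kc.denoise(vol, SegmentationConfig(denoise_radius_vox=-1))

    def test_noise_shrinks_toward_the_noiseless_phantom(
        self, clean_phantom, noisy_phantom
    ):
        _, clean_vol, _ = clean_phantom
        spec, noisy_vol, _ = noisy_phantom
        den = kc.denoise(noisy_vol, SegmentationConfig(denoise_radius_vox=1))
        ref = clean_vol.data.astype(float)
        mad_before = np.abs(noisy_vol.data.astype(float) - ref).mean()
        mad_after = np.abs(den.data.astype(float) - ref).mean()
        assert mad_after < mad_before

    def test_intensity_range_preserved(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        den = kc.denoise(vol, SegmentationConfig(denoise_radius_vox=1))
        assert den.data.min() >= vol.data.min()
        assert den.data.max() <= vol.data.max()


class TestSegmentComponents:
    def test_noiseless_phantom_recovered_exactly_with_midpoints(self, clean_phantom):
        spec, vol, truth = clean_phantom
        seg = make_segmenter(spec, denoise_radius_vox=0)
        pred = seg.segment(vol)
        assert np.array_equal(pred.labels, truth.label_volume.labels)

    def test_all_background_raises_no_foreground(self):
        vol = VoxelVolume(np.zeros((16, 16, 16), dtype=np.uint8), 100.0)
        with pytest.raises(ValueError, match="no foreground"):
            kc.segment_components(vol, SegmentationConfig(
                threshold_method="midpoint",
                grey_levels={"background": 10, "cavity": 40, "seed_coat": 120,
                             "endosperm": 120, "embryo": 200}))

    def test_two_kernels_in_one_volume_raise_with_sizes(self):
        data = np.full((24, 24, 24), 10, dtype=np.uint8)
        data[2:10, 2:10, 2:10] = 120
        data[14:22, 14:22, 14:22] = 120
        vol = VoxelVolume(data, 100.0)
        with pytest.raises(ValueError, match="more than one large foreground"):
            kc.segment_components(vol, SegmentationConfig(
                threshold_method="midpoint",
                grey_levels={"background": 10, "cavity": 40, "seed_coat": 120,
                             "endosperm": 120, "embryo": 200}))

    def test_noisy_phantom_dice_after_denoise(self, noisy_phantom):
        spec, vol, truth = noisy_phantom
        pred = make_segmenter(spec).segment(vol)
        dice, confusion = kc.evaluate_segmentation(pred, truth.label_volume)
        assert dice["endosperm"] >= 0.95
        assert dice["embryo"] >= 0.95
        cav_p = pred.mask(*[4, 5, 6])
        cav_t = truth.label_volume.mask(*[4, 5, 6])
        union_dice = 2 * (cav_p & cav_t).sum() / (cav_p.sum() + cav_t.sum())
        assert union_dice >= 0.95
        assert confusion.to_numpy().sum() == np.prod(vol.shape)

    def test_multiotsu_thresholds_give_high_dice_without_known_greys(
        self, noisy_phantom
    ):
        spec, vol, truth = noisy_phantom
        seg = kc.KernelSegmenter(threshold_method="multiotsu",
                                 coat_thickness_mm=spec.coat_thickness_mm)
        pred = seg.segment(vol)
        dice, _ = kc.evaluate_segmentation(pred, truth.label_volume)
        assert dice["endosperm"] >= 0.95
        assert dice["embryo"] >= 0.95

    def test_dice_non_increasing_in_noise(self):
        scores = []
        for sd in (0.0, 8.0, 20.0):
            spec = kc.KernelPhantomSpec(voxel_size_um=150, noise_sd=sd, rng_seed=11)
            vol, truth = kc.generate_kernel_phantom(spec)
            pred = make_segmenter(spec).segment(vol)
            dice, _ = kc.evaluate_segmentation(pred, truth.label_volume)
            scores.append(dice["endosperm"])
        assert scores[0] >= scores[1] - 0.01
        assert scores[1] >= scores[2] - 0.01

    def test_chain_conserves_foreground_voxels(self, noisy_phantom):
        spec, vol, _ = noisy_phantom
        cfg = make_segmenter(spec).config
        den = kc.denoise(vol, cfg)
        raw = kc.segment_components(den, cfg)
        cleaned = kc.clean_labels(raw, cfg)
        final = kc.classify_cavities(cleaned, cfg)
        fg0 = raw.labels != BACKGROUND
        assert np.array_equal(fg0, cleaned.labels != BACKGROUND)
        assert np.array_equal(fg0, final.labels != BACKGROUND)
        # cavity exhaustiveness: no generic cavity voxels remain
        assert not (final.labels == CAVITY_GENERIC).any()


class TestCleanLabels:
    def _toy(self):
        labels = np.full((12, 12, 12), ENDOSPERM, dtype=np.uint8)
        labels[0] = BACKGROUND
        return labels

    def test_clean_input_unchanged(self):
        lv = LabelVolume(self._toy(), 100.0)
        out = kc.clean_labels(lv, SegmentationConfig(min_object_vox=5))
        assert np.array_equal(out.labels, lv.labels)

    def test_isolated_speck_reassigned_to_enclosing_class(self):
        labels = self._toy()
        labels[6, 6, 6] = CAVITY_GENERIC  # 1-voxel speck inside endosperm
        out = kc.clean_labels(LabelVolume(labels, 100.0),
                              SegmentationConfig(min_object_vox=5))
        assert out.labels[6, 6, 6] == ENDOSPERM

    def test_idempotent(self, noisy_phantom):
        spec, vol, _ = noisy_phantom
        cfg = make_segmenter(spec).config
        raw = kc.segment_components(kc.denoise(vol, cfg), cfg)
        once = kc.clean_labels(raw, cfg)
        twice = kc.clean_labels(once, cfg)
        assert np.array_equal(once.labels, twice.labels)


class TestClassifyCavities:
    def test_planted_location_classes_recovered(self, clean_phantom):
        spec, vol, truth = clean_phantom
        pred = make_segmenter(spec, denoise_radius_vox=0).segment(vol)
        for code in (CAVITY_SUBCUTANEOUS, CAVITY_ENDOSPERM, CAVITY_EMBRYO):
            t_mask = truth.label_volume.labels == code
            assert (pred.labels[t_mask] == code).mean() > 0.99, code

    def test_no_cavities_is_a_no_op(self):
        labels = np.full((8, 8, 8), ENDOSPERM, dtype=np.uint8)
        lv = LabelVolume(labels, 100.0)
        out = kc.classify_cavities(lv)
        assert np.array_equal(out.labels, lv.labels)

    def test_cavity_inside_embryo_lobe_becomes_embryo_cavity(self):
        labels = np.full((16, 16, 16), EMBRYO, dtype=np.uint8)
        labels[0] = BACKGROUND
        labels[7:10, 7:10, 7:10] = CAVITY_GENERIC
        out = kc.classify_cavities(LabelVolume(labels, 100.0))
        assert np.all(out.labels[7:10, 7:10, 7:10] == CAVITY_EMBRYO)

    def test_open_pore_warns_and_still_classifies(self):
        labels = np.full((16, 16, 16), ENDOSPERM, dtype=np.uint8)
        labels[:, :, :2] = BACKGROUND
        labels[8, 8, 2:6] = CAVITY_GENERIC  # tunnel touching background
        with pytest.warns(UserWarning, match="open pore"):
            out = kc.classify_cavities(LabelVolume(labels, 100.0))
        assert not (out.labels == CAVITY_GENERIC).any()


class TestEvaluateSegmentation:
    def test_identical_volumes_have_unit_dice(self, clean_phantom):
        _, _, truth = clean_phantom
        dice, _ = kc.evaluate_segmentation(truth.label_volume, truth.label_volume)
        assert all(v == 1.0 for v in dice.values())

    def test_disjoint_prediction_has_zero_foreground_dice(self):
        t = np.full((6, 6, 6), ENDOSPERM, dtype=np.uint8)
        p = np.zeros_like(t)
        dice, _ = kc.evaluate_segmentation(
            LabelVolume(p, 100.0), LabelVolume(t, 100.0))
        assert dice["endosperm"] == 0.0

    def test_dice_formula_on_enumerated_toy(self):
        # 4 foreground voxels, 3 predicted correctly: 2*3/(4+4) = 0.75
        t = np.zeros((4, 4, 1), dtype=np.uint8)
        p = np.zeros_like(t)
        t[0, 0:4, 0] = ENDOSPERM
        p[0, 0:3, 0] = ENDOSPERM
        p[1, 3, 0] = ENDOSPERM
        dice, conf = kc.evaluate_segmentation(
            LabelVolume(p, 100.0), LabelVolume(t, 100.0))
        assert dice["endosperm"] == pytest.approx(0.75)
        assert conf.to_numpy().sum() == 16

    def test_shape_mismatch_raises(self):
        a = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), 100.0)
        b = LabelVolume(np.zeros((5, 4, 4), dtype=np.uint8), 100.0)
        with pytest.raises(ValueError, match="shape"):
            kc.evaluate_segmentation(a, b)
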