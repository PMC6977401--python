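"""Serial-section preprocessing, registration, alignment, segmentation,
volumetry."""

import numpy as np
import pytest

from ocmstroke.infarct import (LabelVolume, RigidTransform2D, align_stack,
                               infarct_metrics, preprocess_section,
                               register_pair, segment_infarct)
from ocmstroke.sections import SectionStackSpec, apply_rigid, simulate_sections


class TestPreprocessSection:
    def test_constant_image_survives_degenerate_stretch(self):
        img = np.full((40, 40), 10.0)
        out = preprocess_section(img, pixel_size_um=10.0, target_um=20.0)
        assert out.shape == (20, 20)
        assert np.unique(out).size == 1

    def test_lower_median_convention_for_even_window(self):
        """A 2x2 block {0,0,0,255} filters to 0 under the lower-median rule."""
        img = np.zeros((8, 8))
        img[4, 4] = 255.0
        out = preprocess_section(img, pixel_size_um=20.0, target_um=20.0,
                                 invert=False, contrast_percentiles=(0, 100))
        assert out[4, 4] == 0

    def test_factor_two_downsample_shape(self):
        img = np.random.default_rng(0).random((40, 40)) * 255
        out = preprocess_section(img, pixel_size_um=10.0, target_um=20.0)
        assert out.shape == (20, 20)
        assert out.dtype == np.uint8

    def test_inversion(self):
        img = np.zeros((10, 10))
        img[0, 0] = 255.0
        out = preprocess_section(img, pixel_size_um=20.0, target_um=20.0,
                                 contrast_percentiles=(0, 100), median_size=1)
        assert out[0, 0] == 0
        assert out[5, 5] == 255

    def test_target_coarser_than_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess_section(np.zeros((4, 4)), pixel_size_um=10.0, target_um=100.0)


@pytest.fixture(scope="module")
def section():
    spec = SectionStackSpec(n_sections=9, noise_std=0.0, max_shift_px=0.0,
                            max_rot_deg=0.0)
    stack, _, _ = simulate_sections(spec, seed=11)
    return stack.images[4]


class TestRegisterPair:
    def test_identity_for_identical_images(self, section):
        t = register_pair(section, section)
        assert abs(t.rotation_deg) <= 0.1
        assert abs(t.dx) <= 0.1 and abs(t.dy) <= 0.1

    def test_pure_translation_recovered(self, section):
        moving = apply_rigid(section, 5.0, -3.0, 0.0)
        t = register_pair(section, moving)
        assert t.dx == pytest.approx(-5.0, abs=0.5)
        assert t.dy == pytest.approx(3.0, abs=0.5)

    def test_pure_rotation_recovered(self, section):
        moving = apply_rigid(section, 0.0, 0.0, 4.0)
        t = register_pair(section, moving)
        assert t.rotation_deg == pytest.approx(-4.0, abs=0.5)

    def test_flat_image_rejected(self, section):
        with pytest.raises(ValueError, match="flat"):
            register_pair(section, np.zeros_like(section))

    def test_shape_mismatch_rejected(self, section):
        with pytest.raises(ValueError):
            register_pair(section, section[:-1])


class TestAlignStack:
    def test_zero_offset_stack_stays_identity(self):
        spec = SectionStackSpec(n_sections=7, noise_std=0.0, max_shift_px=0.0,
                                max_rot_deg=0.0)
        stack, _, _ = simulate_sections(spec, seed=2)
        _, transforms = align_stack(stack)
        # neighbouring sections differ in content, so "identity" holds up to
        # the content-drift bias of pairwise registration
        for t in transforms:
            assert abs(t.rotation_deg) <= 0.75
            assert abs(t.dx) <= 0.75 and abs(t.dy) <= 0.75

    def test_random_offsets_recovered_within_tolerance(self):
        """Nine sections with offsets U(-8, 8) px / U(-5, 5) deg realign to
        within 1 px / 1 deg per section."""
        spec = SectionStackSpec(n_sections=9, max_shift_px=8.0, max_rot_deg=5.0,
                                noise_std=0.02)
        stack, truth, _ = simulate_sections(spec, seed=11)
        aligned, transforms = align_stack(stack)
        for t, (dx, dy, deg) in zip(transforms, truth):
            assert abs(t.rotation_deg + deg) <= 1.0
            a = np.deg2rad(t.rotation_deg)
            rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            residual = rot @ np.array([dx, dy]) + np.array([t.dx, t.dy])
            assert np.abs(residual).max() <= 1.0

    def test_aligned_stack_ncc_near_ceiling(self):
        """Post-alignment mean pairwise NCC reaches the ground-truth-aligned
        stack's own NCC within a small margin."""
        spec = SectionStackSpec(n_sections=9, max_shift_px=8.0, max_rot_deg=5.0,
                                noise_std=0.02)
        stack, truth, _ = simulate_sections(spec, seed=11)
        aligned, _ = align_stack(stack)

        clean_spec = spec.model_copy(update={"max_shift_px": 0.0, "max_rot_deg": 0.0,
                                             "offsets": tuple((0.0, 0.0, 0.0)
                                                              for _ in range(9))})
        clean, _, _ = simulate_sections(clean_spec, seed=11)

        def ncc(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())

        got = np.mean([ncc(aligned[i], aligned[i + 1]) for i in range(8)])
        ceiling = np.mean([ncc(clean.images[i], clean.images[i + 1])
                           for i in range(8)])
        assert got >= ceiling - 0.05

    def test_too_few_sections_rejected(self):
        with pytest.raises(ValueError):
            align_stack(np.zeros((2, 16, 16)))

    def test_flat_section_aborts_with_index(self):
        spec = SectionStackSpec(n_sections=5, noise_std=0.0, max_shift_px=0.0,
                                max_rot_deg=0.0)
        stack, _, _ = simulate_sections(spec, seed=2)
        images = stack.images.copy()
        images[4] = 0.0
        with pytest.raises(RuntimeError, match="section 4"):
            align_stack(images)


class TestSegmentInfarct:
    def test_clean_stack_matches_truth(self):
        spec = SectionStackSpec(noise_std=0.0, max_shift_px=0.0, max_rot_deg=0.0)
        stack, _, label = simulate_sections(spec, seed=1)
        seg = segment_infarct(stack.images, 20.0, 40.0)
        inter = (seg.data & label).sum()
        dice = 2 * inter / (seg.data.sum() + label.sum())
        assert dice >= 0.98

    def test_user_mask_passthrough(self):
        stack = np.zeros((5, 10, 10))
        mask = np.zeros((5, 10, 10), bool)
        mask[2, 4:6, 4:6] = True
        seg = segment_infarct(stack, 20.0, 40.0, user_mask=mask)
        assert np.array_equal(seg.data, mask)

    def test_all_background_gives_empty_volume(self):
        seg = segment_infarct(np.zeros((5, 10, 10)), 20.0, 40.0, threshold=0.5)
        assert seg.n_voxels == 0


class TestInfarctMetrics:
    def test_voxel_count_volume_arithmetic(self):
        """87,500 voxels at 20 x 20 x 40 um = exactly 1.4 mm^3, which is 1.1%
        of a 127.3 mm^3 hemisphere."""
        data = np.zeros((35, 50, 50), bool)
        data[:35, :50, :50] = True  # 87,500 voxels
        label = LabelVolume(data, 20.0, 40.0)
        m = infarct_metrics(label, hemisphere_mm3=127.3)
        assert label.n_voxels == 87_500
        assert m.volume_mm3 == pytest.approx(1.4, abs=1e-12)
        assert m.percent_hemisphere == pytest.approx(100 * 1.4 / 127.3)
        assert round(m.percent_hemisphere, 1) == 1.1

    def test_ap_length_from_occupied_sections(self):
        """29 occupied 40-um sections span 1.16 mm anterior-posterior."""
        data = np.zeros((29, 4, 4), bool)
        data[:, 1, 1] = True
        m = infarct_metrics(LabelVolume(data, 20.0, 40.0))
        assert m.ap_length_mm == pytest.approx(1.16)

    def test_metrics_invariant_under_in_plane_translation(self):
        rng = np.random.default_rng(0)
        data = np.zeros((5, 30, 30), bool)
        data[1:4, 5:15, 5:18] = True
        moved = np.roll(np.roll(data, 7, axis=1), 4, axis=2)
        a = infarct_metrics(LabelVolume(data, 20.0, 40.0))
        b = infarct_metrics(LabelVolume(moved, 20.0, 40.0))
        assert a == b

    def test_nonpositive_hemisphere_rejected(self):
        with pytest.raises(ValueError):
            infarct_metrics(LabelVolume(np.ones((2, 2, 2), bool), 20.0, 40.0), 0.0)


class TestRigidTransform:
    def test_rotation_range_validated(self):
        with pytest.raises(ValueError):
            RigidTransform2D(200.0, 0.0, 0.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform2D(np.nan, 0.0, 0.0)
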