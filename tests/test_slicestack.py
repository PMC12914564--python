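"""DAPI masking, AP ordering, and midline alignment."""

import numpy as np
import pytest
from scipy import ndimage

from cortiquant import slicestack
from cortiquant.exceptions import EmptyMaskError, SliceOrderError
from cortiquant.types import SliceImage, SliceMask


def make_slice(dapi, pixel_size_um=2.0, ap=0.0, slice_id="s0"):
    return SliceImage(channels={"dapi": dapi}, pixel_size_um=pixel_size_um,
                      ap_position_mm=ap, slice_id=slice_id)


class TestMask:
    def test_bright_field_with_hole_pixel_arithmetic(self):
        """1000×1000 px bright field at 2 μm/px with a dark 100×100 px hole
        → mask area (10⁶ − 10⁴)·4 μm² = 3.96 mm²."""
        img = np.full((1000, 1000), 1000.0)
        img[450:550, 450:550] = 0.0
        m = slicestack.make_dapi_mask(make_slice(img), blur_sigma=0,
                                      threshold=500.0)
        assert m.area_mm2 == pytest.approx(3.96, rel=1e-6)
        assert not m.mask[500, 500]

    def test_small_holes_filled_large_kept(self):
        img = np.full((800, 800), 1000.0)
        img[100:110, 100:110] = 0.0     # 100 px = 0.0004 mm2 -> filled
        img[400:500, 400:500] = 0.0     # 10⁴ px = 0.04 mm2 -> kept as hole
        m = slicestack.make_dapi_mask(make_slice(img), blur_sigma=0,
                                      threshold=500.0)
        assert m.mask[105, 105]
        assert not m.mask[450, 450]

    def test_all_zero_raises(self):
        with pytest.raises(EmptyMaskError):
            slicestack.make_dapi_mask(make_slice(np.zeros((100, 100))))

    def test_phantom_mask_area_within_1pct_of_truth(self, small_stack,
                                                    small_spec):
        slices, truth = small_stack
        s = slices[1]  # mid-lesion
        m = slicestack.make_dapi_mask(s)
        expected = (truth.footprint_area_mm2
                    - truth.per_slice_lesion_area_mm2[1])
        assert m.area_mm2 == pytest.approx(expected, rel=0.01)

    def test_masking_idempotent(self):
        img = np.full((400, 400), 1000.0)
        img[:100] = 0.0
        m1 = slicestack.make_dapi_mask(make_slice(img), blur_sigma=0,
                                       threshold=500.0)
        masked = np.where(m1.mask, img, 0.0)
        m2 = slicestack.make_dapi_mask(make_slice(masked), blur_sigma=0,
                                       threshold=500.0)
        np.testing.assert_array_equal(m1.mask, m2.mask)


class TestSort:
    def test_orders_anterior_to_posterior(self):
        s = [make_slice(np.ones((4, 4)), ap=a, slice_id=f"s{i}")
             for i, a in enumerate([-0.5, 2.0, 0.8])]
        out = slicestack.sort_slices(s)
        assert [x.ap_position_mm for x in out] == [2.0, 0.8, -0.5]

    def test_sorted_input_is_identity_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        aps = np.linspace(2.5, -1.0, 8)
        s = [make_slice(np.ones((4, 4)), ap=a, slice_id=f"s{i}")
             for i, a in enumerate(aps)]
        assert [x.slice_id for x in slicestack.sort_slices(s)] \
            == [x.slice_id for x in s]
        perm = list(rng.permutation(s))
        assert [x.slice_id for x in slicestack.sort_slices(perm)] \
            == [x.slice_id for x in s]

    def test_duplicate_id_raises(self):
        s = [make_slice(np.ones((4, 4)), ap=1.0, slice_id="dup"),
             make_slice(np.ones((4, 4)), ap=0.0, slice_id="dup")]
        with pytest.raises(SliceOrderError):
            slicestack.sort_slices(s)

    def test_missing_ap_raises(self):
        s = [make_slice(np.ones((4, 4)), ap=np.nan)]
        with pytest.raises(SliceOrderError):
            slicestack.sort_slices(s)


def _ellipse_image(shape=(600, 700), semi=(180, 260), rotation=0.0,
                   shift=(0.0, 0.0)):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    c = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    img = ((((rr - c[0]) / semi[0]) ** 2 + ((cc - c[1]) / semi[1]) ** 2)
           <= 1).astype(float) * 1000.0
    if rotation:
        img = ndimage.rotate(img, rotation, reshape=False, order=1)
    if any(shift):
        img = ndimage.shift(img, shift, order=1)
    return img


class TestAlign:
    def test_symmetric_slice_gets_identity_transform(self):
        img = _ellipse_image()
        sl = make_slice(img)
        m = slicestack.make_dapi_mask(sl, blur_sigma=0, threshold=500.0)
        st = slicestack.align_midline([(sl, m)], transform_images=False)
        tf = st.slices[0].transform
        assert abs(tf.rotation_deg) <= 0.5
        assert abs(tf.translation_px[0]) <= 1.0
        assert abs(tf.translation_px[1]) <= 1.0

    def test_planted_rotation_and_shift_recovered(self):
        """Rotation estimate matches the planted angle, and applying the
        estimated rigid transform restores the canonical (unrotated,
        centered) mask to high overlap."""
        img = _ellipse_image(rotation=7.0, shift=(10.0, 30.0))
        sl = make_slice(img)
        m = slicestack.make_dapi_mask(sl, blur_sigma=0, threshold=500.0)
        st = slicestack.align_midline([(sl, m)])
        tf = st.slices[0].transform
        assert tf.rotation_deg == pytest.approx(-7.0, abs=1.0)
        canonical = _ellipse_image() > 500.0
        aligned = st.slices[0].mask.mask
        iou = (np.logical_and(aligned, canonical).sum()
               / np.logical_or(aligned, canonical).sum())
        assert iou >= 0.97

    def test_alignment_preserves_mask_area(self):
        img = _ellipse_image(rotation=5.0)
        sl = make_slice(img)
        m = slicestack.make_dapi_mask(sl, blur_sigma=0, threshold=500.0)
        st = slicestack.align_midline([(sl, m)])
        assert st.slices[0].mask.area_mm2 == pytest.approx(m.area_mm2,
                                                           rel=0.005)

    def test_degenerate_mask_flagged_not_aligned(self):
        img = np.zeros((200, 200))
        img[100:104, 100:104] = 1000.0
        sl = make_slice(img)
        m = slicestack.make_dapi_mask(sl, blur_sigma=0, threshold=500.0)
        with pytest.warns(UserWarning, match="degenerate"):
            st = slicestack.align_midline([(sl, m)], min_area_mm2=0.5)
        assert st.slices[0].flagged
        assert st.slices[0].transform.rotation_deg == 0.0

    def test_phantom_planted_transforms_recovered(self, sphere_spec):
        """Misaligned phantom slices: rotations recovered within 1° and the
        aligned footprints restored onto the analytic centered ellipse."""
        from dataclasses import replace
        from cortiquant import phantom
        from cortiquant.phantom import _ellipse_mask

        spec = replace(sphere_spec, rng_seed=31,
                       misalign_rotation_deg_sd=4.0,
                       misalign_translation_px_sd=10.0,
                       slice_positions_mm=(1.1, 0.9, 0.7, 0.5))
        slices, truth = phantom.generate_slice_stack(spec)
        masks = [slicestack.make_dapi_mask(s) for s in slices]
        st = slicestack.align_midline(list(zip(slices, masks)))
        planted = {s.slice_id: t for s, t in zip(slices,
                                                 truth.planted_transforms)}
        shape = slices[0].shape
        px_mm = 1000.0 / spec.pixel_size_um
        A, B = spec.footprint_semiaxes_mm
        canonical = _ellipse_mask(
            shape, ((shape[0] - 1) / 2, (shape[1] - 1) / 2),
            (B * px_mm, A * px_mm))
        ok = 0
        for a in st.slices:
            rot, _ = planted[a.image.slice_id]
            filled = ndimage.binary_fill_holes(a.mask.mask)
            iou = (np.logical_and(filled, canonical).sum()
                   / np.logical_or(filled, canonical).sum())
            if abs(-a.transform.rotation_deg - rot) <= 1.0 and iou >= 0.97:
                ok += 1
        assert ok >= 0.95 * len(st.slices)
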