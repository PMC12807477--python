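"""Segmentation, compartment masks, morphometry, colocalization, stats."""
import numpy as np
import pytest

from oracles import feret_all_points
from ubnexus.imaging import (NucleusROI, bright_mask, compartment_pearson,
                             feret_diameters, nucleus_intensity_stats,
                             object_shapes, segment_nuclei)
from ubnexus.synthetic import ellipse_mask


def _disc(shape=(100, 100), center=(50, 50), r=15):
    return ellipse_mask(shape, center, (r, r))


def test_single_nucleus_area_matches_analytic():
    img = np.where(ellipse_mask((256, 256), (128, 128), (90, 70)), 3000.0, 20.0)
    rois = segment_nuclei(img)
    assert len(rois) == 1
    analytic = np.pi * 90 * 70
    assert abs(rois[0].area - analytic) / analytic < 0.02


def test_blank_image_yields_no_rois():
    assert segment_nuclei(np.zeros((64, 64))) == []


def test_two_disjoint_nuclei_yield_two_rois():
    img = np.full((128, 256), 20.0)
    img[ellipse_mask((128, 256), (64, 64), (40, 40))] = 3000.0
    img[ellipse_mask((128, 256), (64, 192), (40, 40))] = 3000.0
    assert len(segment_nuclei(img)) == 2


def test_bright_dim_partition_is_exact():
    nuc = ellipse_mask((128, 128), (64, 64), (50, 40))
    roi = NucleusROI(mask=nuc, label=1, area=int(nuc.sum()))
    npm1 = np.where(nuc, 800.0, 20.0)
    npm1[_disc((128, 128), (64, 64), 10)] = 3000.0
    comp = bright_mask(npm1, roi)
    assert not comp.degenerate
    assert np.array_equal(comp.bright | comp.dim, roi.mask)
    assert not (comp.bright & comp.dim).any()


def test_uniform_roi_is_degenerate():
    nuc = ellipse_mask((64, 64), (32, 32), (20, 20))
    roi = NucleusROI(mask=nuc, label=1, area=int(nuc.sum()))
    comp = bright_mask(np.full((64, 64), 5.0), roi)
    assert comp.degenerate
    assert comp.bright.sum() == 0
    assert np.array_equal(comp.dim, roi.mask)


def test_planted_bright_disc_recovered_with_high_iou():
    nuc = ellipse_mask((128, 128), (64, 64), (55, 45))
    roi = NucleusROI(mask=nuc, label=1, area=int(nuc.sum()))
    planted = _disc((128, 128), (60, 60), 12)
    npm1 = np.where(nuc, 800.0, 20.0)
    npm1[planted] = 3000.0
    comp = bright_mask(npm1, roi)
    iou = (comp.bright & planted).sum() / (comp.bright | planted).sum()
    assert iou >= 0.9


def test_disc_circularity_near_one():
    shapes = object_shapes(_disc())
    assert len(shapes) == 1
    assert shapes[0].circularity == pytest.approx(1.0, abs=0.05)
    assert shapes[0].aspect_ratio == pytest.approx(1.0, abs=0.05)


def test_ellipse_aspect_ratio_near_planted():
    mask = ellipse_mask((128, 128), (64, 64), (20, 10))
    shapes = object_shapes(mask)
    assert len(shapes) == 1
    assert shapes[0].aspect_ratio == pytest.approx(0.5, abs=0.05)
    assert shapes[0].min_feret <= shapes[0].max_feret


def test_object_count_and_min_area_monotonicity():
    mask = np.zeros((128, 128), dtype=bool)
    mask |= _disc((128, 128), (30, 30), 12)
    mask |= _disc((128, 128), (90, 90), 6)
    mask |= _disc((128, 128), (30, 90), 3)
    counts = [len(object_shapes(mask, min_area=a)) for a in (1, 30, 200, 10000)]
    assert counts[0] == 3
    assert counts == sorted(counts, reverse=True)


def test_feret_matches_all_points_oracle(rng):
    for _ in range(20):
        mask = ellipse_mask((96, 96), (48, 48),
                            (rng.uniform(5, 25), rng.uniform(5, 25)),
                            angle=rng.uniform(0, np.pi))
        coords = np.argwhere(mask)
        mn, mx = feret_diameters(coords)
        mn_ref, mx_ref = feret_all_points(coords)
        assert mn == pytest.approx(mn_ref, rel=1e-9, abs=1e-9)
        assert mx == pytest.approx(mx_ref, rel=1e-9, abs=1e-9)


def test_shape_metrics_invariant_to_translation_and_rotation():
    base = ellipse_mask((160, 160), (60, 60), (20, 10), angle=0.0)
    shifted = np.roll(np.roll(base, 30, axis=0), 25, axis=1)
    rot90 = np.rot90(base)
    ref = object_shapes(base)[0]
    for variant in (shifted, rot90):
        s = object_shapes(variant)[0]
        assert s.area == ref.area
        assert s.perimeter == pytest.approx(ref.perimeter, rel=1e-9)
        assert s.aspect_ratio == pytest.approx(ref.aspect_ratio, rel=1e-9)
        assert s.circularity == pytest.approx(ref.circularity, rel=1e-9)


def test_compartment_pearson_limits():
    nuc = ellipse_mask((64, 64), (32, 32), (25, 20))
    bright = _disc((64, 64), (32, 32), 8) & nuc
    dim = nuc & ~bright
    rng = np.random.default_rng(0)
    a = rng.normal(100, 10, size=(64, 64))
    r_b, r_d = compartment_pearson(a, a, bright, dim)
    assert r_b == pytest.approx(1.0)
    assert r_d == pytest.approx(1.0)
    r_b, r_d = compartment_pearson(a, -a + 500.0, bright, dim)
    assert r_b == pytest.approx(-1.0)
    assert r_d == pytest.approx(-1.0)


def test_dim_compartment_coupling_detected(rng):
    from ubnexus.config import ImageSimConfig
    from ubnexus.synthetic import gen_nucleus_images
    icfg = ImageSimConfig(n_images=2)
    stacks, _ = gen_nucleus_images(icfg, rng)
    for stack in stacks:
        rois = segment_nuclei(stack[0])
        assert len(rois) == 1
        comp = bright_mask(stack[1], rois[0])
        r_bright, r_dim = compartment_pearson(stack[1], stack[2],
                                              comp.bright, comp.dim)
        assert r_dim > r_bright


def test_nucleus_intensity_stats_closed_forms():
    nuc = np.zeros((10, 10), dtype=bool)
    nuc[:, :] = True
    roi = NucleusROI(mask=nuc, label=1, area=100)
    uniform = np.full((10, 10), 7.0)
    mfi, sd = nucleus_intensity_stats(uniform, roi)
    assert mfi == 7.0 and sd == 0.0
    two_level = np.full((10, 10), 2.0)
    two_level[5:, :] = 8.0
    mfi, sd = nucleus_intensity_stats(two_level, roi)
    assert mfi == pytest.approx(5.0)
    assert sd == pytest.approx(3.0)  # |a-b|/2 for a half/half split
    rng = np.random.default_rng(1)
    noisy = rng.uniform(0, 100, size=(10, 10))
    mfi, sd = nucleus_intensity_stats(noisy, roi)
    assert mfi == pytest.approx(noisy.mean(), rel=1e-12)
    assert sd == pytest.approx(noisy.std(), rel=1e-12)
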