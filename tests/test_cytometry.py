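"""OD transform, segmentation and morphometric measurement."""

import numpy as np
import pytest

from meioscope import cytometry
from meioscope.cytometry import (
    ODImage,
    correct_and_transform,
    measure,
    segment,
    segment_and_measure,
)
from meioscope.imaging import EmptyField, FieldImage

from conftest import match_stage


def _pair(incident, transmitted, px=0.16):
    return (
        FieldImage(transmitted=np.asarray(transmitted, float), pixel_size_um=px),
        EmptyField(incident=np.asarray(incident, float)),
    )


def _disc_od(shape, centers, r, value, px=0.16):
    od = np.zeros(shape)
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        od[(ys - cy) ** 2 + (xs - cx) ** 2 <= r * r] += value
    return ODImage(od=od, pixel_size_um=px)


class TestCorrectAndTransform:
    def test_identity_gives_zero_od(self):
        f, e = _pair(np.full((8, 8), 500.0), np.full((8, 8), 500.0))
        assert np.all(correct_and_transform(f, e).od == 0.0)

    @pytest.mark.parametrize(
        "inc,trans,expected",
        [(100.0, 10.0, 1.0), (200.0, 50.0, np.log10(4.0)), (300.0, 300.0, 0.0)],
    )
    def test_closed_form_pixels(self, inc, trans, expected):
        f, e = _pair(np.full((4, 4), inc), np.full((4, 4), trans))
        assert correct_and_transform(f, e).od[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_transmitted_floored_at_quantization_step(self):
        f, e = _pair(np.full((2, 2), 100.0), np.zeros((2, 2)))
        od = correct_and_transform(f, e, quantization_step=1.0)
        assert np.all(od.od == 2.0)  # log10(100/1)

    def test_shape_mismatch_and_bad_incident(self):
        f, e = _pair(np.full((4, 4), 100.0), np.full((3, 3), 10.0))
        with pytest.raises(ValueError):
            correct_and_transform(f, e)
        f, e = _pair(np.zeros((4, 4)), np.full((4, 4), 10.0))
        with pytest.raises(ValueError):
            correct_and_transform(f, e)


class TestSegment:
    def test_all_zero_image_yields_nothing(self):
        assert segment(ODImage(od=np.zeros((64, 64)), pixel_size_um=0.16)) == []

    def test_two_separated_discs(self):
        odi = _disc_od((128, 128), [(40, 40), (90, 90)], r=12, value=0.5)
        masks = segment(odi)
        assert len(masks) == 2
        true_area = ((odi.od > 0).sum() / 2) * 0.16**2
        for m in masks:
            assert m.sum() * 0.16**2 == pytest.approx(true_area, rel=0.05)

    def test_touching_discs_split_by_watershed(self):
        r = 12
        odi = _disc_od((128, 128), [(64, 50), (64, 50 + int(1.8 * r))], r=r, value=0.5)
        masks = segment(odi)
        assert len(masks) == 2

    def test_area_window_filters(self):
        odi = _disc_od((128, 128), [(64, 64)], r=2, value=0.5)  # ~0.3 µm²
        assert segment(odi, min_area_um2=1.0) == []


class TestMeasure:
    def test_uniform_disc_features(self):
        odi = _disc_od((64, 64), [(32, 32)], r=10, value=0.5)
        mask = odi.od > 0
        obj = measure(mask, odi)
        npix = int(mask.sum())
        assert obj.iod == pytest.approx(0.5 * npix, rel=1e-12)
        assert obj.od_texture == 0.0
        assert obj.mean_od == pytest.approx(0.5)
        assert obj.equivalent_diameter_um == pytest.approx(
            2 * np.sqrt(obj.area_um2 / np.pi)
        )
        assert 0.8 < obj.circularity <= 1.05
        assert obj.elongation == pytest.approx(1.0, abs=0.05)

    def test_mask_on_zero_image_gives_zero_iod(self):
        odi = ODImage(od=np.zeros((32, 32)), pixel_size_um=0.16)
        mask = np.zeros((32, 32), bool)
        mask[10:14, 10:14] = True
        assert measure(mask, odi).iod == 0.0

    def test_empty_mask_raises(self):
        odi = ODImage(od=np.zeros((16, 16)), pixel_size_um=0.16)
        with pytest.raises(ValueError):
            measure(np.zeros((16, 16), bool), odi)

    def test_iod_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(0)
        od = ODImage(od=rng.uniform(0, 1, (32, 32)), pixel_size_um=0.16)
        m1 = np.zeros((32, 32), bool)
        m2 = np.zeros((32, 32), bool)
        m1[2:10, 2:10] = True
        m2[20:30, 12:25] = True
        total = measure(m1 | m2, od).iod
        parts = measure(m1, od).iod + measure(m2, od).iod
        # exact up to float summation order
        assert total == pytest.approx(parts, rel=1e-12)


def test_illumination_scale_invariance():
    """Multiplying both field and empty reference by one positive factor
    leaves every feature unchanged."""
    rng = np.random.default_rng(4)
    inc = np.full((96, 96), 20000.0)
    od_true = _disc_od((96, 96), [(48, 48)], r=14, value=0.4).od
    trans = inc * 10.0**-od_true
    f1, e1 = FieldImage(trans, 0.16), EmptyField(inc)
    f2, e2 = FieldImage(trans * 3.7, 0.16), EmptyField(inc * 3.7)
    o1 = segment_and_measure(correct_and_transform(f1, e1))
    o2 = segment_and_measure(correct_and_transform(f2, e2))
    assert len(o1) == len(o2) == 1
    for attr in ("area_um2", "iod", "mean_od", "circularity", "elongation"):
        assert getattr(o1[0], attr) == pytest.approx(getattr(o2[0], attr), abs=1e-6)


def test_segmentation_matches_ground_truth(clean_objects):
    """On a noise-free render, every nucleus is recovered with Jaccard >= 0.9
    and measured IOD tracks the painted absorbance with R^2 > 0.99."""
    objs, od, truth = clean_objects
    assert len(objs) == 50
    ious, measured, true = [], [], []
    for o in objs:
        _, lab = match_stage(o, truth)
        gtm = truth.label_mask == lab
        ious.append((o.mask & gtm).sum() / (o.mask | gtm).sum())
        measured.append(o.iod)
        true.append(float(truth.objects.set_index("label").loc[lab, "true_iod"]))
    assert min(ious) >= 0.9
    r2 = np.corrcoef(true, measured)[0, 1] ** 2
    assert r2 > 0.99


def test_measured_iod_ratio_2c_vs_1c(clean_objects):
    """Measured IODs of rendered 2C vs 1C nuclei keep the 2:1 ratio within
    the boundary-pixel tolerance."""
    objs, od, truth = clean_objects
    by_c = {1.0: [], 2.0: []}
    for o in objs:
        _, lab = match_stage(o, truth)
        c = float(truth.objects.set_index("label").loc[lab, "true_c"])
        if c in by_c:
            by_c[c].append(o.iod)
    ratio = np.mean(by_c[2.0]) / np.mean(by_c[1.0])
    assert ratio == pytest.approx(2.0, rel=0.02)
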