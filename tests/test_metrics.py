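"""Area, thickness-profile and volume measurements."""

import numpy as np
import pytest
import shapely

from octgraft import (Calibration, CornerSet, GraftCurve, GraftSegmentation,
                      compute_area, estimate_volume, segmentation_from_truth,
                      thickness_profile)
from octgraft.errors import GeometryError, ParameterError
from octgraft.metrics import graft_polygon
from octgraft.phantom import generate_phantom

from conftest import random_lens_spec


def rectangle_segmentation(width=200.0, thickness=50.0, top=100.0):
    ant = GraftCurve(np.array([[0.0, top], [width / 2, top], [width, top]]),
                     smoothing=0.0)
    post = GraftCurve(np.array([[0.0, top + thickness],
                                [width / 2, top + thickness],
                                [width, top + thickness]]), smoothing=0.0)
    corners = CornerSet((0.0, top), (0.0, top + thickness),
                        (width, top), (width, top + thickness))
    return GraftSegmentation(anterior=ant, posterior=post, corners=corners,
                             mode="semi_automated", image_shape=(256, 256))


def test_rectangle_area_is_exact():
    seg = rectangle_segmentation(200.0, 50.0)
    area = compute_area(seg, Calibration(10.0, 10.0))
    assert area.area_um2 == pytest.approx(1_000_000.0, rel=1e-9)


def test_lens_truth_curves_match_closed_form(clean_phantom):
    _, truth = clean_phantom
    seg = segmentation_from_truth(truth, n_points=200)
    area = compute_area(seg, truth.spec.calibration)
    assert area.area_um2 == pytest.approx(truth.true_area_um2, rel=1e-3)


def rasterized_area_px2(seg, ss: int = 8) -> float:
    """Brute-force oracle: count sub-pixel sample points inside the graft
    outline (ss^2 samples per pixel)."""
    poly = graft_polygon(seg)
    (x0, y0, x1, y1) = poly.bounds
    xs = np.arange(np.floor(x0), np.ceil(x1) + 1, 1 / ss)
    ys = np.arange(np.floor(y0), np.ceil(y1) + 1, 1 / ss)
    gx, gy = np.meshgrid(xs, ys)
    shapely.prepare(poly)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
    return float(inside.sum()) / ss ** 2


def test_shoelace_vs_rasterization_on_random_phantoms():
    """Shoelace area agrees with pixel counting within 0.5% over random
    lens geometries."""
    rng = np.random.default_rng(2024)
    for _ in range(50):
        spec = random_lens_spec(rng)
        _, truth = generate_phantom(spec)
        seg = segmentation_from_truth(truth, n_points=100)
        shoe = float(graft_polygon(seg).area)
        raster = rasterized_area_px2(seg)
        assert abs(shoe - raster) / shoe < 0.005


def test_uniform_band_thickness_profile():
    seg = rectangle_segmentation(200.0, 50.0)
    prof = thickness_profile(seg, Calibration(10.0, 10.0), n_samples=21)
    np.testing.assert_allclose(prof.thickness_um, 500.0, atol=1e-9)
    assert prof.lateral_um[0] == 0.0
    assert prof.lateral_um[-1] == pytest.approx(2000.0)


def test_lens_profile_peaks_at_apex(clean_phantom):
    _, truth = clean_phantom
    seg = segmentation_from_truth(truth, n_points=100)
    prof = thickness_profile(seg, truth.spec.calibration, n_samples=201)
    apex = np.argmax(prof.thickness_um)
    assert abs(prof.lateral_um[apex] - prof.lateral_um[-1] / 2) \
        <= 0.05 * prof.lateral_um[-1]


def test_profile_integral_equals_area_on_random_phantoms():
    """Trapezoidal integral of the thickness profile reproduces the
    shoelace area within 1%."""
    rng = np.random.default_rng(7)
    cal = Calibration(18.0, 18.0)
    for _ in range(10):
        spec = random_lens_spec(rng)
        _, truth = generate_phantom(spec)
        seg = segmentation_from_truth(truth, n_points=100)
        prof = thickness_profile(seg, cal, n_samples=400)
        area = compute_area(seg, cal).area_um2
        assert prof.integral_um2() == pytest.approx(area, rel=0.01)


def test_profile_needs_two_samples(clean_phantom):
    _, truth = clean_phantom
    seg = segmentation_from_truth(truth)
    with pytest.raises(ParameterError):
        thickness_profile(seg, truth.spec.calibration, n_samples=1)


def test_area_invariant_under_horizontal_flip(clean_phantom):
    _, truth = clean_phantom
    seg = segmentation_from_truth(truth, n_points=60)
    w = truth.spec.image_width
    def flip(curve):
        pts = curve.control_points[::-1].copy()
        pts[:, 0] = (w - 1) - pts[:, 0]
        return GraftCurve(pts, smoothing=curve.smoothing)
    corners = seg.corners
    flipped = GraftSegmentation(
        anterior=flip(seg.anterior), posterior=flip(seg.posterior),
        corners=CornerSet(
            left_anterior=((w - 1) - corners.right_anterior[0], corners.right_anterior[1]),
            left_posterior=((w - 1) - corners.right_posterior[0], corners.right_posterior[1]),
            right_anterior=((w - 1) - corners.left_anterior[0], corners.left_anterior[1]),
            right_posterior=((w - 1) - corners.left_posterior[0], corners.left_posterior[1]),
        ),
        mode=seg.mode, image_shape=seg.image_shape)
    cal = truth.spec.calibration
    assert compute_area(flipped, cal).area_um2 == pytest.approx(
        compute_area(seg, cal).area_um2, rel=1e-6)


def test_dimensional_scaling_law(clean_phantom):
    """Doubling both pixel pitches quadruples area and doubles thickness."""
    _, truth = clean_phantom
    seg = segmentation_from_truth(truth)
    c1, c2 = Calibration(10.0, 12.0), Calibration(20.0, 24.0)
    assert compute_area(seg, c2).area_um2 == pytest.approx(
        4 * compute_area(seg, c1).area_um2)
    p1 = thickness_profile(seg, c1, 50)
    p2 = thickness_profile(seg, c2, 50)
    np.testing.assert_allclose(p2.thickness_um, 2 * p1.thickness_um)


def test_volume_estimate_as_printed_convention():
    v = estimate_volume(20_000.0, 8.5)
    assert v.value == pytest.approx(170_000.0, rel=1e-12)
    assert "as-printed" in v.convention
    assert estimate_volume(0.0, 8.5).value == 0.0
    assert estimate_volume(12345.0, 1.0).value == pytest.approx(12345.0)


def test_volume_estimate_consistent_units():
    v = estimate_volume(20_000.0, 8.5, consistent_units=True)
    assert v.value == pytest.approx(1.7e8)  # µm² x 8500 µm
    with pytest.raises(ParameterError):
        estimate_volume(20_000.0, -1.0)


def test_negative_area_rejected():
    from octgraft import AreaMeasurement
    with pytest.raises(GeometryError):
        AreaMeasurement(area_um2=-1.0, mode="automated")
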