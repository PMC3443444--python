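"""Corner detection, interface extraction, curve fitting, refinement."""

import dataclasses

import numpy as np
import pytest

from octgraft import (Calibration, CornerSet, OCTImage, SampledBoundary,
                      adjust_control_points, compute_area, detect_corners,
                      extract_anterior_interface, fit_graft, generate_phantom,
                      segment_automated, segmentation_from_truth, snap_to_truth)
from octgraft.errors import (CornerDetectionError, GeometryError,
                             LowContrastError, ParameterError)

CAL = Calibration(18.0, 18.0)


# ---------------------------------------------------------------------------
# corner detection

def rectangle_contour(x0=50, y0=60, x1=250, y1=160, step=2.0):
    top = [(x, y0) for x in np.arange(x0, x1, step)]
    right = [(x1, y) for y in np.arange(y0, y1, step)]
    bottom = [(x, y1) for x in np.arange(x1, x0, -step)]
    left = [(x0, y) for y in np.arange(y1, y0, -step)]
    return np.array(top + right + bottom + left)


def test_rectangle_contour_yields_its_four_vertices():
    corners = detect_corners(rectangle_contour())
    got = {k: v for k, v in corners.as_dict().items()}
    assert got["left_anterior"] == pytest.approx((50, 60), abs=1.0)
    assert got["left_posterior"] == pytest.approx((50, 160), abs=1.0)
    assert got["right_anterior"] == pytest.approx((250, 60), abs=1.0)
    assert got["right_posterior"] == pytest.approx((250, 160), abs=1.0)


def test_circle_contour_has_no_corners():
    t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    circle = np.column_stack([150 + 80 * np.cos(t), 150 + 80 * np.sin(t)])
    with pytest.raises(CornerDetectionError):
        detect_corners(circle)


def test_pipeline_corners_on_noise_free_lens(biconvex_phantom):
    """Full corner localisation lands within 3 px of the true arc
    endpoints on a noise-free lens phantom."""
    image, truth = biconvex_phantom
    seg = segment_automated(image)
    for key, det in seg.corners.as_dict().items():
        ref = truth.corners[0] if "left" in key else truth.corners[1]
        assert abs(det[0] - ref[0]) <= 3.0
        assert abs(det[1] - ref[1]) <= 3.0


def test_corner_detection_equivariant_to_horizontal_flip():
    from octgraft import PhantomSpec
    spec = PhantomSpec.default(corner_cols=(100.0, 380.0))
    image, _ = generate_phantom(spec)
    seg = segment_automated(image)
    mirrored = OCTImage(image.pixels[:, ::-1], image.calibration, image_id="flip")
    seg_m = segment_automated(mirrored)
    w = spec.image_width
    xl, xr = seg.corners.span
    xl_m, xr_m = seg_m.corners.span
    assert abs((w - 1 - xr) - xl_m) <= 1.0
    assert abs((w - 1 - xl) - xr_m) <= 1.0


def test_cornerset_invariants():
    with pytest.raises(GeometryError):
        CornerSet((100, 50), (100, 60), (90, 50), (90, 60))  # left right of right
    with pytest.raises(GeometryError):
        CornerSet((10, 80), (10, 60), (90, 50), (90, 60))  # anterior below posterior


# ---------------------------------------------------------------------------
# anterior-interface extraction

def band_image(k: int, height=160, width=200, post_row=100):
    """Host stroma over a graft band of thickness k over dark background."""
    px = np.full((height, width), 0.05)
    px[30:post_row - k, :] = 0.8        # host stroma
    px[post_row - k:post_row, :] = 0.4  # graft band
    return OCTImage(px, CAL)


def test_interface_recovered_at_known_offset():
    """A band whose interface sits exactly k px above the posterior
    boundary is recovered with ~1 px accuracy."""
    k = 8
    img = band_image(k)
    corners = CornerSet((20.0, 92.0), (20.0, 100.0), (180.0, 92.0), (180.0, 100.0))
    post = SampledBoundary(np.arange(20.0, 181.0, 10.0),
                           np.full(17, 100.0), sampling_step=10)
    iface = extract_anterior_interface(img, corners, post)
    assert len(iface) >= 10
    assert np.max(np.abs(iface.rows - (100 - k))) <= 1.5


def test_interface_accuracy_on_phantom(clean_phantom):
    image, truth = clean_phantom
    seg = segment_automated(image)
    xl, xr = truth.corners[0][0], truth.corners[1][0]
    xs = np.linspace(xl + 30, xr - 30, 60)
    err = seg.anterior.rows(xs) - truth.anterior_interface.row_at(xs)
    assert (np.abs(err) <= 2.0).mean() >= 0.90


def test_zero_contrast_interface_fails_loudly(default_spec):
    image, _ = generate_phantom(
        dataclasses.replace(default_spec, interface_contrast=0.0))
    with pytest.raises(LowContrastError):
        segment_automated(image)


# ---------------------------------------------------------------------------
# curve fitting

def flat_boundary(row, x0=20.0, x1=300.0, step=10.0):
    cols = np.arange(x0, x1 + 1, step)
    return SampledBoundary(cols, np.full(cols.size, row), sampling_step=10)


def test_collinear_points_fit_exactly():
    corners = CornerSet((20.0, 100.0), (20.0, 130.0), (300.0, 100.0), (300.0, 130.0))
    seg = fit_graft(flat_boundary(100.0), flat_boundary(130.0), corners,
                    image_shape=(200, 320))
    xs = np.linspace(20, 300, 100)
    np.testing.assert_allclose(seg.anterior.rows(xs), 100.0, atol=1e-6)
    np.testing.assert_allclose(seg.posterior.rows(xs), 130.0, atol=1e-6)
    assert seg.mode == "automated"


def test_arc_points_fit_within_half_pixel(clean_phantom):
    _, truth = clean_phantom
    ant, post = truth.anterior_interface, truth.posterior_boundary
    cols = np.arange(ant.p1[0] + 10, ant.p2[0] - 9, 10.0)
    a_pts = SampledBoundary(cols, ant.row_at(cols), sampling_step=10)
    p_pts = SampledBoundary(cols, post.row_at(cols), sampling_step=10)
    corners = CornerSet(ant.p1, post.p1, ant.p2, post.p2)
    seg = fit_graft(a_pts, p_pts, corners, image_shape=(384, 512))
    xs = np.linspace(ant.p1[0], ant.p2[0], 300)
    assert np.max(np.abs(seg.anterior.rows(xs) - ant.row_at(xs))) < 0.5
    assert np.max(np.abs(seg.posterior.rows(xs) - post.row_at(xs))) < 0.5


def test_inverted_boundaries_violate_thickness_invariant():
    corners = CornerSet((20.0, 110.0), (20.0, 110.0), (300.0, 110.0), (300.0, 110.0))
    with pytest.raises(GeometryError, match="thickness"):
        fit_graft(flat_boundary(130.0), flat_boundary(100.0), corners,
                  image_shape=(200, 320))


def test_degenerate_span_rejected():
    corners = CornerSet((20.0, 100.0), (20.0, 110.0), (25.0, 100.0), (25.0, 110.0))
    b = SampledBoundary(np.array([21.0, 24.0]), np.array([100.0, 100.0]))
    with pytest.raises(GeometryError, match="span"):
        fit_graft(b, b, corners, image_shape=(200, 320))


# ---------------------------------------------------------------------------
# semi-automated refinement

def test_empty_edit_list_only_changes_mode(clean_phantom):
    _, truth = clean_phantom
    seg = segmentation_from_truth(truth, mode="automated")
    out = adjust_control_points(seg, [])
    assert out.mode == "semi_automated"
    np.testing.assert_array_equal(out.anterior.control_points,
                                  seg.anterior.control_points)
    np.testing.assert_array_equal(out.posterior.control_points,
                                  seg.posterior.control_points)


def test_posterior_edit_increases_area_by_spline_bump_integral(clean_phantom):
    """Moving one posterior control point down adds exactly the area under
    the induced spline bump (numeric quadrature oracle)."""
    _, truth = clean_phantom
    seg = segmentation_from_truth(truth)
    idx = seg.posterior.control_points.shape[0] // 2
    col, row = seg.posterior.control_points[idx]
    out = adjust_control_points(seg, [("posterior", idx, (col, row + 6.0))])
    cal = truth.spec.calibration
    a0 = compute_area(seg, cal).area_um2
    a1 = compute_area(out, cal).area_um2
    assert a1 > a0
    lo, hi = seg.span
    xs = np.linspace(lo, hi, 4000)
    bump = np.trapezoid(out.posterior.rows(xs) - seg.posterior.rows(xs), xs)
    assert (a1 - a0) == pytest.approx(bump * cal.um2_per_px2, rel=2e-2)


def test_edit_outside_image_rejected(clean_phantom):
    _, truth = clean_phantom
    seg = segmentation_from_truth(truth)
    with pytest.raises(ParameterError, match="outside"):
        adjust_control_points(seg, [("posterior", 0, (-10.0, 50.0))])


def test_edit_breaking_single_valuedness_rejected(clean_phantom):
    _, truth = clean_phantom
    seg = segmentation_from_truth(truth)
    c0 = seg.anterior.control_points[0]
    with pytest.raises(GeometryError, match="single-valuedness"):
        adjust_control_points(seg, [("anterior", 1, (c0[0] - 1.0, c0[1]))])


def test_edit_creating_negative_thickness_rejected(clean_phantom):
    _, truth = clean_phantom
    seg = segmentation_from_truth(truth)
    idx = seg.posterior.control_points.shape[0] // 2
    col, row = seg.posterior.control_points[idx]
    with pytest.raises(GeometryError, match="thickness"):
        adjust_control_points(seg, [("posterior", idx, (col, row - 50.0))])


# ---------------------------------------------------------------------------
# full pipeline

def test_automated_pipeline_recovers_area(clean_phantom):
    image, truth = clean_phantom
    seg = segment_automated(image)
    area = compute_area(seg, truth.spec.calibration)
    assert area.area_um2 == pytest.approx(truth.true_area_um2, rel=0.02)
    assert area.mode == "automated"


def test_blank_image_fails_at_corner_detection():
    img = OCTImage(np.full((128, 128), 0.3), CAL)
    with pytest.raises(CornerDetectionError):
        segment_automated(img)


def test_thickness_nonnegative_everywhere(speckled_phantom):
    image, _ = speckled_phantom
    seg = segment_automated(image)
    xs = np.linspace(*seg.span, 500)
    assert seg.thickness_px(xs).min() >= 0.0


def test_truth_snapped_refinement_recovers_area(speckled_phantom):
    """Refining the automated result onto the true curves gives the true
    area within 1% — the refinement API can correct any automated error."""
    image, truth = speckled_phantom
    seg = segment_automated(image)
    snapped = snap_to_truth(seg, truth)
    assert snapped.mode == "semi_automated"
    area = compute_area(snapped, truth.spec.calibration)
    assert area.area_um2 == pytest.approx(truth.true_area_um2, rel=0.01)
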