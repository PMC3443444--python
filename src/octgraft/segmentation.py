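"""Graft segmentation: corner detection, interface extraction, curve fitting.

Steps 2-4 of the pipeline.  Four corner points are located on the extracted
boundary from its discrete curvature (k-cosine dominant-point detection);
the low-contrast host-graft interface is traced by an axial gradient search
in a band anterior to the posterior boundary; smoothing splines through the
two point sets, pinned to the corners, close the graft region.  A
semi-automated mode re-fits the curves after user edits of the control
points, re-checking every geometric invariant.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.ndimage import gaussian_filter, median_filter, uniform_filter1d

from .boundary import (EdgeMap, SampledBoundary, detect_edges, preprocess,
                       refine_rows_subpixel, sample_boundary)
from .config import CornerParams, InterfaceParams, RunConfig, SplineParams
from .errors import (CornerDetectionError, EmptyBoundaryError, GeometryError,
                     LowContrastError, OCTGraftError, ParameterError)
from .io import OCTImage

log = logging.getLogger("octgraft.segmentation")

__all__ = ["CornerSet", "GraftCurve", "GraftSegmentation", "detect_corners",
           "extract_anterior_interface", "fit_graft", "adjust_control_points",
           "segment_automated", "segmentation_from_truth", "snap_to_truth"]

#: residual thickness tolerance (px): spline-overshoot crossings up to
#: this depth (near the corners, where both curves meet) are clamped to
#: zero thickness; deeper crossings are invariant violations
_THICKNESS_TOL = 2.5


@dataclass(frozen=True)
class CornerSet:
    """The four points where the graft band's boundaries terminate.

    For a lens-shaped graft whose anterior and posterior arcs share their
    endpoints, the anterior and posterior corner of a side coincide.
    """

    left_anterior: tuple[float, float]
    left_posterior: tuple[float, float]
    right_anterior: tuple[float, float]
    right_posterior: tuple[float, float]

    def __post_init__(self):
        if not (self.left_anterior[0] < self.right_anterior[0]
                and self.left_posterior[0] < self.right_posterior[0]):
            raise GeometryError("left corner columns must lie left of right corners")
        for side in ("left", "right"):
            ant = getattr(self, f"{side}_anterior")
            post = getattr(self, f"{side}_posterior")
            if ant[1] > post[1] + 1e-6:
                raise GeometryError(
                    f"{side} anterior corner must not lie below the posterior corner"
                )

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {k: getattr(self, k) for k in
                ("left_anterior", "left_posterior", "right_anterior", "right_posterior")}

    @property
    def span(self) -> tuple[float, float]:
        return (self.left_anterior[0], self.right_anterior[0])


@dataclass(frozen=True)
class GraftCurve:
    """A boundary curve: control points plus a cubic smoothing spline.

    The spline minimises curvature subject to a residual budget of
    ``smoothing`` px² per control point (0 = interpolating) and is then
    linearly corrected to pass *exactly* through its two endpoints, which
    are the corners.  Single-valued in column by construction.
    """

    control_points: np.ndarray  # (n, 2), (col, row), strictly increasing col
    smoothing: float = 1.0

    def __post_init__(self):
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise GeometryError("need an (n>=2, 2) array of control points")
        if not np.all(np.diff(pts[:, 0]) > 0):
            raise GeometryError(
                "control-point columns must be strictly increasing (single-valuedness)"
            )
        if self.smoothing < 0:
            raise ParameterError("smoothing must be >= 0")
        object.__setattr__(self, "control_points", pts)

    @property
    def domain(self) -> tuple[float, float]:
        return (float(self.control_points[0, 0]), float(self.control_points[-1, 0]))

    @cached_property
    def _spline(self):
        x, y = self.control_points[:, 0], self.control_points[:, 1]
        n = x.size
        k = min(3, n - 1)
        if self.smoothing == 0.0 or n <= 4:
            spl = UnivariateSpline(x, y, k=k, s=0.0)
        else:
            w = np.ones(n)
            w[0] = w[-1] = 1e6  # corners effectively interpolated
            spl = UnivariateSpline(x, y, w=w, k=k, s=self.smoothing * n)
        # exact endpoint correction (linear ramp over the residuals)
        r0 = y[0] - spl(x[0])
        r1 = y[-1] - spl(x[-1])
        return spl, float(r0), float(r1)

    def rows(self, cols: np.ndarray) -> np.ndarray:
        """Row of the curve at the given columns."""
        cols = np.asarray(cols, dtype=float)
        x0, x1 = self.domain
        if np.any(cols < x0 - 1e-6) or np.any(cols > x1 + 1e-6):
            raise GeometryError("column outside the curve's lateral domain")
        spl, r0, r1 = self._spline
        t = (cols - x0) / (x1 - x0)
        return spl(cols) + r0 + t * (r1 - r0)


@dataclass(frozen=True)
class GraftSegmentation:
    """Closed graft region between the anterior-interface and posterior curves."""

    anterior: GraftCurve
    posterior: GraftCurve
    corners: CornerSet
    mode: str
    image_shape: tuple[int, int]

    def __post_init__(self):
        if self.mode not in ("automated", "semi_automated"):
            raise ParameterError(f"mode must be automated|semi_automated, got {self.mode!r}")
        a0, a1 = self.anterior.domain
        p0, p1 = self.posterior.domain
        if abs(a0 - p0) > 0.5 or abs(a1 - p1) > 0.5:
            raise GeometryError(
                f"curves must share the lateral domain: anterior [{a0}, {a1}] "
                f"vs posterior [{p0}, {p1}]"
            )
        lo, hi = max(a0, p0), min(a1, p1)
        if hi - lo < 10:
            raise GeometryError(f"degenerate lateral span ({hi - lo:.1f} px < 10 px)")
        xs = np.linspace(lo, hi, 257)
        thick = self.posterior.rows(xs) - self.anterior.rows(xs)
        worst = float(thick.min())
        if worst < -_THICKNESS_TOL:
            raise GeometryError(
                f"negative graft thickness ({worst:.2f} px) — posterior curve "
                "crosses anterior curve"
            )

    @property
    def span(self) -> tuple[float, float]:
        a0, a1 = self.anterior.domain
        p0, p1 = self.posterior.domain
        return (max(a0, p0), min(a1, p1))

    def thickness_px(self, cols: np.ndarray) -> np.ndarray:
        """Axial thickness in px, clamped at 0 where the fitted curves touch."""
        return np.maximum(self.posterior.rows(cols) - self.anterior.rows(cols), 0.0)


# ---------------------------------------------------------------------------
# corner detection

def _turn_angles(pts: np.ndarray, k: int, closed: bool) -> np.ndarray:
    """k-cosine turn angle (radians) at each vertex; NaN where undefined.

    The angle is pi minus the angle enclosed by the two support arms
    p[i-k]-p[i] and p[i+k]-p[i]: 0 on a straight line, large at a corner.
    """
    n = pts.shape[0]
    theta = np.full(n, np.nan)
    if closed:
        idx = np.arange(n)
        prev = pts[(idx - k) % n]
        nxt = pts[(idx + k) % n]
        sel = idx
    else:
        sel = np.arange(k, n - k)
        if sel.size == 0:
            return theta
        prev = pts[sel - k]
        nxt = pts[sel + k]
    a = prev - pts[sel]
    b = nxt - pts[sel]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    cosang = np.full(sel.shape, np.nan)
    cosang[ok] = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
    theta[sel] = np.pi - np.arccos(np.clip(cosang, -1.0, 1.0))
    return theta


def _fine_envelope(edges: EdgeMap, col_lo: int, col_hi: int) -> dict[int, float]:
    """Deepest edge row per column over [col_lo, col_hi], refined to
    sub-pixel position on the gradient-magnitude profile."""
    h, w = edges.shape
    grad = edges.gradient
    out: dict[int, float] = {}
    for c in range(max(col_lo, 0), min(col_hi + 1, w)):
        rr = np.flatnonzero(edges.edges[:, c])
        if rr.size == 0:
            continue
        r = float(rr[-1])
        if grad is not None and 0 < rr[-1] < h - 1:
            g = grad[rr[-1] - 1:rr[-1] + 2, c]
            denom = g[0] - 2 * g[1] + g[2]
            if denom < -1e-12:
                r += float(np.clip(0.5 * (g[0] - g[2]) / denom, -0.5, 0.5))
        out[c] = r
    return out


def _refine_corner(edges: EdgeMap, col_lo: int, col_hi: int,
                   arm: int) -> tuple[float, float] | None:
    """Single-column corner localisation by a two-line changepoint fit.

    Within [col_lo, col_hi], the breakpoint that minimises the total
    squared residual of straight-line fits to the envelope on either side
    marks the tangent discontinuity; the corner row is the meeting point
    of the two fitted lines.  The window must be generous: the coarse
    curvature response plateaus over its support arms, so the peak alone
    localises a corner only to within that support.
    """
    env = _fine_envelope(edges, col_lo - arm, col_hi + arm)
    cols = np.array(sorted(env))
    rows = np.array([env[c] for c in cols])
    if cols.size < 10:
        return None
    best = None
    best_sse = np.inf
    # fixed data window: the total two-piece quadratic SSE is comparable
    # across breakpoints, and a breakpoint off the kink forces one side's
    # smooth fit across the tangent discontinuity
    for c in range(col_lo, col_hi + 1):
        left = cols <= c
        right = ~left
        if left.sum() < 4 or right.sum() < 4:
            continue
        sse = 0.0
        rows_at_c = []
        for m in (left, right):
            deg = 2 if m.sum() >= 6 else 1
            coef = np.polyfit(cols[m], rows[m], deg)
            resid = rows[m] - np.polyval(coef, cols[m])
            sse += float(resid @ resid)
            rows_at_c.append(float(np.polyval(coef, c)))
        if sse < best_sse:
            best_sse = sse
            best = (float(c), float(np.mean(rows_at_c)))
    return best


def detect_corners(boundary: SampledBoundary | np.ndarray,
                   edges: EdgeMap | None = None,
                   params: CornerParams = CornerParams()) -> CornerSet:
    """Locate the graft corner points from discrete curvature.

    Turn angles over a ``params.window``-sample support are computed along
    the boundary polyline; candidate corners are local curvature maxima
    whose z-score exceeds ``params.z_threshold`` and whose excess over the
    median turn exceeds ``params.min_angle_deg`` (a contour of constant
    curvature therefore yields none).  The retained corners are the
    lateral extremes of the candidate set; when only one candidate exists
    per side — the cusp of a lens-shaped graft — it serves as both the
    anterior and the posterior corner of that side.  When an edge map is
    supplied, each corner is refined to single-column resolution on the
    posterior edge envelope.
    """
    if isinstance(boundary, SampledBoundary):
        pts = boundary.points
        step = boundary.sampling_step
    else:
        pts = np.asarray(boundary, dtype=float)
        step = 1
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise CornerDetectionError("boundary too short for curvature analysis")
    closed = bool(np.allclose(pts[0], pts[-1], atol=1e-9)) or (
        not isinstance(boundary, SampledBoundary)
        and np.linalg.norm(pts[0] - pts[-1]) < 3 * np.linalg.norm(pts[1] - pts[0]) + 1e-9
    )
    if closed and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    n = pts.shape[0]
    k = min(params.window, (n // 3) if closed else max((n - 1) // 2, 1))
    if k < 2:
        raise CornerDetectionError("boundary too short for the curvature window")
    theta = _turn_angles(pts, k, closed)
    valid_idx = np.flatnonzero(np.isfinite(theta))
    if valid_idx.size < 3:
        raise CornerDetectionError("found 0 significant corner candidates, need at least 2")
    tv = theta[valid_idx]
    # local angle-noise scale from first differences (robust to the smooth
    # arc-bend baseline, which a global z-score is not)
    noise = 1.4826 * np.median(np.abs(np.diff(tv))) / np.sqrt(2.0) if tv.size > 1 else 0.0
    threshold = max(np.deg2rad(params.min_angle_deg), params.z_threshold * noise)

    from scipy.signal import find_peaks
    if closed:
        # unwrap cyclically so peaks at the seam are found
        ext = np.concatenate([tv[-k:], tv, tv[:k]])
        peaks, props = find_peaks(ext, prominence=threshold)
        inner = (peaks >= k) & (peaks < k + tv.size)
        peaks, prom = peaks[inner] - k, props["prominences"][inner]
    else:
        pad = float(tv.min())  # finite padding keeps prominences finite
        padded = np.concatenate([[pad], tv, [pad]])
        peaks, props = find_peaks(padded, prominence=threshold)
        peaks, prom = peaks - 1, props["prominences"]
    if peaks.size:
        # a weak ripple is no corner when a far sharper one exists elsewhere
        strong = prom >= 0.4 * prom.max()
        peaks = peaks[strong]
    cand = [int(valid_idx[p]) for p in np.unique(peaks)]
    if len(cand) < 2:
        raise CornerDetectionError(
            f"found {len(cand)} significant corner candidates, need at least 2"
        )
    cpts = pts[cand]
    order = np.argsort(cpts[:, 0])
    cpts = cpts[order]
    col_lo, col_hi = cpts[0, 0], cpts[-1, 0]
    if col_hi - col_lo < 1e-9:
        raise CornerDetectionError("all corner candidates share one column")
    tol = 1.5 * step
    left = cpts[cpts[:, 0] <= col_lo + tol]
    right = cpts[cpts[:, 0] >= col_hi - tol]

    def pair(group: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
        rows = group[:, 1]
        ant = group[np.argmin(rows)]
        post = group[np.argmax(rows)]
        return (float(ant[0]), float(ant[1])), (float(post[0]), float(post[1]))

    la, lp = pair(left)
    ra, rp = pair(right)

    if edges is not None and step > 1:
        arm = 2 * step
        reach = k * step  # coarse peak may sit anywhere on its support plateau
        mid = 0.5 * (lp[0] + rp[0])
        for side in ("left", "right"):
            ant, post = (la, lp) if side == "left" else (ra, rp)
            if side == "left":
                lo, hi = int(post[0] - reach), int(min(post[0] + reach, mid - 5))
            else:
                lo, hi = int(max(post[0] - reach, mid + 5)), int(post[0] + reach)
            if hi < lo:
                continue
            refined = _refine_corner(edges, lo, hi, arm=arm)
            if refined is None:
                continue
            degenerate = abs(ant[0] - post[0]) < 1e-9 and abs(ant[1] - post[1]) < 1e-9
            shift = (refined[0] - post[0], refined[1] - post[1])
            post = refined
            ant = refined if degenerate else (ant[0] + shift[0], ant[1] + shift[1])
            if side == "left":
                la, lp = ant, post
            else:
                ra, rp = ant, post
    return CornerSet(left_anterior=la, left_posterior=lp,
                     right_anterior=ra, right_posterior=rp)


# ---------------------------------------------------------------------------
# anterior-interface extraction

def _robust_quadfit(x: np.ndarray, y: np.ndarray, iters: int = 6) -> np.ndarray:
    """Quadratic fit of the host posterior surface with one-sided trimming.

    Graft tissue always hangs *below* the host surface (larger rows), so
    points with positive residuals are trimmed aggressively and the fit
    repeated: the quadratic converges onto the upper support of the point
    cloud — the host surface — even when a smooth graft flank leaks into
    the fitting range.  Negative (above-surface) outliers are trimmed at
    the usual 3 robust standard deviations.
    """
    keep = np.ones(x.size, dtype=bool)
    coef = np.polyfit(x, y, 2)
    for _ in range(iters):
        r = y - np.polyval(coef, x)
        sigma = 1.4826 * float(np.median(np.abs(r[keep] - np.median(r[keep]))))
        lo_cut = max(0.7, 1.5 * sigma)   # below-surface (graft) side
        hi_cut = max(1.5, 3.0 * sigma)   # above-surface side
        new = (r <= lo_cut) & (r >= -hi_cut)
        if new.sum() < 6 or (new == keep).all():
            break
        keep = new
        coef = np.polyfit(x[keep], y[keep], 2)
    return coef


def _host_prior_thickness(posterior: SampledBoundary, corners: CornerSet,
                          margin: float = 3.0,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prior band-thickness estimate across the graft span.

    The host posterior surface, visible lateral to the graft, is fitted
    with a quadratic and extrapolated across the span — anatomically the
    interface continues that surface — giving a per-column thickness prior
    posterior_row - extrapolated_row.  Falls back to the corner chord when
    the host surface is not visible.  Returns (span cols, posterior rows,
    thickness prior >= 1 px).
    """
    xl, xr = corners.left_anterior[0], corners.right_anterior[0]
    # dense column grid: the interface is searched at every column so the
    # gap statistics and outlier rejection do not hinge on a handful of
    # boundary samples; posterior rows are interpolated between samples
    span_cols = np.arange(np.ceil(xl + margin), np.floor(xr - margin) + 1.0)
    span_cols = span_cols[(span_cols >= posterior.cols.min())
                          & (span_cols <= posterior.cols.max())]
    span_rows = np.interp(span_cols, posterior.cols, posterior.rows)
    outside = (posterior.cols < xl - margin) | (posterior.cols > xr + margin)
    if outside.sum() >= 6:
        coef = _robust_quadfit(posterior.cols[outside], posterior.rows[outside])
        prior = np.polyval(coef, span_cols)
    else:  # host surface not visible: fall back to the anterior-corner chord
        t = (span_cols - xl) / (xr - xl)
        prior = corners.left_anterior[1] + t * (
            corners.right_anterior[1] - corners.left_anterior[1])
    return span_cols, span_rows, np.clip(span_rows - prior, 1.0, None)


def _edge_band_thickness(edges: EdgeMap, span_cols: np.ndarray,
                         span_rows: np.ndarray) -> np.ndarray:
    """Band thickness as the automated stage can observe it: the distance
    from the posterior boundary up to the next detected edge in the same
    column (NaN where none exists)."""
    t = np.full(span_cols.size, np.nan)
    for i, (c, pr) in enumerate(zip(span_cols, span_rows)):
        top = int(np.floor(pr)) - 1  # exclude the posterior edge's own ridge
        rr = np.flatnonzero(edges.edges[:max(top, 0), int(c)])
        if rr.size:
            t[i] = pr - rr[-1]
    return t


def extract_anterior_interface(image: OCTImage, corners: CornerSet,
                               posterior: SampledBoundary,
                               params: InterfaceParams = InterfaceParams(),
                               edges: EdgeMap | None = None,
                               ) -> SampledBoundary:
    """Trace the low-contrast host-graft interface.

    For every column between the corners, a band anterior to the posterior
    boundary (at most ``band_factor`` x the median band-thickness
    estimate, ending ``posterior_margin_px`` above the posterior boundary
    so its own gradient tail stays out) is searched for the strongest
    interior *local maximum* of the downward intensity drop above an
    absolute noise floor.

    The thickness estimate is the distance from the posterior boundary to
    the next detected edge above it when an edge map is supplied — the
    interface itself when it is crisp.  When the interface is too faint to
    leave edges, the next edge above is the anterior corneal surface and
    the search band inflates accordingly: detection then follows bright
    host-stromal speckle well anterior of the true interface, which is
    exactly the overestimation failure mode of automated analysis on thin
    grafts.  Without an edge map the estimate falls back to extrapolating
    the host posterior surface across the span.

    Columns with no significant response are recorded as gaps; if more
    than ``max_gap_fraction`` of the resolvable columns gap out,
    :class:`LowContrastError` is raised.
    """
    if len(posterior) == 0:
        raise EmptyBoundaryError("posterior boundary is empty")
    xl, xr = corners.left_anterior[0], corners.right_anterior[0]
    span_cols, span_rows, t_prior = _host_prior_thickness(posterior, corners)
    if span_cols.size < 2:
        raise GeometryError("fewer than 2 posterior samples between the corners")
    # columns whose geometric band thickness sits inside the posterior
    # margin hold no resolvable interface (the band is thinner than the
    # blur there); they are geometric, not low-contrast, gaps
    resolvable = t_prior >= params.posterior_margin_px + 1.0
    if resolvable.sum() < 2:
        raise LowContrastError(
            "band too thin to resolve the host-graft interface anywhere")
    # band size from the *observed* thickness where an edge map is given:
    # the distance to the next visible edge, which is the interface only
    # when the interface actually left edges
    t_band = t_prior
    if edges is not None:
        t_obs = _edge_band_thickness(edges, span_cols, span_rows)
        if np.isfinite(t_obs[resolvable]).any():
            t_band = t_obs
    band = float(np.clip(params.band_factor * np.nanmedian(t_band[resolvable]),
                         2.0, image.shape[0] / 2))
    # anatomical ceiling: the interface continues the host posterior
    # surface, so the search never strays far above its extrapolation —
    # this bounds how badly an invisible interface can be overshot
    ceiling = (span_rows - t_prior) - max(
        3.0, float(np.median(t_prior[resolvable])))
    span_cols, span_rows = span_cols[resolvable], span_rows[resolvable]
    ceiling = ceiling[resolvable]

    # downward intensity drop (positive at bright-above/dark-below edges)
    drop = -gaussian_filter(image.pixels, sigma=1.0, order=(1, 0), mode="nearest")
    h = image.shape[0]
    got_cols, got_rows = [], []
    for c, pr, ceil_row in zip(span_cols, span_rows, ceiling):
        r_top = int(np.ceil(max(pr - band, ceil_row, 0.0)))
        r_bot = int(np.floor(pr - max(1.0, params.posterior_margin_px)))
        if r_bot <= r_top:
            continue
        col = drop[r_top:r_bot + 1, int(c)]
        if col.max() < params.abs_floor:
            continue  # gap: nothing above the noise floor
        # strongest interior local maximum of the drop profile; boundary
        # elements are excluded so the monotone tail of a neighbouring
        # edge (e.g. the posterior boundary's) cannot masquerade as one
        best = None
        for j in range(1, col.size - 1):
            if col[j] < params.abs_floor:
                continue
            if col[j] >= col[j - 1] and col[j] >= col[j + 1] \
                    and (best is None or col[j] > col[best]):
                best = j
        if best is None:
            continue
        r = r_top + best
        # sub-pixel parabolic refinement
        if 0 < best < col.size - 1:
            denom = col[best - 1] - 2 * col[best] + col[best + 1]
            if denom < -1e-12:
                r += float(np.clip(0.5 * (col[best - 1] - col[best + 1]) / denom,
                                   -0.5, 0.5))
        got_cols.append(float(c))
        got_rows.append(min(float(r), float(pr - 1.0)))

    n_cols = span_cols.size
    if got_cols and len(got_cols) >= 5:
        # drop isolated excursions from the local median path; the cutoff
        # scales with the path's own scatter so a noise-dominated search
        # is not decimated wholesale
        rows_arr = np.asarray(got_rows)
        smooth = median_filter(rows_arr, size=5, mode="nearest")
        dev = np.abs(rows_arr - smooth)
        cut = max(params.outlier_px, 3.0 * float(np.median(dev)))
        keep = dev <= cut
        got_cols = [c for c, k in zip(got_cols, keep) if k]
        got_rows = [r for r, k in zip(got_rows, keep) if k]
    gap_fraction = 1.0 - len(got_cols) / n_cols
    if gap_fraction > params.max_gap_fraction:
        raise LowContrastError(
            f"host-graft interface undetectable in {gap_fraction:.0%} of "
            f"{n_cols} sampled columns (thin-graft low-contrast regime)"
        )
    return SampledBoundary(np.asarray(got_cols), np.asarray(got_rows),
                           sampling_step=posterior.sampling_step,
                           image_id=image.image_id)


# ---------------------------------------------------------------------------
# curve fitting and refinement

def _assemble_controls(pts: SampledBoundary, left: tuple[float, float],
                       right: tuple[float, float]) -> np.ndarray:
    inner = (pts.cols > left[0] + 2.0) & (pts.cols < right[0] - 2.0)
    ctrl = np.vstack([[left],
                      np.column_stack([pts.cols[inner], pts.rows[inner]]),
                      [right]])
    return ctrl


def fit_graft(anterior_pts: SampledBoundary, posterior_pts: SampledBoundary,
              corners: CornerSet, params: SplineParams = SplineParams(),
              image_shape: tuple[int, int] | None = None) -> GraftSegmentation:
    """Fit corner-pinned smoothing splines through both point sets.

    Gaps in either point set are bridged by the spline.  The result is an
    ``automated``-mode segmentation; every geometric invariant (shared
    domain, non-negative thickness, non-degenerate span) is checked on
    construction.
    """
    for name, pts in (("anterior", anterior_pts), ("posterior", posterior_pts)):
        if len(pts) < 2:
            raise GeometryError(f"{name} boundary needs at least 2 points, got {len(pts)}")
    xl, xr = corners.span
    if xr - xl < 10:
        raise GeometryError(f"degenerate lateral span ({xr - xl:.1f} px < 10 px)")
    ant = GraftCurve(_assemble_controls(anterior_pts, corners.left_anterior,
                                        corners.right_anterior),
                     smoothing=params.smoothing)
    post = GraftCurve(_assemble_controls(posterior_pts, corners.left_posterior,
                                         corners.right_posterior),
                      smoothing=params.smoothing)
    if image_shape is None:
        rows = np.concatenate([anterior_pts.rows, posterior_pts.rows])
        cols = np.concatenate([anterior_pts.cols, posterior_pts.cols])
        image_shape = (int(rows.max()) + 1, int(cols.max()) + 1)
    return GraftSegmentation(anterior=ant, posterior=post, corners=corners,
                             mode="automated", image_shape=image_shape)


def adjust_control_points(seg: GraftSegmentation,
                          edits: Iterable[tuple[str, int, Sequence[float]]],
                          ) -> GraftSegmentation:
    """Apply user edits to curve control points (semi-automated refinement).

    ``edits`` is a list of ``(curve_id, index, (col, row))`` with curve_id
    ``"anterior"`` or ``"posterior"``.  Editing an endpoint moves the
    corresponding corner.  All edits are applied, the curves re-fitted,
    and every invariant re-checked; a violating edit set is rejected with
    the violated invariant named.  The result carries mode
    ``semi_automated`` (also for an empty edit list).
    """
    ctrl = {"anterior": seg.anterior.control_points.copy(),
            "posterior": seg.posterior.control_points.copy()}
    h, w = seg.image_shape
    for curve_id, index, new in edits:
        if curve_id not in ctrl:
            raise ParameterError(f"unknown curve id {curve_id!r}")
        pts = ctrl[curve_id]
        if not -len(pts) <= index < len(pts):
            raise ParameterError(f"control-point index {index} out of range "
                                 f"for {curve_id} ({len(pts)} points)")
        col, row = float(new[0]), float(new[1])
        if not (0 <= col < w and 0 <= row < h):
            raise ParameterError(
                f"edit rejected: new position ({col}, {row}) lies outside "
                f"the {h}x{w} image"
            )
        pts[index] = (col, row)
    for curve_id, pts in ctrl.items():
        if not np.all(np.diff(pts[:, 0]) > 0):
            raise GeometryError(
                f"edit rejected: {curve_id} control-point columns no longer "
                "strictly increasing (single-valuedness violated)"
            )
    ant = GraftCurve(ctrl["anterior"], smoothing=seg.anterior.smoothing)
    post = GraftCurve(ctrl["posterior"], smoothing=seg.posterior.smoothing)
    corners = CornerSet(
        left_anterior=tuple(ctrl["anterior"][0]),
        right_anterior=tuple(ctrl["anterior"][-1]),
        left_posterior=tuple(ctrl["posterior"][0]),
        right_posterior=tuple(ctrl["posterior"][-1]),
    )
    return GraftSegmentation(anterior=ant, posterior=post, corners=corners,
                             mode="semi_automated", image_shape=seg.image_shape)


def _intersect_corners(envelope: SampledBoundary, corners: CornerSet,
                       keep_cols: np.ndarray) -> CornerSet:
    """Refine corner positions to where the graft departs the host surface.

    Where the graft band thins below the imaging blur the curvature-based
    corner estimate drifts (the observable envelope kink does, and on a
    short graft the curvature support arms outspan the band entirely).
    The true corner is where the graft posterior surface meets the host
    posterior surface.  A quadratic is fitted robustly to the host surface
    lateral to the graft; the envelope's deviation below that fit rises
    from ~0 on the host to the full band depth mid-graft, and a straight
    line through its flank, extrapolated back to zero deviation, marks
    the corner.  If no usable flank exists the curvature estimate stands.
    """
    lens_shaped = (corners.left_anterior == corners.left_posterior
                   and corners.right_anterior == corners.right_posterior)
    if not lens_shaped:  # blunt-ended graft: the curvature corners stand
        return corners
    core_cols = np.asarray(keep_cols, dtype=float)
    xl, xr = corners.span
    core_lo, core_hi = core_cols.min(), core_cols.max()
    outside = (envelope.cols < min(xl, core_lo) - 3.0) \
        | (envelope.cols > max(xr, core_hi) + 3.0)
    if outside.sum() < 6 or core_cols.size < 3:
        return corners
    host = _robust_quadfit(envelope.cols[outside], envelope.rows[outside])

    dense = np.arange(envelope.cols.min(), envelope.cols.max() + 1.0)
    dev = np.interp(dense, envelope.cols, envelope.rows) - np.polyval(host, dense)
    dev = uniform_filter1d(dev, size=7, mode="nearest")
    core_mask = (dense >= core_lo) & (dense <= core_hi)
    dmax = float(np.percentile(dev[core_mask], 90)) if core_mask.any() else 0.0
    if dmax < 2.0:
        return corners

    def departure(side: str, col0: float) -> float:
        # walk outward from the core while the deviation stays clearly
        # positive — this anchors the flank to the graft itself, not to a
        # distant noise bump — then extrapolate a line through the flank
        # down to zero deviation
        step = -1 if side == "left" else 1
        i = int(np.clip(np.searchsorted(dense, core_lo if side == "left" else core_hi),
                        0, dense.size - 1))
        j = i
        while 0 < j < dense.size - 1 and dev[j + step] > 0.25 \
                and abs(dense[j] - dense[i]) < 100:
            j += step
        run = slice(min(i, j), max(i, j) + 1)
        hi_d = max(0.7 * dmax, 1.6)
        # include the attenuated tail: near the corner the band is thinner
        # than the blur and its observable deviation decays toward zero
        flank = (dev[run] >= 0.4) & (dev[run] <= hi_d)
        if flank.sum() < 3:
            return col0
        coef = np.polyfit(dense[run][flank], dev[run][flank], 1)
        if abs(coef[0]) < 1e-6:
            return col0
        x0 = -coef[1] / coef[0]
        lo, hi = (dense[j] - 15.0, core_lo) if side == "left" \
            else (core_hi, dense[j] + 15.0)
        return float(x0) if lo <= x0 <= hi else col0

    def roots_refine() -> tuple[float, float] | None:
        # crossing of the graft-surface quadratic with the host surface;
        # used when the core is wide enough that the extrapolation to the
        # corner is a small fraction of the fit support
        graft = np.polyfit(dense[core_mask],
                           np.interp(dense[core_mask], envelope.cols, envelope.rows), 2)
        rts = np.roots(np.polysub(graft, host))
        rts = np.real(rts[np.abs(np.imag(rts)) < 1e-6])
        env_lo = envelope.cols.min() - envelope.sampling_step
        env_hi = envelope.cols.max() + envelope.sampling_step
        left = rts[(rts < core_lo + 5.0) & (rts >= env_lo)]
        right = rts[(rts > core_hi - 5.0) & (rts <= env_hi)]
        if not (left.size and right.size):
            return None
        return (float(left[np.argmin(np.abs(left - xl))]),
                float(right[np.argmin(np.abs(right - xr))]))

    new_xl = new_xr = None
    if core_hi - core_lo >= 60.0:
        pair = roots_refine()
        if pair is not None:
            new_xl, new_xr = pair
    if new_xl is None:
        new_xl, new_xr = departure("left", xl), departure("right", xr)
    if new_xr - new_xl < 10:
        return corners
    lp = (new_xl, float(np.polyval(host, new_xl)))
    rp = (new_xr, float(np.polyval(host, new_xr)))
    return CornerSet(left_anterior=lp, left_posterior=lp,
                     right_anterior=rp, right_posterior=rp)


# ---------------------------------------------------------------------------
# full pipeline

def segment_automated(image: OCTImage, config: RunConfig = RunConfig()) -> GraftSegmentation:
    """Run the full automated pipeline on one B-scan.

    preprocess -> detect_edges -> sample_boundary -> detect_corners ->
    extract_anterior_interface -> fit_graft, all parameterised by
    ``config``.  Stage failures propagate with the stage name prefixed.
    """
    def stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kw)
        except OCTGraftError as exc:
            if str(exc).startswith("["):
                raise
            raise type(exc)(f"[{name}] {exc}") from exc
        log.debug("stage %-25s %.3f s", name, time.perf_counter() - t0)
        return result

    pre = stage("preprocess", preprocess, image, config.preprocess_scale)
    edges = stage("detect_edges", detect_edges, pre,
                  config.canny.low_q, config.canny.high_q, config.canny.sigma)
    try:
        envelope = sample_boundary(edges, step=config.sampling.step, select="deepest")
    except EmptyBoundaryError as exc:
        raise CornerDetectionError(
            f"[detect_corners] no boundary to search for corners: {exc}") from exc
    envelope = refine_rows_subpixel(pre, envelope)
    corners = stage("detect_corners", detect_corners, envelope, edges, config.corner)
    # columns whose prior band thickness is below the edge-merge scale (the
    # interface and posterior edges blur into a single gradient ridge
    # there) are unreliable: they are excluded from the posterior fit and
    # bridged by the corner-anchored spline instead.  Corner refinement is
    # iterated because the reliable core — and with it the host-surface
    # fit — depends on the very corner estimate it refines.
    merge_px = 1.5 * float(np.hypot(config.preprocess_scale, config.canny.sigma))

    def reliable_core(crn):
        cols, _, t_prior = _host_prior_thickness(envelope, crn)
        keep = t_prior >= merge_px
        if keep.sum() < max(3, 0.3 * cols.size):
            keep[:] = True  # band thinner than the blur everywhere
        return cols[keep]

    for _ in range(3):
        keep = reliable_core(corners)
        refined = stage("refine_corners", _intersect_corners, envelope, corners, keep)
        moved = max(abs(refined.span[0] - corners.span[0]),
                    abs(refined.span[1] - corners.span[1]))
        corners = refined
        if moved < 0.5:
            break
    keep = reliable_core(corners)
    anterior_pts = stage("extract_anterior_interface", extract_anterior_interface,
                         pre, corners, envelope, config.interface, edges)
    xl, xr = corners.span
    post_raw = envelope.restrict(xl + 2.0, xr - 2.0)
    sel = np.isin(post_raw.cols, keep)
    if sel.any():
        post_raw = SampledBoundary(post_raw.cols[sel], post_raw.rows[sel],
                                   post_raw.sampling_step, post_raw.image_id)
    posterior_pts = post_raw
    return stage("fit_graft", fit_graft, anterior_pts, posterior_pts, corners,
                 config.spline, image.shape)


# ---------------------------------------------------------------------------
# phantom-truth helpers (semi-automated reference segmentations)

def segmentation_from_truth(truth, n_points: int = 31,
                            mode: str = "semi_automated") -> GraftSegmentation:
    """Segmentation whose control points lie exactly on the phantom's
    ground-truth arcs (the ideal outcome of manual refinement)."""
    ant, post = truth.anterior_interface, truth.posterior_boundary
    xs = np.linspace(ant.p1[0], ant.p2[0], n_points)
    ant_curve = GraftCurve(np.column_stack([xs, ant.row_at(xs)]), smoothing=0.0)
    post_curve = GraftCurve(np.column_stack([xs, post.row_at(xs)]), smoothing=0.0)
    corners = CornerSet(left_anterior=ant.p1, left_posterior=post.p1,
                        right_anterior=ant.p2, right_posterior=post.p2)
    shape = (truth.spec.image_height, truth.spec.image_width)
    return GraftSegmentation(anterior=ant_curve, posterior=post_curve,
                             corners=corners, mode=mode, image_shape=shape)


def snap_to_truth(seg: GraftSegmentation, truth) -> GraftSegmentation:
    """Refine a segmentation by moving every control point onto the
    ground-truth curves via :func:`adjust_control_points` — the manual
    refinement protocol performed by an ideal observer."""
    edits = []
    for curve_id, arc in (("anterior", truth.anterior_interface),
                          ("posterior", truth.posterior_boundary)):
        n = getattr(seg, curve_id).control_points.shape[0]
        xs = np.linspace(arc.p1[0], arc.p2[0], n)
        rows = arc.row_at(xs)
        rows[0], rows[-1] = arc.p1[1], arc.p2[1]  # endpoints exact
        edits.extend((curve_id, i, (float(xs[i]), float(rows[i])))
                     for i in range(n))
    return adjust_control_points(seg, edits)
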