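"""Synthetic OCT B-scan phantoms with analytically known graft geometry.

A phantom emulates a high-resolution anterior-segment cornea scan: a bright
corneal band (circular-arc anterior surface, constant thickness) over a
dark background, with a lens/meniscus-shaped graft appended to the
posterior corneal surface.  The graft is the region between two shallow
circular arcs sharing the two corner endpoints, so its cross-sectional
area has a closed form (difference of circular-segment areas) — the ground
truth every pipeline stage can be scored against.

The host-graft interface is rendered as an intensity step of
``interface_contrast`` x the band intensity: at contrast 0 the graft is
radiometrically indistinguishable from host stroma, reproducing the
low-contrast regime in which automated interface detection degrades.
Speckle is modelled as multiplicative unit-mean lognormal noise, the
standard first-order OCT speckle model, reproducible under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import PhantomSpecError
from .geometry import Arc, area_between_arcs
from .io import Calibration, OCTImage

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "thin_graft_spec",
           "truth_to_dict", "truth_from_dict", "BAND_INTENSITY",
           "THIN_GRAFT_AREA_UM2", "THIN_GRAFT_CONTRAST", "THIN_GRAFT_SPECKLE"]

#: rendered intensity of corneal tissue (fraction of full scale)
BAND_INTENSITY = 0.8
#: area below which a graft counts as "thin" (µm²); automated interface
#: detection is least reliable below this size
THIN_GRAFT_AREA_UM2 = 80_000.0

#: study conditions for the thin-graft low-contrast regime: an interface
#: step well below the speckle floor, the setting in which automated
#: readings systematically overshoot
THIN_GRAFT_CONTRAST = 0.12
THIN_GRAFT_SPECKLE = 0.10

_SUPERSAMPLE = 8  # axial supersampling factor for sub-pixel boundary rendering


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic B-scan.

    Lengths are in pixels; ``graft_central_thickness`` is the separation of
    the two graft arcs at the corner-chord midpoint, measured perpendicular
    to the chord.  ``anterior_sagitta`` (signed, positive = anterior bulge)
    fixes the interface arc; when ``None`` it is derived so the interface
    continues the posterior corneal surface through the graft span — the
    anatomical default.
    """

    image_height: int = 384
    image_width: int = 512
    calibration: Calibration = Calibration()
    cornea_apex_row: float = 60.0
    cornea_anterior_sagitta: float = 40.0
    cornea_thickness: float = 30.0
    graft_left_corner: tuple[float, float] = (116.0, 104.45)
    graft_right_corner: tuple[float, float] = (396.0, 104.45)
    graft_central_thickness: float = 10.0
    anterior_sagitta: Optional[float] = None
    interface_contrast: float = 0.5
    speckle_sigma: float = 0.0
    background_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_height, self.image_width
        if h < 32 or w < 32:
            raise PhantomSpecError(f"image {h}x{w} too small (need >= 32x32)")
        for name in ("graft_left_corner", "graft_right_corner"):
            c, r = getattr(self, name)
            if not (0 <= c < w and 0 <= r < h):
                raise PhantomSpecError(f"{name} ({c}, {r}) lies outside the {h}x{w} image")
        if self.graft_right_corner[0] <= self.graft_left_corner[0]:
            raise PhantomSpecError("graft corners must be ordered left < right in column")
        if self.graft_central_thickness < 1:
            raise PhantomSpecError("graft_central_thickness must be >= 1 px")
        if not 0.0 <= self.interface_contrast <= 1.0:
            raise PhantomSpecError("interface_contrast must lie in [0, 1]")
        if self.speckle_sigma < 0:
            raise PhantomSpecError("speckle_sigma must be >= 0")
        if not 0.0 <= self.background_level <= 1.0:
            raise PhantomSpecError("background_level must lie in [0, 1]")
        if self.cornea_anterior_sagitta <= 0 or self.cornea_thickness <= 0:
            raise PhantomSpecError("cornea sagitta and thickness must be positive")

    # -- derived geometry ------------------------------------------------

    @property
    def cornea_anterior(self) -> Arc:
        """Anterior corneal surface spanning the full image width."""
        edge_row = self.cornea_apex_row + self.cornea_anterior_sagitta
        return Arc((0.0, edge_row), (self.image_width - 1.0, edge_row),
                   self.cornea_anterior_sagitta)

    @property
    def cornea_radius(self) -> float:
        return self.cornea_anterior.radius

    def _anterior_sagitta(self) -> float:
        if self.anterior_sagitta is not None:
            return float(self.anterior_sagitta)
        # arc of the corneal radius through the corners: the interface then
        # continues the posterior corneal surface
        dx = self.graft_right_corner[0] - self.graft_left_corner[0]
        dy = self.graft_right_corner[1] - self.graft_left_corner[1]
        a = 0.5 * np.hypot(dx, dy)
        r = self.cornea_radius
        if a >= r:
            raise PhantomSpecError("graft chord wider than the corneal diameter")
        return float(r - np.sqrt(r * r - a * a))

    @property
    def interface_arc(self) -> Arc:
        return Arc(self.graft_left_corner, self.graft_right_corner,
                   self._anterior_sagitta())

    @property
    def posterior_arc(self) -> Arc:
        return Arc(self.graft_left_corner, self.graft_right_corner,
                   self._anterior_sagitta() - self.graft_central_thickness)

    def true_area_um2(self) -> float:
        return area_between_arcs(self.interface_arc, self.posterior_arc) \
            * self.calibration.um2_per_px2

    @classmethod
    def default(cls, **overrides) -> "PhantomSpec":
        """Default spec with graft corners snapped onto the posterior
        corneal surface (columns may be overridden via ``corner_cols``)."""
        cols = overrides.pop("corner_cols", None)
        spec = cls(**overrides)
        if cols is None:
            cols = (spec.graft_left_corner[0], spec.graft_right_corner[0])
        post = spec.cornea_anterior
        rows = post.row_at(np.asarray(cols, dtype=float)) + spec.cornea_thickness
        return replace(spec,
                       graft_left_corner=(float(cols[0]), float(rows[0])),
                       graft_right_corner=(float(cols[1]), float(rows[1])))


@dataclass(frozen=True)
class PhantomTruth:
    """Exact graft geometry paired with a generated image."""

    anterior_interface: Arc
    posterior_boundary: Arc
    true_area_um2: float
    true_thickness_profile: np.ndarray  # (n, 2): lateral µm from left corner, µm
    spec: PhantomSpec

    @property
    def corners(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (self.anterior_interface.p1, self.anterior_interface.p2)


def _render(spec: PhantomSpec) -> np.ndarray:
    """Noise-free rendering with axial supersampling for sub-pixel edges."""
    h, w, ss = spec.image_height, spec.image_width, _SUPERSAMPLE
    cols = np.arange(w, dtype=float)
    ant = spec.cornea_anterior.row_at(cols)                  # (w,)
    post = ant + spec.cornea_thickness
    x0, x1 = spec.graft_left_corner[0], spec.graft_right_corner[0]
    in_span = (cols >= x0) & (cols <= x1)
    g_top = np.full(w, np.nan)
    g_bot = np.full(w, np.nan)
    g_top[in_span] = spec.interface_arc.row_at(cols[in_span])
    g_bot[in_span] = spec.posterior_arc.row_at(cols[in_span])

    # fine axial grid of sub-pixel sample centres; pixel r spans [r-.5, r+.5)
    fine = (np.arange(h * ss, dtype=float) + 0.5) / ss - 0.5  # (h*ss,)
    fr = fine[:, None]
    img = np.full((h * ss, w), spec.background_level)
    img[(fr >= ant) & (fr <= post)] = BAND_INTENSITY
    graft_level = BAND_INTENSITY * (1.0 - spec.interface_contrast)
    graft_mask = in_span[None, :] & (fr >= g_top) & (fr <= g_bot)
    img[graft_mask] = graft_level
    return img.reshape(h, ss, w).mean(axis=1)


def generate_phantom(spec: PhantomSpec) -> tuple[OCTImage, PhantomTruth]:
    """Render the phantom and return it with its exact ground truth.

    Identical spec (including seed) gives a bit-identical image.  Output
    intensities are quantised to the 16-bit grid so that writing the image
    to PNG/TIFF and reading it back is lossless.
    """
    px = _render(spec)
    if spec.speckle_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        s = spec.speckle_sigma
        field = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=px.shape)
        px = px * field
    px = np.clip(px, 0.0, 1.0)
    px = np.round(px * 65535.0) / 65535.0

    ant, post = spec.interface_arc, spec.posterior_arc
    n = 257
    xs = np.linspace(ant.p1[0], ant.p2[0], n)
    cal = spec.calibration
    profile = np.column_stack([
        (xs - ant.p1[0]) * cal.microns_per_pixel_lateral,
        (post.row_at(xs) - ant.row_at(xs)) * cal.microns_per_pixel_axial,
    ])
    truth = PhantomTruth(
        anterior_interface=ant,
        posterior_boundary=post,
        true_area_um2=spec.true_area_um2(),
        true_thickness_profile=profile,
        spec=spec,
    )
    image = OCTImage(px, cal, image_id=f"phantom-{spec.seed}")
    return image, truth


def thin_graft_spec(base: PhantomSpec,
                    max_area_um2: float = THIN_GRAFT_AREA_UM2) -> PhantomSpec:
    """Return a spec whose true area falls below the thin-graft threshold.

    Already-thin specs are returned unchanged.  Otherwise the graft is
    shrunk deterministically: central thickness is capped and the chord is
    narrowed (corners kept on the posterior corneal surface) until the
    closed-form area is below the threshold, preferring thicker, shorter
    grafts — the blunt biconvex silhouette of a small lenticule — over
    degenerate 1-px bands.
    """
    if base.true_area_um2() < max_area_um2:
        return base
    target = 0.97 * max_area_um2  # stay clear of the threshold
    mid = 0.5 * (base.graft_left_corner[0] + base.graft_right_corner[0])
    base_half = 0.5 * (base.graft_right_corner[0] - base.graft_left_corner[0])
    for t in range(int(min(base.graft_central_thickness, 6)), 0, -1):
        # widest feasible half-chord for this thickness, by bisection
        lo, hi = max(8.0, 1.5 * t), base_half
        def area(half: float) -> float:
            cand = PhantomSpec.default(
                **{**_public_fields(base),
                   "graft_central_thickness": float(t)},
                corner_cols=(mid - half, mid + half))
            return cand.true_area_um2()
        if area(lo) >= target:
            continue  # even the narrowest graft of this thickness is too big
        if area(hi) < target:
            half = hi
        else:
            for _ in range(60):
                mid_h = 0.5 * (lo + hi)
                if area(mid_h) < target:
                    lo = mid_h
                else:
                    hi = mid_h
            half = lo
        if half < 20.0:
            continue  # too short to be a plausible graft; try thinner
        return PhantomSpec.default(
            **{**_public_fields(base), "graft_central_thickness": float(t)},
            corner_cols=(mid - half, mid + half))
    raise PhantomSpecError(
        f"no graft below {max_area_um2:g} µm² is feasible at calibration "
        f"{base.calibration.um2_per_px2:g} µm²/px² with thickness >= 1 px"
    )


def truth_to_dict(truth: PhantomTruth) -> dict:
    """JSON-serializable form of a :class:`PhantomTruth` (arcs + area)."""
    def arc(a: Arc) -> dict:
        return {"p1": list(a.p1), "p2": list(a.p2), "sagitta": a.sagitta}
    cal = truth.spec.calibration
    return {
        "anterior_interface": arc(truth.anterior_interface),
        "posterior_boundary": arc(truth.posterior_boundary),
        "true_area_um2": truth.true_area_um2,
        "image_shape": [truth.spec.image_height, truth.spec.image_width],
        "calibration": {"microns_per_pixel_lateral": cal.microns_per_pixel_lateral,
                        "microns_per_pixel_axial": cal.microns_per_pixel_axial},
    }


def truth_from_dict(doc: dict) -> PhantomTruth:
    """Rebuild a :class:`PhantomTruth` from :func:`truth_to_dict` output.

    The attached spec is a minimal geometric reconstruction (noise and
    contrast settings are not round-tripped; the geometry and area are).
    """
    def arc(d: dict) -> Arc:
        return Arc(tuple(d["p1"]), tuple(d["p2"]), float(d["sagitta"]))
    ant = arc(doc["anterior_interface"])
    post = arc(doc["posterior_boundary"])
    h, w = doc["image_shape"]
    cal = Calibration(**doc["calibration"])
    spec = PhantomSpec(image_height=h, image_width=w, calibration=cal,
                       graft_left_corner=ant.p1, graft_right_corner=ant.p2,
                       anterior_sagitta=ant.sagitta,
                       graft_central_thickness=max(ant.sagitta - post.sagitta, 1.0))
    n = 257
    xs = np.linspace(ant.p1[0], ant.p2[0], n)
    profile = np.column_stack([
        (xs - ant.p1[0]) * cal.microns_per_pixel_lateral,
        (post.row_at(xs) - ant.row_at(xs)) * cal.microns_per_pixel_axial,
    ])
    return PhantomTruth(anterior_interface=ant, posterior_boundary=post,
                        true_area_um2=float(doc["true_area_um2"]),
                        true_thickness_profile=profile, spec=spec)


def _public_fields(spec: PhantomSpec) -> dict:
    d = {f: getattr(spec, f) for f in (
        "image_height", "image_width", "calibration", "cornea_apex_row",
        "cornea_anterior_sagitta", "cornea_thickness", "interface_contrast",
        "speckle_sigma", "background_level", "seed")}
    return d
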