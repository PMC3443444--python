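"""Circular-arc geometry for graft boundaries.

A DSAEK graft cross-section is modelled as the region between two shallow
circular arcs that share their two endpoints (the graft corners).  Arcs are
parameterised by the chord (the two endpoints) and a *signed sagitta*: the
perpendicular distance from the chord midpoint to the arc apex, positive
when the arc bulges toward the anterior side (smaller image rows), negative
when it bulges posteriorly.  All lengths are in pixels; rows increase with
axial depth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = ["Arc", "circular_segment_area", "area_between_arcs"]


def circular_segment_area(half_chord: float, sagitta: float) -> float:
    """Area of a circular segment with chord half-length ``a`` and
    (unsigned) sagitta ``h``; the shallow branch ``h <= a`` is assumed.

    Uses R = (a^2 + h^2) / 2h and A = R^2 arccos((R-h)/R) - (R-h) sqrt(2Rh - h^2).
    """
    a, h = float(half_chord), float(abs(sagitta))
    if a <= 0:
        raise GeometryError(f"half_chord must be positive, got {a}")
    if h == 0.0:
        return 0.0
    if h > a:
        raise GeometryError(f"sagitta {h} exceeds half chord {a}: arc not shallow")
    r = (a * a + h * h) / (2.0 * h)
    return r * r * np.arccos((r - h) / r) - (r - h) * np.sqrt(2.0 * r * h - h * h)


@dataclass(frozen=True)
class Arc:
    """Shallow circular arc through two endpoints, single-valued in column.

    ``p1``/``p2`` are (col, row) endpoints with p1 left of p2; ``sagitta``
    is signed: positive bulges anteriorly (towards smaller rows).  A zero
    sagitta degenerates to the straight chord.
    """

    p1: tuple[float, float]
    p2: tuple[float, float]
    sagitta: float

    def __post_init__(self):
        if self.p2[0] <= self.p1[0]:
            raise GeometryError("arc endpoints must have strictly increasing columns")

    @property
    def chord_length(self) -> float:
        dx = self.p2[0] - self.p1[0]
        dy = self.p2[1] - self.p1[1]
        return float(np.hypot(dx, dy))

    @property
    def radius(self) -> float:
        h = abs(self.sagitta)
        if h == 0.0:
            return np.inf
        a = self.chord_length / 2.0
        return (a * a + h * h) / (2.0 * h)

    def _center(self) -> tuple[float, float]:
        # unit normal to the chord pointing anteriorly (negative row component)
        (x1, y1), (x2, y2) = self.p1, self.p2
        L = self.chord_length
        nx, ny = (y2 - y1) / L, -(x2 - x1) / L  # rotate chord by -90 deg
        if ny > 0:  # ensure anterior orientation
            nx, ny = -nx, -ny
        mx, my = (x1 + x2) / 2.0, (y1 + y2) / 2.0
        h = self.sagitta
        # center lies on the opposite side of the apex, distance R from it
        off = h - np.sign(h) * self.radius
        return (mx + nx * off, my + ny * off)

    def row_at(self, cols: np.ndarray) -> np.ndarray:
        """Arc row at the given columns (vectorised).

        Columns outside [p1.col, p2.col] raise; the arc is single-valued in
        column only for shallow arcs, which ``sagitta <= half-chord``
        guarantees.
        """
        cols = np.asarray(cols, dtype=float)
        lo, hi = self.p1[0], self.p2[0]
        if np.any(cols < lo - 1e-9) or np.any(cols > hi + 1e-9):
            raise GeometryError("column outside the arc's lateral domain")
        if self.sagitta == 0.0:
            t = (cols - lo) / (hi - lo)
            return self.p1[1] + t * (self.p2[1] - self.p1[1])
        cx, cy = self._center()
        r = self.radius
        disc = np.maximum(r * r - (cols - cx) ** 2, 0.0)
        root = np.sqrt(disc)
        # anterior bulge -> arc is the upper (smaller-row) branch
        return cy - root if self.sagitta > 0 else cy + root

    def sample(self, n: int = 512) -> np.ndarray:
        """Dense (col, row) samples, endpoints included."""
        cols = np.linspace(self.p1[0], self.p2[0], n)
        return np.column_stack([cols, self.row_at(cols)])

    def segment_area(self) -> float:
        """Unsigned area between the arc and its chord."""
        if self.sagitta == 0.0:
            return 0.0
        return circular_segment_area(self.chord_length / 2.0, self.sagitta)


def area_between_arcs(anterior: Arc, posterior: Arc) -> float:
    """Area of the lens/meniscus region bounded by two arcs sharing a chord.

    The signed sagitta convention makes this the difference of signed
    segment areas: arcs bulging to the same side partially cancel
    (meniscus), opposite sides add (biconvex lens).
    """
    for a, b in zip(anterior.p1 + anterior.p2, posterior.p1 + posterior.p2):
        if abs(a - b) > 1e-9:
            raise GeometryError("arcs must share both endpoints")
    sa = np.sign(anterior.sagitta) * anterior.segment_area()
    sp = np.sign(posterior.sagitta) * posterior.segment_area()
    return float(abs(sa - sp))
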