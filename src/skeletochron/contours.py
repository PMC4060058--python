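"""Planar contour geometry for bone cross-section measurements.

Traced boundaries of a transverse bone section (medullary cavity, cyclical
growth marks, periosteal surface) are closed planar polygons in millimetre
coordinates.  This module computes the quantities a histomorphometry study
derives from such tracings: perimeter ("circumference"), enclosed and
cortical (annular) area, centroid and principal axes of the cortical region,
and the four-ray radial thickness profile measured from the centroid along
the +/- principal axes.

All polygon integrals (area, first and second moments) are evaluated with
the closed-form Green's-theorem formulas on the vertex list; shapely is used
for validity (simplicity) and containment checks only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "Contour",
    "AnnularSection",
    "PrincipalFrame",
    "RadialProfile",
    "ContourError",
    "perimeter",
    "enclosed_area",
    "cortical_area",
    "region_centroid",
    "principal_frame",
    "radial_profile",
]

#: labels a contour may carry; cgm contours use "cgm1", "cgm2", ...
BASE_LABELS = ("medullary", "surface", "hatchling_surface")


class ContourError(ValueError):
    """Raised for degenerate or invalid contour geometry."""


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y1 - x1 * y))


@dataclass(frozen=True)
class Contour:
    """A simple closed polygon tracing one histological boundary.

    Vertices are stored counter-clockwise with the first vertex not
    repeated at the end; other input conventions are normalised on
    construction.  Coordinates are in mm.
    """

    vertices: np.ndarray
    label: str = "surface"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ContourError("vertices must be an (n, 2) array of points")
        # drop an explicitly repeated closing vertex
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ContourError(f"degenerate contour: {len(v)} vertices (<3)")
        a = _signed_area(v)
        if abs(a) < 1e-12:
            raise ContourError("degenerate contour: zero enclosed area")
        if a < 0:  # stored CCW
            v = v[::-1]
        if not Polygon(v).is_valid:
            raise ContourError("self-intersecting contour")
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def transformed(self, *, rotation: float = 0.0,
                    translation: Sequence[float] = (0.0, 0.0)) -> "Contour":
        """Rigidly transform the contour (rotation in radians about origin)."""
        c, s = math.cos(rotation), math.sin(rotation)
        R = np.array([[c, -s], [s, c]])
        return Contour(self.vertices @ R.T + np.asarray(translation, float),
                       label=self.label)


@dataclass(frozen=True)
class AnnularSection:
    """Cortical region between an outer boundary and an optional inner one.

    ``outer`` is typically a growth-mark or periosteal-surface contour;
    ``inner`` the medullary cavity.  When ``inner`` is absent the section is
    the full region enclosed by ``outer``.
    """

    outer: Contour
    inner: Optional[Contour] = None

    def __post_init__(self) -> None:
        if self.inner is not None:
            if not self.outer.shapely.contains(self.inner.shapely):
                raise ContourError("inner contour does not nest inside outer")


@dataclass(frozen=True)
class PrincipalFrame:
    """Centroid and principal axes of a cortical annulus.

    ``second_moments`` are the central second area moments
    (Ixx = ∫y'²dA, Iyy = ∫x'²dA, Ixy = ∫x'y'dA) in mm⁴, primes taken about
    the centroid.  ``major_axis`` points along the direction of largest
    areal variance; axes are orthonormal with minor = major rotated +90°.
    """

    centroid: np.ndarray
    major_axis: np.ndarray
    minor_axis: np.ndarray
    second_moments: tuple[float, float, float]

    @property
    def eigenvalues(self) -> tuple[float, float]:
        ixx, iyy, ixy = self.second_moments
        t = np.array([[iyy, ixy], [ixy, ixx]])
        w = np.linalg.eigvalsh(t)
        return float(w[1]), float(w[0])  # (major, minor)


@dataclass(frozen=True)
class RadialProfile:
    """Centroid-to-contour distances along ±major / ±minor axes (mm)."""

    distances: tuple[float, float, float, float]  # +major, -major, +minor, -minor
    mean: float


# ---------------------------------------------------------------------------
# scalar measurements

def perimeter(c: Contour) -> float:
    """Circumference of the contour: summed edge lengths incl. closing edge."""
    d = np.diff(np.vstack([c.vertices, c.vertices[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def enclosed_area(c: Contour) -> float:
    """Absolute shoelace area enclosed by the contour (mm²)."""
    return abs(_signed_area(c.vertices))


def cortical_area(s: AnnularSection) -> float:
    """Area of the annulus: enclosed_area(outer) − enclosed_area(inner)."""
    a = enclosed_area(s.outer)
    if s.inner is not None:
        a -= enclosed_area(s.inner)
    return a


# ---------------------------------------------------------------------------
# polygon moment integrals (Green's theorem closed forms)

def _moments(v: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Signed (A, Sx, Sy, Ixx, Iyy, Ixy) about the origin for one polygon."""
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    sx = np.sum(cross * (x + x1)) / 6.0          # ∫x dA
    sy = np.sum(cross * (y + y1)) / 6.0          # ∫y dA
    ixx = np.sum(cross * (y * y + y * y1 + y1 * y1)) / 12.0   # ∫y² dA
    iyy = np.sum(cross * (x * x + x * x1 + x1 * x1)) / 12.0   # ∫x² dA
    ixy = np.sum(cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)) / 24.0
    return float(a), float(sx), float(sy), float(ixx), float(iyy), float(ixy)


def _section_moments(s: AnnularSection):
    a, sx, sy, ixx, iyy, ixy = _moments(s.outer.vertices)
    if s.inner is not None:
        ai, sxi, syi, ixxi, iyyi, ixyi = _moments(s.inner.vertices)
        a, sx, sy = a - ai, sx - sxi, sy - syi
        ixx, iyy, ixy = ixx - ixxi, iyy - iyyi, ixy - ixyi
    return a, sx, sy, ixx, iyy, ixy


def region_centroid(s: AnnularSection) -> np.ndarray:
    """Centroid of the annular region by signed-area composition."""
    a, sx, sy, *_ = _section_moments(s)
    if abs(a) < 1e-12:
        raise ContourError("zero-area annulus: centroid undefined")
    return np.array([sx / a, sy / a])


_ISOTROPY_RTOL = 1e-9


def principal_frame(s: AnnularSection) -> PrincipalFrame:
    """Centroid and principal axes of the cortical annulus.

    Second moments are taken about the region centroid (parallel-axis
    shift of the origin moments).  For an isotropic tensor (circular
    sections) the axes default to +x/+y so downstream four-ray means are
    reproducible.
    """
    a, sx, sy, ixx, iyy, ixy = _section_moments(s)
    if abs(a) < 1e-12:
        raise ContourError("zero-area annulus")
    cx, cy = sx / a, sy / a
    ixx_c = ixx - a * cy * cy
    iyy_c = iyy - a * cx * cx
    ixy_c = ixy - a * cx * cy
    # areal variance tensor: [[var_x, cov], [cov, var_y]]
    t = np.array([[iyy_c, ixy_c], [ixy_c, ixx_c]])
    w, vec = np.linalg.eigh(t)
    scale = max(abs(w[0]), abs(w[1]), 1e-30)
    if abs(w[1] - w[0]) <= _ISOTROPY_RTOL * scale:
        major = np.array([1.0, 0.0])
        minor = np.array([0.0, 1.0])
    else:
        major = vec[:, 1]  # larger eigenvalue
        # deterministic sign: positive x half-plane (ties → positive y)
        if major[0] < 0 or (abs(major[0]) < 1e-12 and major[1] < 0):
            major = -major
        minor = np.array([-major[1], major[0]])
    return PrincipalFrame(
        centroid=np.array([cx, cy]),
        major_axis=major,
        minor_axis=minor,
        second_moments=(ixx_c, iyy_c, ixy_c),
    )


# ---------------------------------------------------------------------------
# ray casting

def _ray_crossings(origin: np.ndarray, direction: np.ndarray,
                  v: np.ndarray) -> np.ndarray:
    """Positive ray parameters t where origin + t·direction crosses edges."""
    p = v
    q = np.roll(v, -1, axis=0)
    e = q - p
    d = direction
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    w = p - origin
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
        u = (w[:, 0] * d[1] - w[:, 1] * d[0]) / denom
    # half-open edge interval with a tolerance so a ray through a shared
    # vertex is counted exactly once
    eps = 1e-9
    ok = (np.abs(denom) > 1e-15) & (u >= -eps) & (u < 1.0 - eps) & (t > 1e-12)
    t = np.sort(t[ok])
    if t.size > 1:  # drop duplicates from vertex-grazing numerics
        t = t[np.concatenate([[True], np.diff(t) > 1e-9 * max(1.0, t[0])])]
    return t


def radial_profile(frame: PrincipalFrame, c: Contour) -> RadialProfile:
    """Distances from the frame centroid to the contour along the four
    principal half-axes, plus their mean (the cumulative cortical radial
    thickness at this growth mark).

    The contour must enclose the centroid; if a ray crosses the boundary
    more than once (contour not star-convex about the centroid) the nearest
    crossing is used and a warning is logged.
    """
    if not c.shapely.contains(Point(frame.centroid)):
        raise ContourError("centroid lies outside contour: rays undefined")
    dirs = (frame.major_axis, -frame.major_axis,
            frame.minor_axis, -frame.minor_axis)
    dist = []
    for d in dirs:
        t = _ray_crossings(frame.centroid, d, c.vertices)
        if t.size == 0:
            raise ContourError("ray does not intersect contour")
        if t.size > 1:
            logger.warning(
                "contour %r not star-convex about centroid; using nearest "
                "of %d crossings", c.label, t.size)
        dist.append(float(t[0]))
    dist = tuple(dist)
    return RadialProfile(distances=dist, mean=float(np.mean(dist)))
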