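"""Spherical geometry of the retinal coordinate system.

The retina is modeled as a cap of the unit sphere with the fovea at the
pole.  A location is given in retinal polar coordinates: *eccentricity*,
the arc angle from the fovea (degrees, 0-60 inside the mapped window), and
*polar angle*, measured from the superior vertical meridian (0 deg) toward
the nasal horizontal meridian (90 deg) in canonical right-eye orientation.

Flat maps use the azimuthal equidistant projection centered on the fovea:
``x = ecc * sin(angle)`` (positive nasal), ``y = ecc * cos(angle)``
(positive superior).  The projection preserves distances and directions
from the fovea exactly; all other pairwise distances are inflated, so the
planar Euclidean distance between two projected points is always >= the
great-circle distance between the retinal locations.

Areas and centroids of retinal regions are computed on the sphere itself,
via line integrals around the (densified, great-circle-edged) boundary, to
avoid the distortion of the flat projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "CapWindow",
    "EyeSide",
    "RetinalPoint",
    "ProjectedPoint",
    "project",
    "unproject",
    "to_unit_vectors",
    "from_unit_vectors",
    "great_circle_distance",
    "canonicalize",
    "densify_boundary",
    "spherical_region_area",
    "spherical_centroid",
    "perimeter_centroid",
    "cap_boundary",
    "max_centroid_eccentricity",
]

#: degrees <-> radians
_D2R = np.pi / 180.0
_R2D = 180.0 / np.pi

LEFT = "left"
RIGHT = "right"
EyeSide = str  # one of {"left", "right"}


class GeometryError(ValueError):
    """Raised for degenerate or self-intersecting boundaries."""


class OutOfWindowError(ValueError):
    """Raised when a point lies outside the mapped retinal window."""


@dataclass(frozen=True)
class CapWindow:
    """The mapped retinal window: a spherical cap around the fovea.

    Parameters
    ----------
    radius : float
        Maximum eccentricity of the mapped retina, degrees (default 60).
    optic_disc_angle : float
        Polar angle of the optic disc in canonical right-eye orientation,
        degrees (default 88; the disc sits essentially on the nasal
        horizontal meridian).
    """

    radius: float = 60.0
    optic_disc_angle: float = 88.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("window radius must be positive")

    @property
    def planar_area(self) -> float:
        """Area of the window in the flat projection, square degrees."""
        return float(np.pi * self.radius**2)

    @property
    def solid_angle(self) -> float:
        """Spherical area of the window, steradians."""
        return float(2.0 * np.pi * (1.0 - np.cos(self.radius * _D2R)))

    def contains(self, ecc_deg, tol: float = 1e-9):
        return np.asarray(ecc_deg) <= self.radius + tol


@dataclass(frozen=True)
class RetinalPoint:
    """A location on the retina in (eccentricity, polar angle) degrees."""

    eccentricity: float
    polar_angle: float

    def __post_init__(self) -> None:
        if self.eccentricity < 0:
            raise ValueError("eccentricity must be nonnegative")
        ang = 0.0 if self.eccentricity == 0 else float(self.polar_angle) % 360.0
        object.__setattr__(self, "polar_angle", ang)

    def as_tuple(self) -> tuple[float, float]:
        return (self.eccentricity, self.polar_angle)


@dataclass(frozen=True)
class ProjectedPoint:
    """A location in the azimuthal equidistant projection, degrees."""

    x: float
    y: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


# ---------------------------------------------------------------------------
# coordinate transforms (vectorized; degrees in, degrees out)
# ---------------------------------------------------------------------------

def project(ecc_deg, angle_deg):
    """Azimuthal equidistant projection of retinal polar coordinates.

    Returns ``(x, y)`` in degrees with superior up (+y) and nasal right
    (+x).  The radial distance from the origin equals the eccentricity
    exactly — the defining property of the projection.
    """
    ecc = np.asarray(ecc_deg, dtype=float)
    ang = np.asarray(angle_deg, dtype=float) * _D2R
    return ecc * np.sin(ang), ecc * np.cos(ang)


def unproject(x_deg, y_deg, window: CapWindow | None = None):
    """Inverse of :func:`project`; errors for points outside the window."""
    x = np.asarray(x_deg, dtype=float)
    y = np.asarray(y_deg, dtype=float)
    ecc = np.hypot(x, y)
    if window is not None and np.any(ecc > window.radius + 1e-9):
        raise OutOfWindowError("point outside the mapped window")
    ang = np.degrees(np.arctan2(x, y)) % 360.0
    ang = np.where(ecc == 0, 0.0, ang)
    return ecc, ang


def to_unit_vectors(ecc_deg, angle_deg):
    """Unit vectors on the retinal sphere, fovea at the +z pole.

    Eccentricity is the colatitude, polar angle the longitude measured
    from the +y (superior) axis toward +x (nasal).
    """
    th = np.asarray(ecc_deg, dtype=float) * _D2R
    lam = np.asarray(angle_deg, dtype=float) * _D2R
    st = np.sin(th)
    return np.stack([st * np.sin(lam), st * np.cos(lam), np.cos(th)], axis=-1)


def from_unit_vectors(u):
    """Retinal (eccentricity, polar angle) in degrees from unit vectors."""
    u = np.asarray(u, dtype=float)
    ecc = np.degrees(np.arccos(np.clip(u[..., 2], -1.0, 1.0)))
    ang = np.degrees(np.arctan2(u[..., 0], u[..., 1])) % 360.0
    ang = np.where(ecc == 0, 0.0, ang)
    return ecc, ang


def great_circle_distance(ecc_a, ang_a, ecc_b, ang_b):
    """Great-circle (arc) distance between retinal locations, degrees.

    Uses the numerically stable arctan2 form; symmetric and satisfies the
    triangle inequality.
    """
    ua = to_unit_vectors(ecc_a, ang_a)
    ub = to_unit_vectors(ecc_b, ang_b)
    cross = np.linalg.norm(np.cross(ua, ub), axis=-1)
    dot = np.sum(ua * ub, axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def canonicalize(ecc_deg, angle_deg, side: EyeSide):
    """Map a retinal location to canonical right-eye orientation.

    Right-eye points are unchanged.  Left-eye points are reflected across
    the vertical meridian (superior/inferior preserved, nasal/temporal
    swapped) so that nasal retina aligns with nasal retina when pooling
    the two eyes.
    """
    if side not in (LEFT, RIGHT):
        raise ValueError(f"unknown eye side {side!r}")
    ecc = np.asarray(ecc_deg, dtype=float)
    ang = np.asarray(angle_deg, dtype=float) % 360.0
    if side == LEFT:
        ang = (360.0 - ang) % 360.0
    ang = np.where(ecc == 0, 0.0, ang)
    return ecc, ang


# ---------------------------------------------------------------------------
# spherical region area and centroid
# ---------------------------------------------------------------------------

def _slerp_densify(u, max_step_deg: float):
    """Insert points along great-circle edges so steps are <= max_step_deg.

    ``u``: (n, 3) closed-implied vertex unit vectors.  Returns an (m, 3)
    closed polyline (first point repeated at the end).
    """
    a = u
    b = np.roll(u, -1, axis=0)
    dot = np.clip(np.sum(a * b, axis=1), -1.0, 1.0)
    omega = np.arccos(dot)  # (n,) edge arc lengths
    # one shared subdivision count keeps the interpolation fully vectorized
    nseg = max(1, int(np.ceil(np.degrees(omega.max(initial=0.0)) / max_step_deg)))
    t = (np.arange(nseg) / nseg)[None, :, None]  # (1, nseg, 1)
    om = omega[:, None, None]
    so = np.sin(om)
    safe = np.where(so > 1e-12, so, 1.0)
    seg = (np.sin((1 - t) * om) * a[:, None, :] + np.sin(t * om) * b[:, None, :]) / safe
    degenerate = (so <= 1e-12)[:, 0, 0]
    if degenerate.any():
        seg[degenerate] = a[degenerate, None, :]
    pts = np.concatenate([seg.reshape(-1, 3), u[:1]], axis=0)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _check_simple(ecc_deg, ang_deg) -> None:
    x, y = project(ecc_deg, ang_deg)
    poly = _ShapelyPolygon(np.column_stack([x, y]))
    if not poly.is_valid:
        raise GeometryError("boundary is self-intersecting or degenerate")


def _boundary_integrals(u_closed):
    """Line integrals around a closed spherical polyline.

    Returns the signed enclosed solid angle and the (unnormalized) first
    moment of position over the enclosed area, from the antiderivatives of
    the spherical area element: with colatitude theta and longitude lam,

        area = integral (1 - cos theta) d lam
        Sx   = integral sin(lam) (theta/2 - sin(2 theta)/4) d lam
        Sy   = integral cos(lam) (theta/2 - sin(2 theta)/4) d lam
        Sz   = integral sin(theta)^2 / 2 d lam

    evaluated by the trapezoid rule with the longitude unwrapped.  Exact in
    the limit of dense boundary points; regions containing the pole are
    handled by the +-2*pi winding of the longitude.
    """
    z = np.clip(u_closed[:, 2], -1.0, 1.0)
    th = np.arccos(z)
    lam = np.unwrap(np.arctan2(u_closed[:, 0], u_closed[:, 1]))
    dlam = np.diff(lam)

    def _trapz(f):
        return float(np.sum(0.5 * (f[1:] + f[:-1]) * dlam))

    area = _trapz(1.0 - np.cos(th))
    m = th / 2.0 - np.sin(2.0 * th) / 4.0
    sx = _trapz(np.sin(lam) * m)
    sy = _trapz(np.cos(lam) * m)
    sz = _trapz(np.sin(th) ** 2 / 2.0)
    return area, np.array([sx, sy, sz])


def densify_boundary(ecc_deg, ang_deg, max_step_deg: float = 0.5):
    """Densify a closed retinal boundary along great-circle edges.

    Returns (ecc, ang) arrays of the densified open polyline (the closing
    point is not repeated).
    """
    u = to_unit_vectors(np.asarray(ecc_deg, float), np.asarray(ang_deg, float))
    dense = _slerp_densify(u, max_step_deg)[:-1]
    return from_unit_vectors(dense)


def _prepare_boundary(ecc_deg, ang_deg, max_step_deg, check_simple):
    ecc = np.atleast_1d(np.asarray(ecc_deg, dtype=float))
    ang = np.atleast_1d(np.asarray(ang_deg, dtype=float))
    pts = np.column_stack([ecc, ang])
    distinct = np.unique(np.round(pts, 9), axis=0)
    if len(distinct) < 3:
        raise GeometryError("boundary needs at least 3 distinct vertices")
    if check_simple:
        _check_simple(ecc, ang)
    u = to_unit_vectors(ecc, ang)
    return _slerp_densify(u, max_step_deg)


def spherical_region_area(
    ecc_deg,
    ang_deg,
    window: CapWindow | None = None,
    max_step_deg: float = 0.5,
    check_simple: bool = True,
):
    """Solid angle and window-fraction of a simple closed spherical polygon.

    Edges between consecutive vertices are great-circle arcs, densified to
    ``max_step_deg`` before integration.  The fraction is relative to the
    spherical area of the 60-degree window (or the window supplied).
    """
    window = window or CapWindow()
    closed = _prepare_boundary(ecc_deg, ang_deg, max_step_deg, check_simple)
    area, _ = _boundary_integrals(closed)
    solid = abs(area)
    return solid, solid / window.solid_angle


def spherical_centroid(
    ecc_deg,
    ang_deg,
    max_step_deg: float = 0.5,
    check_simple: bool = True,
) -> RetinalPoint:
    """Center of mass of the region enclosed by a spherical polygon.

    The mean of unit position vectors over the enclosed area (uniform
    surface density), renormalized to the sphere and returned in retinal
    coordinates.  Raises :class:`GeometryError` when the mean vector is
    degenerate (antipodally balanced region).
    """
    closed = _prepare_boundary(ecc_deg, ang_deg, max_step_deg, check_simple)
    area, s = _boundary_integrals(closed)
    if area < 0:
        s = -s
    norm = np.linalg.norm(s)
    if norm < 1e-12:
        raise GeometryError("degenerate centroid: mean direction undefined")
    ecc, ang = from_unit_vectors(s / norm)
    return RetinalPoint(float(ecc), float(ang))


def perimeter_centroid(ecc_deg, ang_deg, max_step_deg: float = 0.5) -> RetinalPoint:
    """Mean direction of the boundary curve itself (arc-length weighted).

    Provided as an alternative to the area centroid: the center of mass of
    the contour rather than of the enclosed surface.
    """
    u = to_unit_vectors(np.asarray(ecc_deg, float), np.asarray(ang_deg, float))
    closed = _slerp_densify(u, max_step_deg)
    mid = 0.5 * (closed[1:] + closed[:-1])
    seg = np.degrees(
        np.arctan2(
            np.linalg.norm(np.cross(closed[:-1], closed[1:]), axis=1),
            np.sum(closed[:-1] * closed[1:], axis=1),
        )
    )
    s = np.sum(mid * seg[:, None], axis=0)
    norm = np.linalg.norm(s)
    if norm < 1e-12:
        raise GeometryError("degenerate centroid: mean direction undefined")
    ecc, ang = from_unit_vectors(s / norm)
    return RetinalPoint(float(ecc), float(ang))


def cap_boundary(center_ecc, center_ang, radius_deg, n_vertices: int = 72):
    """Vertices of a circular cap of angular radius ``radius_deg`` around a
    retinal center, as (ecc, ang) arrays ordered around the cap."""
    c = to_unit_vectors(center_ecc, center_ang)
    # orthonormal frame at the center
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(c, ref)) > 0.999999:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(c, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(c, e1)
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = radius_deg * _D2R
    pts = (
        np.cos(r) * c[None, :]
        + np.sin(r) * (np.cos(t)[:, None] * e1[None, :] + np.sin(t)[:, None] * e2[None, :])
    )
    return from_unit_vectors(pts)


def max_centroid_eccentricity(area_fraction, mode: str = "approx", window: CapWindow | None = None):
    """Maximum eccentricity of the center of a circular tumor of given area.

    A circular tumor covering ``area_fraction`` of the window can sit no
    further out than where it just touches the window edge.  ``approx``
    uses the flat-map rule ``R * (1 - sqrt(area_fraction))``; ``exact``
    inverts the spherical-cap area formula for the tumor radius rho and
    returns ``R - rho``.  Both are monotonically decreasing in the area
    fraction and agree at 0 and 1.
    """
    window = window or CapWindow()
    a = np.asarray(area_fraction, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("area_fraction must lie in [0, 1]")
    r = window.radius
    if mode == "approx":
        return r * (1.0 - np.sqrt(a))
    if mode == "exact":
        # cap radius rho with (1 - cos rho) / (1 - cos R) = a
        cos_rho = 1.0 - a * (1.0 - np.cos(r * _D2R))
        rho = np.degrees(np.arccos(np.clip(cos_rho, -1.0, 1.0)))
        return r - rho
    raise ValueError(f"unknown mode {mode!r}")
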