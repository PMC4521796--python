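"""Tumor perimeters, per-tumor metrics, burden maps, and margin distances.

A tumor is recorded as an ordered list of retinal perimeter vertices plus
clinical marks (mutation type, age at diagnosis, eye side, ICRB group).
Perimeters are interpolated with a periodic cubic spline in the flat
projection (matching how hand-drawn fundus maps are traced), while areas
and centroids are evaluated on the sphere, where the map is undistorted.

Cumulative tumor burden at a retinal location is the number of distinct
eyes with tumor covering that location; per-age-quartile burden is the
fraction of that quartile's tumors overlapping each location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon as _ShapelyPolygon

from . import geometry
from .geometry import CapWindow, GeometryError, RetinalPoint

__all__ = [
    "TumorPerimeter",
    "TumorRecord",
    "SectorRecord",
    "Cohort",
    "RasterGrid",
    "BurdenMap",
    "interpolate_perimeter",
    "rasterize",
    "compute_tumor_metrics",
    "cumulative_burden",
    "margin_distance",
]

GERMLINE = "germline"
SOMATIC = "somatic"


@dataclass(frozen=True)
class TumorPerimeter:
    """Closed tumor boundary: ordered retinal vertices (degrees).

    The final vertex connects back to the first.  Vertices are stored in
    canonical right-eye orientation.
    """

    eccentricity: np.ndarray
    polar_angle: np.ndarray

    def __post_init__(self) -> None:
        ecc = np.atleast_1d(np.asarray(self.eccentricity, dtype=float))
        ang = np.atleast_1d(np.asarray(self.polar_angle, dtype=float)) % 360.0
        if len(ecc) != len(ang):
            raise ValueError("eccentricity and polar_angle differ in length")
        distinct = np.unique(np.round(np.column_stack([ecc, ang]), 9), axis=0)
        if len(distinct) < 3:
            raise GeometryError("perimeter needs at least 3 distinct vertices")
        object.__setattr__(self, "eccentricity", ecc)
        object.__setattr__(self, "polar_angle", ang)

    def __len__(self) -> int:
        return len(self.eccentricity)

    def projected(self):
        return geometry.project(self.eccentricity, self.polar_angle)


@dataclass
class TumorRecord:
    """One mapped tumor with marks and derived spatial metrics."""

    patient_id: str
    eye_id: str
    tumor_id: str
    side: str
    mutation: str
    age_months: float
    perimeter: TumorPerimeter
    icrb_group: str | None = None
    centroid: RetinalPoint | None = None
    area_fraction: float | None = None
    age_quartile: int | None = None
    area_quartile: int | None = None


@dataclass(frozen=True)
class SectorRecord:
    """A fundoscopy-only small tumor located to a retinal sector.

    ``vertical`` is one of superior / inferior / meridian / macula (the
    meridian and macula labels are excluded from superior-vs-inferior
    tallies); ``horizontal`` is nasal / temporal / macula; ``depth`` is
    anterior / posterior relative to the equator.
    """

    patient_id: str
    eye_id: str
    vertical: str
    horizontal: str
    depth: str
    age_months: float
    age_quartile: int | None = None

    _VERT = {"superior", "inferior", "meridian", "macula"}
    _HORZ = {"nasal", "temporal", "macula"}
    _DEPTH = {"anterior", "posterior"}

    def __post_init__(self) -> None:
        if self.vertical not in self._VERT:
            raise ValueError(f"unknown vertical sector {self.vertical!r}")
        if self.horizontal not in self._HORZ:
            raise ValueError(f"unknown horizontal sector {self.horizontal!r}")
        if self.depth not in self._DEPTH:
            raise ValueError(f"unknown depth sector {self.depth!r}")


@dataclass
class Cohort:
    """Patients -> eyes -> tumors, plus fundoscopy-only sector records."""

    tumors: list[TumorRecord]
    sectors: list[SectorRecord] = field(default_factory=list)
    patients: "object | None" = None  # pandas DataFrame of per-patient rows
    seed: int | None = None

    def eyes(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.tumors:
            seen.setdefault(t.eye_id)
        return list(seen)

    def multiplet_eyes(self) -> dict[str, list[int]]:
        """Eye id -> indices of its tumors, for eyes with >= 2 tumors."""
        by_eye: dict[str, list[int]] = {}
        for i, t in enumerate(self.tumors):
            by_eye.setdefault(t.eye_id, []).append(i)
        return {e: idx for e, idx in by_eye.items() if len(idx) >= 2}


# ---------------------------------------------------------------------------
# perimeter interpolation
# ---------------------------------------------------------------------------

def interpolate_perimeter(
    perimeter: TumorPerimeter,
    step: float = 0.25,
    window: CapWindow | None = None,
) -> TumorPerimeter:
    """Smoothly interpolate a closed perimeter through its vertices.

    A periodic cubic spline in projected coordinates, parameterized by
    cumulative chord length and resampled so consecutive points are at
    most ``step`` degrees apart.  The curve passes through every input
    vertex.  Points that leave the window are clipped radially to the
    window rim.  A self-intersecting result triggers a warning (the
    rasterizer then applies its fill rule) but is returned as-is.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    window = window or CapWindow()
    x, y = perimeter.projected()
    xc = np.append(x, x[0])
    yc = np.append(y, y[0])
    chord = np.hypot(np.diff(xc), np.diff(yc))
    if np.any(chord == 0):
        keep = np.concatenate([[True], chord[:-1] > 0])
        xc = np.append(xc[:-1][keep], xc[0])
        yc = np.append(yc[:-1][keep], yc[0])
        chord = np.hypot(np.diff(xc), np.diff(yc))
    t = np.concatenate([[0.0], np.cumsum(chord)])
    sx = CubicSpline(t, xc, bc_type="periodic")
    sy = CubicSpline(t, yc, bc_type="periodic")
    # sample each inter-vertex segment, keeping the knots themselves
    ts = [np.array([0.0])]
    for i in range(len(t) - 1):
        n = max(1, int(np.ceil((t[i + 1] - t[i]) / step)))
        ts.append(np.linspace(t[i], t[i + 1], n + 1)[1:])
    tt = np.concatenate(ts)[:-1]  # drop the duplicated closing point
    xs, ys = sx(tt), sy(tt)
    r = np.hypot(xs, ys)
    outside = r > window.radius
    if np.any(outside):
        scale = window.radius / r[outside]
        xs[outside] *= scale
        ys[outside] *= scale
    poly = _ShapelyPolygon(np.column_stack([xs, ys]))
    if not poly.is_valid:
        warnings.warn(
            "interpolated perimeter self-intersects; even-odd fill will be "
            "used at rasterization",
            stacklevel=2,
        )
    ecc, ang = geometry.unproject(xs, ys)
    return TumorPerimeter(ecc, ang)


# ---------------------------------------------------------------------------
# rasterization and burden maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RasterGrid:
    """Square pixel grid covering the projected window.

    Pixel centers at ``-R + pitch/2, ...`` on both axes; pixels whose
    centers fall outside the circular window are masked.
    """

    pitch: float = 0.25
    window: CapWindow = field(default_factory=CapWindow)

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n(self) -> int:
        return int(np.ceil(2.0 * self.window.radius / self.pitch))

    @property
    def centers(self):
        c = -self.window.radius + self.pitch * (np.arange(self.n) + 0.5)
        return c

    @property
    def xy(self):
        """(x, y) meshgrids of pixel centers; y decreases down rows so the
        array renders with superior at the top."""
        c = self.centers
        x, y = np.meshgrid(c, c[::-1])
        return x, y

    @property
    def in_window(self):
        x, y = self.xy
        return np.hypot(x, y) <= self.window.radius

    def pixel_solid_angles(self):
        """Spherical solid angle of each pixel (steradians).

        The azimuthal equidistant area element is sin(theta)/theta per
        unit projected area (theta the eccentricity in radians), so pixel
        solid angle = sinc-corrected pitch^2.
        """
        x, y = self.xy
        th = np.radians(np.hypot(x, y))
        jac = np.where(th > 0, np.sin(th) / np.where(th > 0, th, 1.0), 1.0)
        return jac * (np.radians(self.pitch) ** 2)


@dataclass
class BurdenMap:
    """Per-pixel overlap values on a raster grid.

    ``values`` holds eye counts (integers) or per-quartile overlap
    fractions in [0, 1]; out-of-window pixels are masked with NaN in
    :meth:`as_masked`.
    """

    grid: RasterGrid
    values: np.ndarray
    mode: str

    def as_masked(self):
        out = np.asarray(self.values, dtype=float).copy()
        out[~self.grid.in_window] = np.nan
        return out


def rasterize(boundary: TumorPerimeter, grid: RasterGrid) -> np.ndarray:
    """Boolean mask of grid pixels on or inside a closed boundary.

    Point-in-polygon is evaluated in the flat projection (a homeomorphism
    of the window, so region membership is preserved).  The spherical area
    of the true pixels converges to the exact region area as the pitch
    shrinks.  An empty mask (tumor smaller than one pixel) triggers a
    warning.
    """
    x, y = boundary.projected()
    verts = np.column_stack([x, y])
    path = _MplPath(verts, closed=False)
    gx, gy = grid.xy
    # restrict the test to the boundary's bounding box
    xmin, xmax = x.min() - grid.pitch, x.max() + grid.pitch
    ymin, ymax = y.min() - grid.pitch, y.max() + grid.pitch
    cols = (gx[0] >= xmin) & (gx[0] <= xmax)
    rows = (gy[:, 0] >= ymin) & (gy[:, 0] <= ymax)
    mask = np.zeros(gx.shape, dtype=bool)
    if rows.any() and cols.any():
        sub = np.column_stack([gx[np.ix_(rows, cols)].ravel(), gy[np.ix_(rows, cols)].ravel()])
        inside = path.contains_points(sub, radius=1e-9)
        mask[np.ix_(rows, cols)] = inside.reshape(rows.sum(), cols.sum())
    mask &= grid.in_window
    if not mask.any():
        warnings.warn("tumor smaller than one pixel: empty raster mask", stacklevel=2)
    return mask


def compute_tumor_metrics(record: TumorRecord, interpolation_step: float = 0.25) -> TumorRecord:
    """Fill the derived centroid and area fraction of a tumor record.

    The perimeter is first smoothly interpolated, then the spherical area
    fraction and area centroid are computed on the sphere.  Idempotent.
    """
    dense = interpolate_perimeter(record.perimeter, step=interpolation_step)
    _, frac = geometry.spherical_region_area(
        dense.eccentricity, dense.polar_angle, check_simple=False
    )
    centroid = geometry.spherical_centroid(
        dense.eccentricity, dense.polar_angle, check_simple=False
    )
    return replace(record, centroid=centroid, area_fraction=float(frac))


def cumulative_burden(
    tumors: list[TumorRecord],
    grid: RasterGrid | None = None,
    mode: str = "eye_count",
    interpolation_step: float = 0.25,
) -> BurdenMap:
    """Cumulative tumor burden over the retina.

    ``eye_count``: per pixel, the number of distinct eyes with tumor there
    (several tumors in one eye count once).  ``quartile_fraction``: per
    pixel, the fraction of the supplied tumors overlapping it (call with
    one age quartile's tumors to reproduce per-quartile overlap maps).
    """
    grid = grid or RasterGrid()
    if mode not in ("eye_count", "quartile_fraction"):
        raise ValueError(f"unknown burden mode {mode!r}")
    if mode == "eye_count":
        values = np.zeros((grid.n, grid.n), dtype=int)
        by_eye: dict[str, np.ndarray] = {}
        for t in tumors:
            dense = interpolate_perimeter(t.perimeter, step=interpolation_step)
            m = rasterize(dense, grid)
            if t.eye_id in by_eye:
                by_eye[t.eye_id] |= m
            else:
                by_eye[t.eye_id] = m
        for m in by_eye.values():
            values += m
        return BurdenMap(grid, values, mode)
    values = np.zeros((grid.n, grid.n), dtype=float)
    for t in tumors:
        dense = interpolate_perimeter(t.perimeter, step=interpolation_step)
        values += rasterize(dense, grid)
    if tumors:
        values /= len(tumors)
    return BurdenMap(grid, values, mode)


def margin_distance(
    a: TumorRecord,
    b: TumorRecord,
    densify_step: float = 0.25,
) -> tuple[float, float, bool]:
    """Shortest boundary-to-boundary distance between two tumors.

    Returns ``(margin, centroid_distance, overlap)`` with both distances
    as great-circle degrees.  The margin is 0 when the regions intersect
    or one contains the other (``overlap=True``); tangency gives margin 0
    without overlap.  Always ``margin <= centroid_distance``.
    """
    da = interpolate_perimeter(a.perimeter, step=densify_step)
    db = interpolate_perimeter(b.perimeter, step=densify_step)
    pa = _ShapelyPolygon(np.column_stack(da.projected()))
    pb = _ShapelyPolygon(np.column_stack(db.projected()))
    overlap = bool(pa.buffer(0).intersection(pb.buffer(0)).area > 0)
    ca = a.centroid or geometry.spherical_centroid(da.eccentricity, da.polar_angle, check_simple=False)
    cb = b.centroid or geometry.spherical_centroid(db.eccentricity, db.polar_angle, check_simple=False)
    cdist = float(
        geometry.great_circle_distance(
            ca.eccentricity, ca.polar_angle, cb.eccentricity, cb.polar_angle
        )
    )
    if overlap:
        return 0.0, cdist, True
    ua = geometry.to_unit_vectors(da.eccentricity, da.polar_angle)
    ub = geometry.to_unit_vectors(db.eccentricity, db.polar_angle)
    dots = np.clip(ua @ ub.T, -1.0, 1.0)
    margin = float(np.degrees(np.arccos(dots.max())))
    return min(margin, cdist), cdist, False
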