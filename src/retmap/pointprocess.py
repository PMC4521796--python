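"""Marked inhomogeneous Poisson point-process models for tumor centroids.

Tumor centroids in the 60-degree retinal window are treated as a marked
spatial point pattern (marks: mutation type, age quartile, tumor-area
quartile, eye id).  The first-order structure is modeled as an
inhomogeneous Poisson process whose log intensity is polynomial in the
projected Cartesian coordinates,

    log lambda(x, y) = sum_{i+j <= d} beta_ij x^i y^j,

fitted by maximizing the Poisson process log-likelihood

    l(beta) = sum_k log lambda(x_k) - integral_W lambda

via the Berman-Turner quadrature device: data and dummy points receive
counting-measure weights that sum exactly to the window area, turning the
likelihood into a weighted Poisson GLM, which is fitted with statsmodels.

Second-order diagnostics (Ripley's K with CSR simulation envelopes),
nearest-neighbor distances in projected-Euclidean and great-circle
metrics, kernel relative-density maps, and the within-eye permutation
test for tumor repulsion live here as well.

Fitting is done in the flat projection (Euclidean geometry); the
great-circle metric is available for the distance analyses, where the
planar metric is an upper bound on the true retinal distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage

from . import geometry
from .geometry import CapWindow

__all__ = [
    "PointPattern",
    "PoissonIntensityModel",
    "PoissonIntensityResults",
    "MarkedIntensityResults",
    "KResult",
    "PermutationResult",
    "simulate_poisson",
    "simulate_csr",
    "k_function",
    "csr_envelope",
    "nn_distances",
    "within_eye_permutation_test",
    "relative_density_map",
]


# ---------------------------------------------------------------------------
# pattern container
# ---------------------------------------------------------------------------

@dataclass
class PointPattern:
    """A marked point pattern in the projected retinal window.

    ``x``/``y`` are projected coordinates in degrees; ``marks`` is an
    optional DataFrame aligned with the points (columns typically
    ``mutation``, ``age_quartile``, ``area_quartile``, ``eye_id``).
    """

    x: np.ndarray
    y: np.ndarray
    marks: pd.DataFrame | None = None
    window: CapWindow = field(default_factory=CapWindow)

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if len(self.x) != len(self.y):
            raise ValueError("x and y differ in length")
        r = np.hypot(self.x, self.y)
        if np.any(r > self.window.radius + 1e-6):
            raise ValueError("points outside the window")
        if self.marks is not None and len(self.marks) != len(self.x):
            raise ValueError("marks must align with points")

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def from_cohort(cls, cohort, window: CapWindow | None = None) -> "PointPattern":
        """Centroid pattern of a cohort's tumors (must have metrics filled)."""
        window = window or CapWindow()
        ecc = np.array([t.centroid.eccentricity for t in cohort.tumors])
        ang = np.array([t.centroid.polar_angle for t in cohort.tumors])
        x, y = geometry.project(ecc, ang)
        marks = pd.DataFrame(
            {
                "mutation": [t.mutation for t in cohort.tumors],
                "age_quartile": [t.age_quartile for t in cohort.tumors],
                "area_quartile": [t.area_quartile for t in cohort.tumors],
                "eye_id": [t.eye_id for t in cohort.tumors],
            }
        )
        return cls(x, y, marks, window)

    def subset(self, mask) -> "PointPattern":
        mask = np.asarray(mask)
        marks = self.marks.loc[mask].reset_index(drop=True) if self.marks is not None else None
        return PointPattern(self.x[mask], self.y[mask], marks, self.window)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"x_deg": self.x, "y_deg": self.y})
        if self.marks is not None:
            out = pd.concat([out, self.marks.reset_index(drop=True)], axis=1)
        return out


def _poly_design(x, y, degree: int) -> np.ndarray:
    """Monomial design matrix x^i y^j for i + j <= degree."""
    cols = [np.ones_like(np.asarray(x, dtype=float))]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for total in range(1, degree + 1):
        for j in range(total + 1):
            cols.append(x ** (total - j) * y**j)
    return np.column_stack(cols)


def poly_term_names(degree: int) -> list[str]:
    names = ["1"]
    for total in range(1, degree + 1):
        for j in range(total + 1):
            i = total - j
            term = ""
            if i:
                term += f"x^{i}" if i > 1 else "x"
            if j:
                term += f"y^{j}" if j > 1 else "y"
            names.append(term)
    return names


# ---------------------------------------------------------------------------
# Berman-Turner quadrature
# ---------------------------------------------------------------------------

def _quadrature(pattern: PointPattern, n_grid: int = 32, subsample: int = 8):
    """Berman-Turner quadrature scheme on a clipped dummy grid.

    The window is covered by an ``n_grid`` x ``n_grid`` grid of cells; each
    cell intersecting the window contributes one dummy point at the
    centroid of its in-window part (estimated on a ``subsample`` x
    ``subsample`` sub-grid).  Cell areas are the clipped planar areas,
    normalized so they sum exactly to the window area.  Each data or dummy
    point receives weight cell_area / (points in cell), so the weights sum
    exactly to |W| and the weighted Poisson GLM reproduces the process
    likelihood.

    Returns (qx, qy, weights, is_data).
    """
    win = pattern.window
    R = win.radius
    edges = np.linspace(-R, R, n_grid + 1)
    cell = edges[1] - edges[0]
    sub = (np.arange(subsample) + 0.5) / subsample * cell
    sx, sy = np.meshgrid(sub, sub)
    sx = sx.ravel()
    sy = sy.ravel()

    dummy_x, dummy_y, areas, cell_idx = [], [], [], []
    for i in range(n_grid):
        for j in range(n_grid):
            px = edges[i] + sx
            py = edges[j] + sy
            inside = np.hypot(px, py) <= R
            k = int(inside.sum())
            if k == 0:
                continue
            dummy_x.append(px[inside].mean())
            dummy_y.append(py[inside].mean())
            areas.append(cell**2 * k / len(sx))
            cell_idx.append((i, j))
    areas = np.asarray(areas)
    areas *= win.planar_area / areas.sum()
    cell_map = {ij: k for k, ij in enumerate(cell_idx)}

    qx = np.concatenate([pattern.x, np.asarray(dummy_x)])
    qy = np.concatenate([pattern.y, np.asarray(dummy_y)])
    is_data = np.zeros(len(qx), dtype=bool)
    is_data[: len(pattern)] = True

    ci = np.clip(np.searchsorted(edges, qx, side="right") - 1, 0, n_grid - 1)
    cj = np.clip(np.searchsorted(edges, qy, side="right") - 1, 0, n_grid - 1)
    bins = np.array([cell_map[(a, b)] for a, b in zip(ci, cj)])
    counts = np.bincount(bins, minlength=len(areas))
    w = areas[bins] / counts[bins]
    return qx, qy, w, is_data


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PoissonIntensityModel:
    """Inhomogeneous Poisson process with polynomial log intensity.

    Parameters
    ----------
    pattern : PointPattern
        Observed points in the window.
    degree : int
        Polynomial degree of the log intensity (0 = homogeneous).
    mark : str, optional
        Name of a mark column; when given, :meth:`fit` fits an independent
        intensity per mark level (valid for Poisson processes, where the
        marked process splits into independent unmarked processes).
    n_quad : int
        Dummy-grid resolution per axis for the Berman-Turner quadrature.
    """

    def __init__(
        self,
        pattern: PointPattern,
        degree: int = 2,
        mark: str | None = None,
        n_quad: int = 32,
    ) -> None:
        if degree < 0:
            raise ValueError("degree must be nonnegative")
        n_coef = (degree + 1) * (degree + 2) // 2
        if len(pattern) < n_coef:
            raise ValueError(
                f"need at least {n_coef} points to fit degree {degree}"
            )
        if mark is not None and (pattern.marks is None or mark not in pattern.marks):
            raise ValueError(f"mark column {mark!r} not present")
        self.pattern = pattern
        self.degree = degree
        self.mark = mark
        self.n_quad = n_quad

    @classmethod
    def from_cohort(cls, cohort, degree: int = 2, mark: str | None = None, **kw):
        return cls(PointPattern.from_cohort(cohort), degree=degree, mark=mark, **kw)

    def _fit_single(self, pattern: PointPattern) -> "PoissonIntensityResults":
        qx, qy, w, is_data = _quadrature(pattern, self.n_quad)
        X = _poly_design(qx, qy, self.degree)
        y = is_data.astype(float) / w
        glm = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
        res = glm.fit()
        if not res.converged:
            raise RuntimeError(
                "intensity fit did not converge; see GLM history: "
                f"{getattr(res, 'fit_history', None)}"
            )
        coefs = np.asarray(res.params)
        # process log-likelihood: sum over data of log lambda minus the
        # quadrature approximation of the intensity integral
        eta = X @ coefs
        loglik = float(eta[is_data].sum() - np.sum(w * np.exp(eta)))
        return PoissonIntensityResults(
            model=self,
            pattern=pattern,
            coefficients=coefs,
            bse=np.asarray(res.bse),
            loglik=loglik,
            glm_results=res,
        )

    def fit(self):
        """Fit the model; returns results (per mark level when marked)."""
        if self.mark is None:
            return self._fit_single(self.pattern)
        levels = {}
        values = self.pattern.marks[self.mark]
        for level in pd.unique(values):
            sub = self.pattern.subset(np.asarray(values == level))
            levels[level] = self._fit_single(sub)
        return MarkedIntensityResults(model=self, levels=levels)


@dataclass
class PoissonIntensityResults:
    """Fitted polynomial Poisson intensity.

    ``coefficients`` follow the monomial ordering of
    :func:`poly_term_names`; ``loglik`` is the point-process
    log-likelihood (quadrature approximation of the intensity integral).
    """

    model: PoissonIntensityModel
    pattern: PointPattern
    coefficients: np.ndarray
    bse: np.ndarray
    loglik: float
    glm_results: object | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.coefficients)

    def intensity(self, x, y):
        """Fitted intensity lambda(x, y), points per square degree."""
        X = _poly_design(np.asarray(x, float).ravel(), np.asarray(y, float).ravel(), self.model.degree)
        lam = np.exp(X @ self.coefficients)
        return lam.reshape(np.shape(x))

    def intensity_grid(self, n: int = 121):
        """Intensity on a square grid over the window (NaN outside)."""
        R = self.pattern.window.radius
        c = np.linspace(-R, R, n)
        gx, gy = np.meshgrid(c, c[::-1])
        lam = self.intensity(gx, gy)
        lam[np.hypot(gx, gy) > R] = np.nan
        return gx, gy, lam

    def expected_count(self, n_grid: int = 256) -> float:
        """Quadrature estimate of the intensity integral over the window."""
        R = self.pattern.window.radius
        c = (np.arange(n_grid) + 0.5) / n_grid * 2 * R - R
        gx, gy = np.meshgrid(c, c)
        inside = np.hypot(gx, gy) <= R
        pix = (2 * R / n_grid) ** 2
        return float(self.intensity(gx[inside], gy[inside]).sum() * pix)

    def simulate(self, seed: int | None = None) -> PointPattern:
        return simulate_poisson(self, self.pattern.window, seed=seed)

    def summary(self) -> str:
        names = poly_term_names(self.model.degree)
        lines = [
            "Inhomogeneous Poisson intensity (log-polynomial)",
            f"  n points: {len(self.pattern)}   degree: {self.model.degree}",
            f"  log-likelihood: {self.loglik:.3f}   AIC: {self.aic:.3f}",
            f"  {'term':>8} {'coef':>12} {'se':>10}",
        ]
        for name, c, s in zip(names, self.coefficients, self.bse):
            lines.append(f"  {name:>8} {c:12.6f} {s:10.6f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "degree": self.model.degree,
            "terms": poly_term_names(self.model.degree),
            "coefficients": [float(c) for c in self.coefficients],
            "bse": [float(s) for s in self.bse],
            "loglik": self.loglik,
            "aic": self.aic,
            "n": len(self.pattern),
        }


@dataclass
class MarkedIntensityResults:
    """Per-mark-level intensity fits (independent Poisson components)."""

    model: PoissonIntensityModel
    levels: dict

    @property
    def loglik(self) -> float:
        return float(sum(r.loglik for r in self.levels.values()))

    @property
    def aic(self) -> float:
        return float(sum(r.aic for r in self.levels.values()))

    def summary(self) -> str:
        parts = [
            f"Marked Poisson intensity by {self.model.mark!r}: "
            f"total loglik {self.loglik:.3f}, AIC {self.aic:.3f}"
        ]
        for level in sorted(self.levels, key=str):
            parts.append(f"-- level {level} --")
            parts.append(self.levels[level].summary())
        return "\n".join(parts)

    def to_dict(self) -> dict:
        return {
            "mark": self.model.mark,
            "loglik": self.loglik,
            "aic": self.aic,
            "levels": {str(k): v.to_dict() for k, v in self.levels.items()},
        }


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_csr(n: int, window: CapWindow | None = None, seed=None) -> PointPattern:
    """Exactly n points uniform on the window (binomial/conditional CSR)."""
    window = window or CapWindow()
    rng = np.random.default_rng(seed)
    R = window.radius
    r = R * np.sqrt(rng.uniform(size=n))
    t = rng.uniform(0, 2 * np.pi, size=n)
    return PointPattern(r * np.cos(t), r * np.sin(t), window=window)


def simulate_poisson(
    intensity,
    window: CapWindow | None = None,
    seed=None,
    lam_max: float | None = None,
) -> PointPattern:
    """Simulate an inhomogeneous Poisson process by thinning.

    ``intensity`` is fitted results (anything with ``.intensity(x, y)``) or
    a callable ``f(x, y) -> rate per square degree``.  A homogeneous
    proposal at the grid-checked maximum rate is thinned; reproducible for
    a given seed.
    """
    window = window or (intensity.pattern.window if hasattr(intensity, "pattern") else CapWindow())
    fn = intensity.intensity if hasattr(intensity, "intensity") else intensity
    rng = np.random.default_rng(seed)
    R = window.radius
    if lam_max is None:
        c = np.linspace(-R, R, 201)
        gx, gy = np.meshgrid(c, c)
        inside = np.hypot(gx, gy) <= R
        vals = np.asarray(fn(gx[inside], gy[inside]), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensity is unbounded or overflows on the window")
        lam_max = float(vals.max()) * 1.05
    if lam_max <= 0:
        return PointPattern(np.empty(0), np.empty(0), window=window)
    n_prop = rng.poisson(lam_max * window.planar_area)
    r = R * np.sqrt(rng.uniform(size=n_prop))
    t = rng.uniform(0, 2 * np.pi, size=n_prop)
    px, py = r * np.cos(t), r * np.sin(t)
    lam = np.asarray(fn(px, py), dtype=float)
    if np.any(lam > lam_max * (1 + 1e-9)):
        raise ValueError("intensity exceeds its grid-checked bound")
    keep = rng.uniform(size=n_prop) < lam / lam_max
    return PointPattern(px[keep], py[keep], window=window)


# ---------------------------------------------------------------------------
# second-order statistics
# ---------------------------------------------------------------------------

@dataclass
class KResult:
    """Ripley's K estimate with its CSR reference (and optional envelope)."""

    r: np.ndarray
    k: np.ndarray
    theoretical: np.ndarray
    correction: str
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None


def _pairwise_euclidean(x, y):
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    return np.hypot(dx, dy)


def _disc_overlap_area(d, R):
    """Area of intersection of two discs of radius R at center distance d."""
    d = np.minimum(np.asarray(d, dtype=float), 2 * R)
    return 2 * R**2 * np.arccos(np.clip(d / (2 * R), -1, 1)) - 0.5 * d * np.sqrt(
        np.maximum(4 * R**2 - d**2, 0.0)
    )


def k_function(
    pattern: PointPattern,
    r_grid=None,
    correction: str = "translation",
) -> KResult:
    """Ripley's K function of a pattern in the circular window.

    K_hat(r) = |W| / (n (n-1)) * sum_{i != j} e_ij 1[d_ij <= r], with
    translation edge-correction weights e_ij = |W| / |W intersect W+t_ij|
    for a disc window, or e_ij = 1 (``none``).  The CSR reference pi r^2
    is attached.
    """
    n = len(pattern)
    if n < 2:
        raise ValueError("K function needs at least 2 points")
    win = pattern.window
    if r_grid is None:
        r_grid = np.linspace(0.0, win.radius / 2.0, 101)
    r_grid = np.asarray(r_grid, dtype=float)
    d = _pairwise_euclidean(pattern.x, pattern.y)
    iu = ~np.eye(n, dtype=bool)
    dij = d[iu]
    if correction == "translation":
        w = win.planar_area / _disc_overlap_area(dij, win.radius)
    elif correction == "none":
        w = np.ones_like(dij)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    order = np.argsort(dij)
    csum = np.concatenate([[0.0], np.cumsum(w[order])])
    idx = np.searchsorted(dij[order], r_grid, side="right")
    k = win.planar_area / (n * (n - 1)) * csum[idx]
    return KResult(r_grid, k, np.pi * r_grid**2, correction)


def csr_envelope(
    pattern: PointPattern,
    statistic=None,
    n_sim: int = 99,
    seed=None,
    rank: int = 1,
    r_grid=None,
):
    """Pointwise CSR envelope of a summary statistic.

    Simulates ``n_sim`` CSR patterns with the observed n in the observed
    window, evaluates the statistic (default: translation-corrected K) on
    each, and returns the rank-``rank`` lower/upper pointwise envelopes
    (rank 1 = min/max).  Returns ``(r, lo, hi, sims)``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if not 1 <= rank <= (n_sim + 1) // 2:
        raise ValueError("rank out of range")
    win = pattern.window
    if r_grid is None:
        r_grid = np.linspace(0.0, win.radius / 2.0, 101)
    if statistic is None:
        statistic = lambda p: k_function(p, r_grid).k  # noqa: E731
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, len(np.atleast_1d(statistic(pattern)))))
    for s in range(n_sim):
        sims[s] = statistic(simulate_csr(len(pattern), win, seed=rng.integers(2**31)))
    srt = np.sort(sims, axis=0)
    return np.asarray(r_grid), srt[rank - 1], srt[n_sim - rank], sims


def nn_distances(pattern: PointPattern, metric: str = "projected_euclidean"):
    """Nearest-neighbor distance of every point, degrees.

    ``projected_euclidean`` measures in the flat projection;
    ``great_circle`` measures on the retinal sphere.  The great-circle
    value never exceeds the projected one for the same pair.
    """
    n = len(pattern)
    if n < 2:
        raise ValueError("nearest-neighbor distances need at least 2 points")
    if metric == "projected_euclidean":
        d = _pairwise_euclidean(pattern.x, pattern.y)
    elif metric == "great_circle":
        ecc, ang = geometry.unproject(pattern.x, pattern.y)
        u = geometry.to_unit_vectors(ecc, ang)
        d = np.degrees(np.arccos(np.clip(u @ u.T, -1.0, 1.0)))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


# ---------------------------------------------------------------------------
# within-eye permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_permutations: int
    seed: object
    alternative: str

    def summary(self) -> str:
        return (
            f"within-eye NN permutation test: observed {self.observed:.3f} deg, "
            f"null mean {self.null.mean():.3f} deg, "
            f"p = {self.p_value:.4g} ({self.alternative}, B={self.n_permutations})"
        )


def _group_nn_mean(dist, groups):
    """Mean within-group NN distance over all points in groups (>=2 each)."""
    vals = []
    for g in groups:
        sub = dist[np.ix_(g, g)].copy()
        np.fill_diagonal(sub, np.inf)
        vals.append(sub.min(axis=1))
    return float(np.concatenate(vals).mean())


def within_eye_permutation_test(
    cohort,
    B: int = 999,
    seed=None,
    alternative: str = "greater",
    replace: bool = False,
) -> PermutationResult:
    """Test whether tumors within an eye repel each other.

    The observed statistic is the mean great-circle nearest-neighbor
    distance among tumors within the same eye, over all eyes with two or
    more tumors.  Null draws resample groups of the same sizes from the
    full set of tumor centroids (without replacement within a draw by
    default), matching the observed multiplet-size multiset; the one-sided
    p-value for repulsion (observed greater than null) is
    ``(1 + #{null >= obs}) / (1 + B)``.

    ``cohort`` may be a Cohort (centroids must be computed) or a
    PointPattern with an ``eye_id`` mark.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if isinstance(cohort, PointPattern):
        pattern = cohort
        if pattern.marks is None or "eye_id" not in pattern.marks:
            raise ValueError("pattern needs an eye_id mark")
        eye_ids = pattern.marks["eye_id"].to_numpy()
    else:
        pattern = PointPattern.from_cohort(cohort)
        eye_ids = pattern.marks["eye_id"].to_numpy()
    n = len(pattern)
    groups = {}
    for i, e in enumerate(eye_ids):
        groups.setdefault(e, []).append(i)
    multiplets = [np.array(v) for v in groups.values() if len(v) >= 2]
    if not multiplets:
        raise ValueError("no eye has two or more tumors")
    sizes = [len(g) for g in multiplets]

    ecc, ang = geometry.unproject(pattern.x, pattern.y)
    u = geometry.to_unit_vectors(ecc, ang)
    dist = np.degrees(np.arccos(np.clip(u @ u.T, -1.0, 1.0)))

    observed = _group_nn_mean(dist, multiplets)
    rng = np.random.default_rng(seed)
    total = sum(sizes)
    null = np.empty(B)
    for b in range(B):
        if replace:
            pick = rng.integers(0, n, size=total)
        else:
            pick = rng.choice(n, size=total, replace=False)
        out, groups_b = 0, []
        for s in sizes:
            groups_b.append(pick[out : out + s])
            out += s
        null[b] = _group_nn_mean(dist, groups_b)
    if alternative == "greater":
        p = (1 + np.sum(null >= observed)) / (1 + B)
    elif alternative == "less":
        p = (1 + np.sum(null <= observed)) / (1 + B)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PermutationResult(observed, null, float(p), B, seed, alternative)


# ---------------------------------------------------------------------------
# relative-density maps
# ---------------------------------------------------------------------------

def relative_density_map(
    pattern: PointPattern,
    n_grid: int = 241,
    bandwidth: float = 10.0,
):
    """Kernel intensity relative to the CSR expectation.

    Gaussian kernel estimate of the intensity in the projection with the
    uniform (convolution) edge correction, divided by the CSR intensity
    n / |W|; values above 1 mark excess density.  Returns
    ``(x, y, ratio)`` grids with NaN outside the window.
    """
    if len(pattern) < 1:
        raise ValueError("need at least one point")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    R = pattern.window.radius
    edges = np.linspace(-R, R, n_grid + 1)
    pitch = edges[1] - edges[0]
    counts, _, _ = np.histogram2d(pattern.x, pattern.y, bins=[edges, edges])
    sigma_pix = bandwidth / pitch
    raw = ndimage.gaussian_filter(counts, sigma_pix, mode="constant") / pitch**2
    centers = 0.5 * (edges[:-1] + edges[1:])
    gx, gy = np.meshgrid(centers, centers, indexing="ij")
    inside = np.hypot(gx, gy) <= R
    edge = ndimage.gaussian_filter(inside.astype(float), sigma_pix, mode="constant")
    lam = np.full_like(raw, np.nan)
    ok = inside & (edge > 1e-12)
    lam[ok] = raw[ok] / edge[ok]
    ratio = lam / (len(pattern) / pattern.window.planar_area)
    # return with x varying along columns, y along rows (map orientation)
    return gx.T[::-1], gy.T[::-1], ratio.T[::-1]
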