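"""Seeded synthetic retinoblastoma cohorts.

Generates cohorts with the statistical structure the mapping analysis
assumes, so every pipeline stage can be exercised without patient data:

* ~67 patients with ~58% bilateral disease, all bilateral patients
  carrying germline RB1 mutations;
* ages at diagnosis log-normal per mutation type (germline median 7.9
  months, somatic 21.6 months, clipped to plausible ranges), so germline
  patients are younger;
* tumor centroids drawn from age-quartile-specific mixtures of Gaussian
  kernels in the projection (macula + superonasal periphery for the
  youngest quartile, inferotemporal posterior pole, inferonasal quadrant,
  then nasal + superotemporal periphery), giving the central-to-peripheral
  progression with age;
* tumor areas decreasing with eccentricity and age quartile, constrained
  so each tumor fits inside the 60-degree window;
* germline eyes carrying extra tumors (within-eye multiplets) with a
  minimum-separation (repulsion) parameter;
* fundoscopy-only small tumors assigned to retinal sectors with an
  anterior bias and a superior-to-inferior shift across age quartiles.

The kernel centers and effect sizes are plausible stand-ins chosen to
reproduce the qualitative structure; they are configuration, not fitted
values.  All randomness flows from one seed through named substreams, so
equal seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .geometry import CapWindow, RetinalPoint
from .stats import quartile_split
from .tumors import (
    GERMLINE,
    SOMATIC,
    Cohort,
    SectorRecord,
    TumorPerimeter,
    TumorRecord,
    compute_tumor_metrics,
)

__all__ = ["CohortConfig", "generate_cohort", "generate_tumor_perimeter", "summarize_cohort"]


class InfeasiblePlacementError(ValueError):
    """A tumor of the requested area cannot sit at the requested centroid."""


#: default per-age-quartile centroid intensity kernels in projected degrees:
#: (x, y, sd, weight); weights need not sum to 1 -- the remainder is a
#: uniform background over the window.
DEFAULT_KERNELS: dict[int, tuple] = {
    1: ((0.0, 0.0, 8.0, 0.55), (32.0, 32.0, 10.0, 0.25)),       # macula + superonasal periphery
    2: ((-12.0, -12.0, 8.0, 0.80),),                            # inferotemporal posterior pole
    3: ((15.0, -15.0, 10.0, 0.80),),                            # inferonasal quadrant
    4: ((45.0, 0.0, 12.0, 0.40), (-30.0, 30.0, 12.0, 0.30)),    # nasal + superotemporal periphery
}


@dataclass
class CohortConfig:
    """Generator settings; defaults emulate the mapped-cohort structure."""

    n_patients: int = 67
    bilateral_fraction: float = 39 / 67
    germline_fraction: float = 43 / 67
    # age-at-diagnosis model, months (log-normal per mutation type)
    germline_age_median: float = 7.9
    germline_age_sigma: float = 0.9
    germline_age_range: tuple = (0.4, 108.3)
    somatic_age_median: float = 21.6
    somatic_age_sigma: float = 0.7
    somatic_age_range: tuple = (1.4, 77.5)
    # eyes and multiplicity
    eye_mapping_rate: float = 91 / 106
    extra_tumor_rate: float = 0.54  # Poisson extra tumors per germline eye
    min_separation: float = 20.0  # within-eye repulsion, great-circle degrees
    # centroid intensity
    kernels: dict = field(default_factory=lambda: dict(DEFAULT_KERNELS))
    max_centroid_eccentricity_sampled: float = 56.0
    # tumor area model (fractions of the window area)
    area_median_by_quartile: tuple = (0.050, 0.035, 0.020, 0.010)
    area_sigma: float = 0.7
    area_eccentricity_scale: float = 60.0  # median shrinks as exp(-ecc/scale)
    min_area_fraction: float = 0.0015
    detection_area_cutoff: float | None = None  # drop tumors below this area
    perimeter_vertices: int = 32
    irregularity: float = 0.25
    # fundoscopy-only small tumors (per bilateral patient)
    small_tumor_rate: float = 50 / 39
    small_anterior_prob: float = 0.84
    small_meridian_prob: float = 0.18
    small_macula_prob: float = 0.04
    small_nasal_prob: float = 0.6
    small_superior_prob_by_quartile: tuple = (0.65, 0.55, 0.40, 0.30)
    icrb_probs: tuple = (3 / 91, 29 / 91, 18 / 91, 32 / 91, 9 / 91)
    window: CapWindow = field(default_factory=CapWindow)
    seed: int = 0

    def validate(self) -> None:
        for name in ("bilateral_fraction", "germline_fraction", "eye_mapping_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bilateral_fraction > self.germline_fraction:
            raise ValueError("bilateral patients are all germline; fraction too large")
        max_a = float(
            geometry.max_centroid_eccentricity(1.0, "exact", self.window)
        )  # = 0; sanity only
        del max_a
        feasible = geometry.max_centroid_eccentricity(
            max(self.area_median_by_quartile), "exact", self.window
        )
        if self.max_centroid_eccentricity_sampled >= self.window.radius:
            raise ValueError("sampled centroids must stay inside the window")
        if feasible <= 0:
            raise ValueError("median tumor area too large for any allowed centroid")


# ---------------------------------------------------------------------------
# tumor boundary generator
# ---------------------------------------------------------------------------

def generate_tumor_perimeter(
    centroid: RetinalPoint,
    area_fraction: float,
    irregularity: float = 0.25,
    seed=None,
    n_vertices: int = 32,
    window: CapWindow | None = None,
) -> TumorPerimeter:
    """Closed star-shaped boundary around a centroid with a target area.

    The boundary is a circular cap whose angular radius is modulated by a
    smooth random low-order Fourier perturbation of relative amplitude
    ``irregularity`` (0 gives an exact circular cap).  Radii are rescaled
    so the realized spherical area is within ~1% of the request (the
    generator contract is 5%); the boundary never leaves the window.
    """
    window = window or CapWindow()
    if not 0 < area_fraction <= 1:
        raise InfeasiblePlacementError("area_fraction must lie in (0, 1]")
    max_ecc = float(geometry.max_centroid_eccentricity(area_fraction, "exact", window))
    if centroid.eccentricity > max_ecc + 1e-9:
        raise InfeasiblePlacementError(
            f"tumor of area {area_fraction:.4f} cannot fit at eccentricity "
            f"{centroid.eccentricity:.2f} (max {max_ecc:.2f})"
        )
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    if irregularity > 0:
        order = 4
        amp = rng.normal(size=order) / np.arange(1, order + 1)
        phase = rng.uniform(0, 2 * np.pi, order)
        g = np.zeros_like(t)
        for m in range(order):
            g += amp[m] * np.cos((m + 1) * t + phase[m])
        peak = np.abs(g).max()
        if peak > 0:
            g *= irregularity / peak
    else:
        g = np.zeros_like(t)
    # base cap radius for the requested spherical area
    cos_rho = 1.0 - area_fraction * (1.0 - np.cos(np.radians(window.radius)))
    rho0 = np.degrees(np.arccos(np.clip(cos_rho, -1.0, 1.0)))
    rho_cap = window.radius - centroid.eccentricity
    radii = np.minimum(rho0 * (1.0 + g), rho_cap)

    target_solid = area_fraction * window.solid_angle
    boundary = None
    for _ in range(6):
        boundary = _star_boundary(centroid, radii, t)
        solid, _ = geometry.spherical_region_area(
            boundary[0], boundary[1], window, check_simple=False
        )
        ratio = target_solid / solid
        if abs(ratio - 1.0) < 0.01:
            break
        radii = np.minimum(radii * np.sqrt(ratio), rho_cap)
    return TumorPerimeter(boundary[0], boundary[1])


def _star_boundary(centroid: RetinalPoint, radii_deg, t):
    c = geometry.to_unit_vectors(centroid.eccentricity, centroid.polar_angle)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(c @ ref)) > 0.999999:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(c, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(c, e1)
    r = np.radians(radii_deg)
    pts = (
        np.cos(r)[:, None] * c[None, :]
        + np.sin(r)[:, None]
        * (np.cos(t)[:, None] * e1[None, :] + np.sin(t)[:, None] * e2[None, :])
    )
    return geometry.from_unit_vectors(pts)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def _sample_ages(rng, n, median, sigma, rng_clip):
    a = np.exp(rng.normal(np.log(median), sigma, size=n))
    return np.clip(a, *rng_clip)


def _sample_centroid(rng, kernels, max_ecc, window):
    """One centroid from the quartile's kernel mixture (+uniform background)."""
    weights = np.array([k[3] for k in kernels])
    bg = max(0.0, 1.0 - weights.sum())
    probs = np.append(weights, bg)
    probs = probs / probs.sum()
    for _ in range(10_000):
        comp = rng.choice(len(probs), p=probs)
        if comp == len(kernels):  # uniform background on the spherical cap
            zmin = np.cos(np.radians(max_ecc))
            z = rng.uniform(zmin, 1.0)
            ecc = np.degrees(np.arccos(z))
            ang = rng.uniform(0.0, 360.0)
            return RetinalPoint(float(ecc), float(ang))
        cx, cy, sd, _ = kernels[comp]
        x, y = rng.normal(cx, sd), rng.normal(cy, sd)
        if np.hypot(x, y) <= max_ecc:
            ecc, ang = geometry.unproject(x, y)
            return RetinalPoint(float(ecc), float(ang))
    raise RuntimeError("centroid sampling failed; kernels far outside window?")


def _sample_area(rng, cfg: CohortConfig, quartile: int, ecc: float) -> float:
    med = cfg.area_median_by_quartile[quartile - 1] * np.exp(
        -ecc / cfg.area_eccentricity_scale
    )
    a = float(np.exp(rng.normal(np.log(med), cfg.area_sigma)))
    # keep the tumor inside the window with room for boundary irregularity
    rho_max = 0.9 * (cfg.window.radius - ecc)
    a_max = (1.0 - np.cos(np.radians(rho_max))) / (
        1.0 - np.cos(np.radians(cfg.window.radius))
    )
    return float(np.clip(a, cfg.min_area_fraction, a_max))


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort (tumors, sector records, patients).

    Reproducible for a given seed (``seed`` overrides ``config.seed``).
    Every tumor carries marks, a perimeter, and derived metrics consistent
    with that perimeter; bilateral patients are always germline.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_pat, rng_loc, rng_area, rng_perim, rng_small = (
        np.random.default_rng(s) for s in streams
    )

    n = cfg.n_patients
    n_bilateral = int(round(cfg.bilateral_fraction * n))
    n_germline = max(int(round(cfg.germline_fraction * n)), n_bilateral)
    mutation = np.array([GERMLINE] * n_germline + [SOMATIC] * (n - n_germline))
    bilateral = np.zeros(n, dtype=bool)
    bilateral[:n_bilateral] = True  # bilateral disease implies germline
    perm = rng_pat.permutation(n)
    mutation, bilateral = mutation[perm], bilateral[perm]

    ages = np.empty(n)
    gm = mutation == GERMLINE
    ages[gm] = _sample_ages(
        rng_pat, gm.sum(), cfg.germline_age_median, cfg.germline_age_sigma, cfg.germline_age_range
    )
    ages[~gm] = _sample_ages(
        rng_pat, (~gm).sum(), cfg.somatic_age_median, cfg.somatic_age_sigma, cfg.somatic_age_range
    )
    qs = quartile_split(ages)
    age_quartile = qs.quartile

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "mutation": mutation,
            "bilateral": bilateral,
            "age_months": ages,
            "age_quartile": age_quartile,
        }
    )

    icrb_levels = np.array(["A", "B", "C", "D", "E"])
    tumors: list[TumorRecord] = []
    for i, row in patients.iterrows():
        sides = ["right", "left"] if row.bilateral else [
            "right" if rng_pat.uniform() < 0.5 else "left"
        ]
        # each eye mapped with the configured rate, but the patient stays in
        # the mapped cohort with at least one eye
        mapped = [rng_pat.uniform() < cfg.eye_mapping_rate for _ in sides]
        if not any(mapped):
            mapped[int(rng_pat.integers(len(sides)))] = True
        for side, is_mapped in zip(sides, mapped):
            if not is_mapped:
                continue
            eye_id = f"{row.patient_id}-{side[0].upper()}"
            k_tumors = 1 + (
                rng_pat.poisson(cfg.extra_tumor_rate) if row.mutation == GERMLINE else 0
            )
            icrb = str(rng_pat.choice(icrb_levels, p=cfg.icrb_probs))
            placed: list[RetinalPoint] = []
            for j in range(k_tumors):
                centroid = _place_with_repulsion(
                    rng_loc, cfg, int(row.age_quartile), placed
                )
                placed.append(centroid)
                area = _sample_area(rng_area, cfg, int(row.age_quartile), centroid.eccentricity)
                perim = generate_tumor_perimeter(
                    centroid,
                    area,
                    irregularity=cfg.irregularity,
                    seed=rng_perim,
                    n_vertices=cfg.perimeter_vertices,
                    window=cfg.window,
                )
                rec = TumorRecord(
                    patient_id=row.patient_id,
                    eye_id=eye_id,
                    tumor_id=f"{eye_id}-T{j}",
                    side=side,
                    mutation=row.mutation,
                    age_months=float(row.age_months),
                    icrb_group=icrb,
                    perimeter=_canonical_perimeter(perim, side),
                    age_quartile=int(row.age_quartile),
                )
                tumors.append(compute_tumor_metrics(rec, interpolation_step=0.5))

    if cfg.detection_area_cutoff is not None:
        tumors = [t for t in tumors if t.area_fraction >= cfg.detection_area_cutoff]

    if len(tumors) >= 4:
        areas = np.array([t.area_fraction for t in tumors])
        aq = quartile_split(areas).quartile
        for t, q in zip(tumors, aq):
            t.area_quartile = int(q)

    sectors = _generate_sectors(rng_small, cfg, patients)
    return Cohort(tumors=tumors, sectors=sectors, patients=patients, seed=seed)


def _canonical_perimeter(perim: TumorPerimeter, side: str) -> TumorPerimeter:
    """Perimeters are generated in canonical orientation already; for left
    eyes the record stores the canonicalized (right-eye aligned) vertices,
    which is the identity here -- placement happens post-pooling.  Kept as
    an explicit hook so file-based cohorts and synthetic cohorts share the
    same convention."""
    return perim


def _place_with_repulsion(rng, cfg: CohortConfig, quartile: int, placed) -> RetinalPoint:
    kernels = cfg.kernels[quartile]
    best, best_sep = None, -np.inf
    for _ in range(200):
        cand = _sample_centroid(
            rng, kernels, cfg.max_centroid_eccentricity_sampled, cfg.window
        )
        if not placed:
            return cand
        sep = min(
            float(
                geometry.great_circle_distance(
                    cand.eccentricity, cand.polar_angle, p.eccentricity, p.polar_angle
                )
            )
            for p in placed
        )
        if sep >= cfg.min_separation:
            return cand
        if sep > best_sep:
            best, best_sep = cand, sep
    return best  # fall back to the most separated candidate


def _generate_sectors(rng, cfg: CohortConfig, patients) -> list[SectorRecord]:
    records: list[SectorRecord] = []
    for _, row in patients.iterrows():
        if not row.bilateral:
            continue
        k = rng.poisson(cfg.small_tumor_rate)
        for j in range(k):
            depth = "anterior" if rng.uniform() < cfg.small_anterior_prob else "posterior"
            u = rng.uniform()
            if depth == "posterior" and u < cfg.small_macula_prob:
                vertical, horizontal = "macula", "macula"
            elif u < cfg.small_macula_prob + cfg.small_meridian_prob:
                vertical = "meridian"
                horizontal = "nasal" if rng.uniform() < cfg.small_nasal_prob else "temporal"
            else:
                p_sup = cfg.small_superior_prob_by_quartile[int(row.age_quartile) - 1]
                vertical = "superior" if rng.uniform() < p_sup else "inferior"
                horizontal = "nasal" if rng.uniform() < cfg.small_nasal_prob else "temporal"
            side = "right" if rng.uniform() < 0.5 else "left"
            records.append(
                SectorRecord(
                    patient_id=row.patient_id,
                    eye_id=f"{row.patient_id}-{side[0].upper()}",
                    vertical=vertical,
                    horizontal=horizontal,
                    depth=depth,
                    age_months=float(row.age_months),
                    age_quartile=int(row.age_quartile),
                )
            )
    return records


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def summarize_cohort(cohort: Cohort) -> dict:
    """Descriptive summary tables of a cohort (counts and percentages).

    Covers laterality, mutation type, age quartiles with their cut points,
    eye side, ICRB group, and tumor multiplicity -- the inputs the
    contingency-table statistics consume.
    """
    pats = cohort.patients
    out: dict = {}

    def counts_pct(series) -> pd.DataFrame:
        c = series.value_counts().sort_index()
        return pd.DataFrame({"count": c, "percent": 100.0 * c / c.sum()})

    out["n_patients"] = int(len(pats))
    out["n_eyes"] = len(cohort.eyes())
    out["n_tumors"] = len(cohort.tumors)
    out["n_small_tumors"] = len(cohort.sectors)
    out["laterality"] = counts_pct(
        pats.bilateral.map({True: "bilateral", False: "unilateral"})
    )
    out["mutation"] = counts_pct(pats.mutation)
    qs = quartile_split(pats.age_months.to_numpy())
    out["age_quartile_cuts"] = qs.cuts
    out["age_quartile"] = counts_pct(pd.Series(qs.quartile, name="age_quartile"))
    out["age_median_by_mutation"] = pats.groupby("mutation").age_months.median().to_dict()
    eye_rows = {}
    for t in cohort.tumors:
        eye_rows[t.eye_id] = {"side": t.side, "icrb_group": t.icrb_group}
    eyes = pd.DataFrame.from_dict(eye_rows, orient="index")
    out["eye_side"] = counts_pct(eyes.side)
    out["icrb_group"] = counts_pct(eyes.icrb_group.dropna())
    mult = pd.Series([len(v) for v in _tumors_by_eye(cohort).values()])
    out["tumors_per_eye"] = counts_pct(mult)
    return out


def _tumors_by_eye(cohort: Cohort) -> dict:
    by_eye: dict = {}
    for t in cohort.tumors:
        by_eye.setdefault(t.eye_id, []).append(t)
    return by_eye
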