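"""End-to-end analysis pipeline.

Runs the full tumor-mapping analysis on a cohort (loaded from files or
generated synthetically): per-tumor metrics, cumulative burden maps,
quartile splits, per-age-quartile polynomial Poisson intensity fits,
Ripley's K with CSR envelopes, nearest-neighbor comparisons in both
metrics, the within-eye permutation test, and the cohort summary tables.
Results are written as JSON plus figures and a plain-text log; every
numeric output is traceable to a stage and the run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio
from . import plots
from .geometry import CapWindow
from .pointprocess import (
    PointPattern,
    PoissonIntensityModel,
    csr_envelope,
    k_function,
    nn_distances,
    within_eye_permutation_test,
)
from .stats import fisher_exact, quartile_split, sector_tally, wilcoxon_rank_sum
from .synthetic import CohortConfig, generate_cohort
from .tumors import RasterGrid, compute_tumor_metrics, cumulative_burden

__all__ = ["RunConfig", "PipelineError", "pipeline_run"]

log = logging.getLogger("retmap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Settings of one pipeline run."""

    output_dir: str = "retmap_results"
    perimeter_csv: str | None = None  # when None, a synthetic cohort is used
    metadata_json: str | None = None
    window_radius: float = 60.0
    raster_pitch: float = 0.25
    model_degree: int = 2
    n_envelope: int = 99
    permutation_B: int = 999
    seed: int = 0
    render_figures: bool = True
    synthetic: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        # permutation_B is validated by the permutation stage itself
        for name in ("window_radius", "raster_pitch", "n_envelope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.model_degree < 0:
            raise ValueError("model_degree must be nonnegative")

    def content_hash(self) -> str:
        # the output location does not affect the analysis
        payload = {
            k: v for k, v in asdict(self).items() if k not in ("synthetic", "output_dir")
        }
        payload["synthetic"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self.synthetic).items()
            if not isinstance(v, (dict, CapWindow))
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def pipeline_run(config: RunConfig) -> dict:
    """Execute every analysis stage; returns (and writes) the result bundle.

    Any stage failure aborts with the stage name; partial outputs written
    so far are preserved in the output directory.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    window = CapWindow(radius=config.window_radius)
    results: dict = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "stages": {},
    }
    t_start = time.time()
    stage = "load"

    def _finish_stage(name: str, t0: float, **info) -> None:
        results["stages"][name] = {"wall_s": round(time.time() - t0, 3), **info}
        log.info("stage %-12s %6.2fs  %s", name, time.time() - t0, info)

    try:
        t0 = time.time()
        if config.perimeter_csv:
            cohort, report = rio.read_cohort(config.perimeter_csv, config.metadata_json, window)
            for line in report:
                log.warning("validation: %s", line)
            results["validation_report"] = report
        else:
            cfg = config.synthetic
            cohort = generate_cohort(cfg, seed=config.seed)
        _finish_stage("load", t0, n_tumors=len(cohort.tumors))

        stage = "metrics"
        t0 = time.time()
        cohort.tumors = [
            t if t.area_fraction is not None else compute_tumor_metrics(t)
            for t in cohort.tumors
        ]
        ages = np.array([t.age_months for t in cohort.tumors])
        areas = np.array([t.area_fraction for t in cohort.tumors])
        age_q = quartile_split(ages)
        area_q = quartile_split(areas)
        for t, qa, qr in zip(cohort.tumors, age_q.quartile, area_q.quartile):
            if t.age_quartile is None:
                t.age_quartile = int(qa)
            t.area_quartile = int(qr)
        results["tumor_metrics"] = {
            "n_tumors": len(cohort.tumors),
            "age_quartile_cuts_months": list(age_q.cuts),
            "area_quartile_cuts_fraction": list(area_q.cuts),
            "median_area_fraction": float(np.median(areas)),
            "median_eccentricity_by_age_quartile": {
                int(q): float(
                    np.median(
                        [t.centroid.eccentricity for t in cohort.tumors if t.age_quartile == q]
                    )
                )
                for q in (1, 2, 3, 4)
            },
        }
        _finish_stage("metrics", t0)

        stage = "burden"
        t0 = time.time()
        grid = RasterGrid(pitch=config.raster_pitch, window=window)
        burden = cumulative_burden(cohort.tumors, grid, mode="eye_count")
        rio.write_burden_matrix(burden, outdir / "burden_eye_count.txt")
        results["burden"] = {
            "max_eye_count": int(burden.values.max()),
            "n_eyes": len(cohort.eyes()),
        }
        if config.render_figures:
            plots.render_polar_map(outdir / "burden_map.png", burden=burden, window=window,
                                   title="cumulative tumor burden (eyes)")
        _finish_stage("burden", t0, max_count=int(burden.values.max()))

        stage = "intensity"
        t0 = time.time()
        pattern = PointPattern.from_cohort(cohort, window)
        fit_all = PoissonIntensityModel(pattern, degree=config.model_degree).fit()
        marked = PoissonIntensityModel(pattern, degree=config.model_degree, mark="age_quartile").fit()
        results["intensity"] = {"pooled": fit_all.to_dict(), "by_age_quartile": marked.to_dict()}
        (outdir / "intensity_model.json").write_text(
            json.dumps(results["intensity"], indent=1)
        )
        _finish_stage("intensity", t0, loglik=round(fit_all.loglik, 2))

        stage = "k_function"
        t0 = time.time()
        kr = k_function(pattern)
        rgrid, lo, hi, _ = csr_envelope(
            pattern, n_sim=config.n_envelope, seed=config.seed, r_grid=kr.r
        )
        above = kr.k > hi
        results["k_function"] = {
            "r_max": float(kr.r[-1]),
            "fraction_above_csr_envelope": float(above.mean()),
            "clustered": bool(above[1:].any()),
        }
        _finish_stage("k_function", t0, clustered=results["k_function"]["clustered"])

        stage = "nn_distances"
        t0 = time.time()
        nn_g = nn_distances(pattern, "great_circle")
        nn_e = nn_distances(pattern, "projected_euclidean")
        w_stat, w_p = wilcoxon_rank_sum(nn_e, nn_g)
        results["nn_distances"] = {
            "median_great_circle": float(np.median(nn_g)),
            "median_projected_euclidean": float(np.median(nn_e)),
            "all_gc_le_euclidean": bool(np.all(nn_g <= nn_e + 1e-9)),
            "wilcoxon_W": w_stat,
            "wilcoxon_p": w_p,
        }
        _finish_stage("nn_distances", t0)

        stage = "permutation"
        t0 = time.time()
        perm = within_eye_permutation_test(cohort, B=config.permutation_B, seed=config.seed)
        results["permutation"] = {
            "observed_mean_nn_deg": perm.observed,
            "null_mean_nn_deg": float(perm.null.mean()),
            "p_value": perm.p_value,
            "B": perm.n_permutations,
        }
        _finish_stage("permutation", t0, p=perm.p_value)

        stage = "tables"
        t0 = time.time()
        pats = cohort.patients
        tables: dict = {}
        if pats is not None:
            germ = pats[pats.mutation == "germline"].age_months
            som = pats[pats.mutation == "somatic"].age_months
            if len(germ) and len(som):
                w, p = wilcoxon_rank_sum(germ, som)
                tables["age_by_mutation"] = {
                    "median_germline": float(germ.median()),
                    "median_somatic": float(som.median()),
                    "wilcoxon_W": w,
                    "wilcoxon_p": p,
                }
            lat = pats.bilateral.astype(bool)
            gm = pats.mutation == "germline"
            table = [
                [int((lat & gm).sum()), int((lat & ~gm).sum())],
                [int((~lat & gm).sum()), int((~lat & ~gm).sum())],
            ]
            fr = fisher_exact(table)
            tables["laterality_by_mutation"] = {
                "table": table,
                "odds_ratio": fr.odds_ratio,
                "p": fr.p_value,
            }
        if cohort.sectors:
            tally, p_sect = sector_tally(cohort.sectors)
            tables["sector_tally"] = {
                "table": tally.to_dict(),
                "superior_inferior_p": p_sect,
                "n_small_tumors": len(cohort.sectors),
            }
        results["tables"] = tables
        _finish_stage("tables", t0)

        if config.render_figures:
            stage = "render"
            t0 = time.time()
            plots.render_polar_map(
                outdir / "centroids.png", centroids=pattern, window=window,
                title="tumor centroids",
            )
            _finish_stage("render", t0)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        (outdir / "results_partial.json").write_text(json.dumps(results, indent=1, default=str))
        raise PipelineError(stage, exc) from exc

    results["wall_s"] = round(time.time() - t_start, 3)
    (outdir / "results.json").write_text(json.dumps(results, indent=1, default=str))
    return results
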