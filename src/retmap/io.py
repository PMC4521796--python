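"""Reading and writing cohorts as perimeter CSV + metadata JSON.

The perimeter CSV has one row per tumor boundary vertex in the eye's
original orientation: ``patient_id, eye_id, tumor_id, vertex_index,
eccentricity_deg, polar_angle_deg``.  The metadata JSON carries per-tumor
marks, patient rows, and fundoscopy-only sector records.  Left eyes are
canonicalized (mirrored to right-eye orientation) on load; the original
side is retained on the record.  Angles are serialized in degrees with six
decimals, which round-trips the analyses at full working precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .tumors import Cohort, SectorRecord, TumorPerimeter, TumorRecord

__all__ = ["write_cohort", "read_cohort", "write_burden_matrix"]

PERIMETER_COLUMNS = [
    "patient_id",
    "eye_id",
    "tumor_id",
    "vertex_index",
    "eccentricity_deg",
    "polar_angle_deg",
]


def write_cohort(cohort: Cohort, perimeter_csv, metadata_json) -> None:
    """Write a cohort to the perimeter-CSV / metadata-JSON pair.

    Records store canonical (right-eye) coordinates internally; left-eye
    perimeters are mirrored back to their original orientation on disk.
    """
    rows = []
    meta_tumors = {}
    for t in cohort.tumors:
        ecc, ang = t.perimeter.eccentricity, t.perimeter.polar_angle
        # undo canonicalization for storage (involution, so reuse it)
        ecc_o, ang_o = geometry.canonicalize(ecc, ang, t.side)
        for i, (e, a) in enumerate(zip(ecc_o, ang_o)):
            rows.append((t.patient_id, t.eye_id, t.tumor_id, i, round(float(e), 6), round(float(a), 6)))
        meta_tumors[t.tumor_id] = {
            "patient_id": t.patient_id,
            "eye_id": t.eye_id,
            "side": t.side,
            "mutation": t.mutation,
            "age_months": float(t.age_months),
            "icrb_group": t.icrb_group,
        }
    pd.DataFrame(rows, columns=PERIMETER_COLUMNS).to_csv(perimeter_csv, index=False)
    meta = {
        "seed": cohort.seed,
        "tumors": meta_tumors,
        "patients": (
            cohort.patients.to_dict(orient="records") if cohort.patients is not None else None
        ),
        "sectors": [
            {
                "patient_id": s.patient_id,
                "eye_id": s.eye_id,
                "vertical": s.vertical,
                "horizontal": s.horizontal,
                "depth": s.depth,
                "age_months": float(s.age_months),
                "age_quartile": s.age_quartile,
            }
            for s in cohort.sectors
        ],
    }
    Path(metadata_json).write_text(json.dumps(meta, indent=1))


def read_cohort(perimeter_csv, metadata_json, window=None) -> tuple[Cohort, list[str]]:
    """Load a cohort; returns ``(cohort, validation_report)``.

    Vertices are grouped by tumor in vertex-index order; left eyes are
    canonicalized on load.  Per-record problems (out-of-window vertices,
    fewer than 3 vertices) are collected in the report and the offending
    tumors dropped, never silently.  Metadata referencing an absent tumor,
    or a tumor without metadata, is a referential-integrity error.
    """
    window = window or geometry.CapWindow()
    df = pd.read_csv(perimeter_csv)
    missing = set(PERIMETER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"perimeter CSV missing columns: {sorted(missing)}")
    meta = json.loads(Path(metadata_json).read_text())
    meta_tumors = meta.get("tumors", {})

    csv_ids = set(df.tumor_id.astype(str))
    meta_ids = set(meta_tumors)
    if csv_ids != meta_ids:
        raise ValueError(
            "referential integrity: tumor ids differ between CSV and metadata "
            f"(csv-only {sorted(csv_ids - meta_ids)[:5]}, "
            f"meta-only {sorted(meta_ids - csv_ids)[:5]})"
        )

    report: list[str] = []
    tumors: list[TumorRecord] = []
    for tid, grp in df.groupby("tumor_id", sort=False):
        grp = grp.sort_values("vertex_index")
        info = meta_tumors[str(tid)]
        ecc = grp.eccentricity_deg.to_numpy(dtype=float)
        ang = grp.polar_angle_deg.to_numpy(dtype=float)
        bad = (ecc < 0) | (ecc > window.radius + 1e-6)
        if bad.any():
            report.append(
                f"{tid}: {int(bad.sum())} vertex(es) outside the {window.radius:g} deg "
                "window; tumor dropped"
            )
            continue
        if len(np.unique(np.round(np.column_stack([ecc, ang]), 9), axis=0)) < 3:
            report.append(f"{tid}: fewer than 3 distinct vertices; tumor dropped")
            continue
        cecc, cang = geometry.canonicalize(ecc, ang, info["side"])
        tumors.append(
            TumorRecord(
                patient_id=info["patient_id"],
                eye_id=info["eye_id"],
                tumor_id=str(tid),
                side=info["side"],
                mutation=info["mutation"],
                age_months=float(info["age_months"]),
                icrb_group=info.get("icrb_group"),
                perimeter=TumorPerimeter(cecc, cang),
            )
        )
    sectors = [
        SectorRecord(
            patient_id=s["patient_id"],
            eye_id=s["eye_id"],
            vertical=s["vertical"],
            horizontal=s["horizontal"],
            depth=s["depth"],
            age_months=s["age_months"],
            age_quartile=s.get("age_quartile"),
        )
        for s in meta.get("sectors", [])
    ]
    patients = pd.DataFrame(meta["patients"]) if meta.get("patients") else None
    return Cohort(tumors=tumors, sectors=sectors, patients=patients, seed=meta.get("seed")), report


def write_burden_matrix(burden, path) -> None:
    """Plain-text matrix export of a burden map (NaN outside the window)."""
    np.savetxt(path, burden.as_masked(), fmt="%.6g")
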