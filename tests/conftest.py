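import numpy as np
import pytest

from retmap.geometry import CapWindow, RetinalPoint
from retmap.synthetic import CohortConfig, generate_cohort, generate_tumor_perimeter
from retmap.tumors import TumorRecord, compute_tumor_metrics


@pytest.fixture(scope="session")
def window():
    return CapWindow()


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_patients=30), seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort shared by read-only tests."""
    return generate_cohort(seed=5)


def make_cap_tumor(
    center: tuple,
    radius_deg: float,
    *,
    tumor_id: str = "T0",
    eye_id: str = "E0",
    patient_id: str = "P0",
    side: str = "right",
    mutation: str = "germline",
    age_months: float = 10.0,
    with_metrics: bool = True,
    n_vertices: int = 72,
) -> TumorRecord:
    """A circular-cap tumor record, optionally with derived metrics."""
    area = (1 - np.cos(np.radians(radius_deg))) / (1 - np.cos(np.radians(60)))
    perim = generate_tumor_perimeter(
        RetinalPoint(*center), area, irregularity=0.0, seed=0, n_vertices=n_vertices
    )
    rec = TumorRecord(
        patient_id=patient_id,
        eye_id=eye_id,
        tumor_id=tumor_id,
        side=side,
        mutation=mutation,
        age_months=age_months,
        perimeter=perim,
    )
    return compute_tumor_metrics(rec) if with_metrics else rec
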