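import numpy as np
import pandas as pd
import pytest

from specount.io import (
    CohortTable,
    ProteinAnnotationTable,
    SpectralCountMatrix,
)


@pytest.fixture
def tiny_matrix() -> SpectralCountMatrix:
    """3 proteins x 6 samples (3 paired PT/LT cases)."""
    samples = ["PT_01", "PT_02", "PT_03", "LT_01", "LT_02", "LT_03"]
    counts = pd.DataFrame(
        [
            [2, 0, 3, 5, 1, 4],   # shared
            [3, 1, 0, 0, 0, 2],   # the SpI worked example
            [0, 0, 0, 6, 2, 1],   # LT-only
        ],
        index=pd.Index(["P1", "P2", "P3"], name="accession"),
        columns=samples,
        dtype=np.int64,
    )
    groups = pd.Series(["PT"] * 3 + ["LT"] * 3, index=samples)
    cases = pd.Series(["c1", "c2", "c3"] * 2, index=samples)
    return SpectralCountMatrix(counts, groups, cases)


@pytest.fixture
def tiny_annotations() -> ProteinAnnotationTable:
    table = pd.DataFrame(
        {"length": [100, 400, 250], "symbol": ["S1", "S2", "S3"], "description": ""},
        index=pd.Index(["P1", "P2", "P3"], name="accession"),
    )
    return ProteinAnnotationTable(table)


def make_cohort(n_sync=8, n_meta=12, n_none=50, seed=0) -> CohortTable:
    """Cohort with the 8/12/50 metastasis-group structure, built row-wise."""
    rng = np.random.default_rng(seed)
    rows = []
    plan = [("synchronous", n_sync), ("metachronous", n_meta), ("none", n_none)]
    i = 0
    for group, n in plan:
        for _ in range(n):
            i += 1
            sync = group == "synchronous"
            event = 1 if group == "metachronous" else 0
            rfs = np.nan if sync else float(rng.uniform(6, 60) if event else rng.uniform(24, 200))
            marker_rate = {"synchronous": 0.875, "metachronous": 0.83, "none": 0.38}[group]
            rows.append(
                {
                    "patient_id": f"PX{i:04d}",
                    "group": group,
                    "gender": rng.choice(["male", "female"]),
                    "age": int(rng.integers(30, 80)),
                    "function_type": rng.choice(["NF", "insulinoma"], p=[0.75, 0.25]),
                    "who_grade": rng.choice(["G1", "G2", "G3"], p=[0.45, 0.45, 0.1]),
                    "ki67": float(np.round(rng.uniform(0.5, 40), 1)),
                    "mitotic_count": int(rng.integers(0, 10)),
                    "tumor_size_mm": float(rng.integers(8, 90)),
                    "lymph_node_metastasis": int(rng.random() < 0.2),
                    "vascular_invasion": int(rng.random() < 0.4),
                    "lymphatic_invasion": int(rng.random() < 0.3),
                    "enets_stage": rng.choice(["I", "II", "III", "IV"]),
                    "marker_CNPY2": int(rng.random() < marker_rate),
                    "liver_rfs_months": rfs,
                    "liver_recurrence": np.nan if sync else event,
                    "os_months": float(np.round(rng.uniform(10, 200), 1)),
                    "death": int(rng.random() < 0.3),
                }
            )
    return CohortTable(pd.DataFrame(rows))


@pytest.fixture
def table3_cohort() -> CohortTable:
    return make_cohort()
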