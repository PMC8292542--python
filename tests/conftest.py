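import numpy as np
import pandas as pd
import pytest

from cnvmorph.data_model import CohortTable


def make_cohort_frame(
    n_per_group: dict[str, int],
    n_roi: int = 5,
    seed: int = 0,
    n_sites: int = 2,
    diagnosis: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Small synthetic cohort frame with iid N(0,1) ROI values."""
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group, n in n_per_group.items():
        for _ in range(n):
            rows.append(
                {
                    "subject_id": f"s{sid:04d}",
                    "group": group,
                    "ascertainment": "clinical",
                    "site": f"S{sid % n_sites + 1}",
                    "age": float(rng.uniform(10, 60)),
                    "sex": int(rng.integers(2)),
                    "TIV": float(rng.normal(1.45, 0.15)),
                    "total_GM": float(rng.normal(0.85, 0.08)),
                }
            )
            sid += 1
    df = pd.DataFrame(rows)
    if diagnosis:
        df["diagnosis"] = ""
        for idx, flags in diagnosis.items():
            df.loc[idx, "diagnosis"] = flags
    roi = pd.DataFrame(
        rng.standard_normal((len(df), n_roi)),
        columns=[f"roi_{i:03d}" for i in range(n_roi)],
    )
    return pd.concat([df, roi], axis=1)


@pytest.fixture
def small_cohort() -> CohortTable:
    return CohortTable(
        make_cohort_frame({"16p11.2_del": 5, "control": 5}, n_roi=5, seed=1)
    )
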