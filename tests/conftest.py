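import numpy as np
import pandas as pd
import pytest

from pdl1het.cohort import SimulationConfig, generate_cohort


def make_scored_frame(pairs, scheme="cps", lesion_prefix="L"):
    """Build a minimal scored per-core table from (reference, comparison)
    score pairs, one lesion per pair, both cores QC-passing."""
    rows = []
    for i, (ref, comp) in enumerate(pairs):
        lid = f"{lesion_prefix}{i}"
        for j, val in enumerate((ref, comp), start=1):
            rows.append(
                {
                    "patient_id": f"P{i}",
                    "lesion_id": lid,
                    "lesion_type": "primary",
                    "treated": False,
                    "core_id": f"{lid}-c{j}",
                    "sample_index": j,
                    "qc_pass": True,
                    "cps": float(val),
                    "tps": float(val),
                    "cps_raw": float(val),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 300-patient cohort shared across read-only tests."""
    cores, patients = generate_cohort(SimulationConfig(n_patients=300, seed=42))
    return cores, patients
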