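import numpy as np
import pandas as pd
import pytest

from prognosig import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """400-patient cohort with a planted 3-marker signature + 5 noise markers."""
    cohort, truth = simulate_cohort(SimConfig(n_patients=400, n_noise_markers=5, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """400-patient cohort with no planted signal (noise markers only)."""
    cohort, truth = simulate_cohort(
        SimConfig(n_patients=400, n_noise_markers=6, planted=[], seed=12)
    )
    return cohort, truth


@pytest.fixture()
def mixed_survival():
    """10 patients with hand-checkable mixed censoring."""
    time = np.array([3.0, 5.0, 5.0, 8.0, 10.0, 12.0, 12.0, 15.0, 20.0, 25.0])
    event = np.array([1, 1, 0, 1, 0, 1, 1, 0, 1, 0])
    return time, event


@pytest.fixture()
def tiny_cohort_file(tmp_path):
    df = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C", "D", "E"],
            "time": [12.0, 30.0, 45.0, 60.5, 88.0],
            "event": [1, 0, 1, 0, 0],
            "t_stage": ["T2", "T3", "T4", "T1", "T3"],
            "n_stage": ["N0", "N1", "N0", "N0", "N2"],
            "MK1": [0, 1, 2, np.nan, 3],
            "MK2": [5, 5, np.nan, 2, 1],
            "MK3": [1, 0, 1, 1, 0],
        }
    )
    path = tmp_path / "tiny.csv"
    df.to_csv(path, index=False, na_rep="NA")
    schema = {
        "id": "patient_id",
        "time": "time",
        "event": "event",
        "covariates": ["t_stage", "n_stage"],
        "markers": ["MK1", "MK2", "MK3"],
    }
    return path, schema
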