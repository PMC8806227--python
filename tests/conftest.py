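import numpy as np
import pandas as pd
import pytest

from pairhazard.data_model_io import ClinicalTable, ExpressionMatrix
from pairhazard.synthetic_cohorts import SimulationConfig, simulate_cohort_pair


@pytest.fixture(scope="session")
def study():
    """One simulated two-cohort study at the reference conditions (seed-fixed)."""
    return simulate_cohort_pair(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_study():
    """A lighter study for stages where sample size is not the point."""
    return simulate_cohort_pair(
        SimulationConfig(n_samples_per_cohort=120, seed=7, with_immune_markers=False))


@pytest.fixture()
def expr_3x2():
    return ExpressionMatrix(pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=["GENEA", "GENEB", "GENEC"], columns=["S1", "S2"]))


def make_clinical(times, events, **extra) -> ClinicalTable:
    n = len(times)
    df = pd.DataFrame({"os_time": np.asarray(times, dtype=float),
                       "os_event": np.asarray(events, dtype=int), **extra},
                      index=[f"S{i}" for i in range(n)])
    df.index.name = "sample_id"
    return ClinicalTable(df)
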