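import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import refchip as rc

settings.register_profile("default", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_experiment() -> rc.SimulatedExperiment:
    """A compact null-free experiment shared by read-only tests."""
    cfg = rc.SimulationConfig(
        n_target_peaks=400,
        n_control_peaks=800,
        n_spikein_peaks=100,
        fraction_changed=0.5,
        seed=101,
    )
    return rc.generate_experiment(cfg)


@pytest.fixture
def two_by_two() -> rc.CountsMatrix:
    return rc.CountsMatrix(
        pd.DataFrame(
            {"s1": [3, 0], "s2": [7, 5]}, index=["p1", "p2"]
        ),
        library_totals={"s1": 100.0, "s2": 200.0},
    )


def pair_sheet(n_rep: int = 1) -> rc.SampleSheet:
    """Minimal sheet with conditions 'control'/'treated', n_rep each."""
    recs = [
        {"sample_id": f"c{r}", "condition": "control", "replicate": r}
        for r in range(1, n_rep + 1)
    ] + [
        {"sample_id": f"t{r}", "condition": "treated", "replicate": r}
        for r in range(1, n_rep + 1)
    ]
    return rc.SampleSheet.from_records(recs)


def matrix_from_xy(x, y) -> rc.CountsMatrix:
    """One replicate per condition: per-peak means equal the given vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    names = [f"p{i}" for i in range(len(x))]
    return rc.CountsMatrix(pd.DataFrame({"c1": x, "t1": y}, index=names))
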