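from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from smoldercmp.config import SimulationConfig
from smoldercmp.synthetic import simulate_cohort


def visits_df(points, pid="P1"):
    """Build a visit table from (day, edss) tuples."""
    return pd.DataFrame(
        [(pid, d, e) for d, e in points], columns=["patient_id", "day", "edss"]
    )


def relapses_df(days, pid="P1"):
    return pd.DataFrame([(pid, d) for d in days], columns=["patient_id", "day"])


def mri_df(entries, pid="P1"):
    """entries: (day, new_t2_flag) tuples."""
    return pd.DataFrame(
        [(pid, d, f) for d, f in entries],
        columns=["patient_id", "day", "new_t2_flag"],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small simulated cohort (64/group) for module-level tests."""
    cfg = SimulationConfig(
        n_per_group=64,
        seed=20240917,
        n_atrophy_per_group=40,
        n_dti_per_group=20,
        n_prl_per_group=20,
    )
    return simulate_cohort(cfg)


def random_trajectory(rng: np.random.Generator):
    """Random visit grid + EDSS walk + relapse days for oracle checks."""
    n = int(rng.integers(2, 10))
    days = np.cumsum(rng.integers(30, 400, size=n)) - 30
    steps = [0.0] + [x / 2 for x in range(2, 21)]
    e = float(rng.choice(steps[:14]))
    edss = []
    for _ in range(n):
        edss.append(e)
        move = float(rng.choice([-1.5, -1.0, -0.5, 0.0, 0.0, 0.5, 1.0, 1.5, 2.0]))
        e = min(max(e + move, 0.0), 10.0)
        if e == 0.5:
            e = 1.0 if move > 0 else 0.0
    span = int(days[-1]) + 60
    n_rel = int(rng.integers(0, 4))
    rel = sorted(int(d) for d in rng.integers(0, span, size=n_rel))
    return list(zip((int(d) for d in days), edss)), rel
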