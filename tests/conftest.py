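import numpy as np
import pandas as pd
import pytest

from cadkin import (
    ExposureSchedule,
    KineticParams,
    SimulationConfig,
    generate_dataset,
    pooled_config,
)

DESIGN_DAYS = (0, 1, 3, 5, 10, 15, 21, 22, 24, 26, 31, 36, 42)


@pytest.fixture
def schedule():
    return ExposureSchedule(C_I0=2.0, C_Eu=100.0, C_Ed=1.0, t_C=21.0)


@pytest.fixture
def pooled_params():
    return {
        "contamination": KineticParams(kA=0.871, kE=1.119),
        "decontamination": KineticParams(kA=4.075, kE=0.33),
    }


@pytest.fixture
def noiseless_dataset():
    """Observations lying exactly on the pooled-truth two-phase curve."""
    cfg = pooled_config(
        noise_sd_contamination=0.0,
        noise_sd_decontamination=0.0,
        exceedance_prob=0.0,
        baseline_range=(2.0, 2.0),
        seed=0,
    )
    return generate_dataset(cfg).observations


@pytest.fixture
def default_dataset():
    return generate_dataset(SimulationConfig(seed=42)).observations


def make_endpoint_frame(cell_means, n_per_cell=4, sd=0.0, seed=0):
    """Balanced day-0/day-42 frame with given (time, habitat) cell means."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for (day, habitat), mean in cell_means.items():
        for _ in range(n_per_cell):
            i += 1
            rows.append(
                {
                    "colony_id": f"E{i:03d}",
                    "habitat": habitat,
                    "region": "paris" if i % 2 else "lyon",
                    "time_days": float(day),
                    "concentration": mean + (rng.normal(0, sd) if sd else 0.0),
                }
            )
    return pd.DataFrame(rows)
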