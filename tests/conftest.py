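import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gillscale as g

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null_truth() -> g.ScalingTruth:
    return g.ScalingTruth.null_scenario()


@pytest.fixture(scope="session")
def small_cohort(null_truth) -> pd.DataFrame:
    cfg = g.CohortConfig(n_per_temperature=6, seed=11)
    return g.generate_cohort(cfg, null_truth)


@pytest.fixture()
def example_gill_bins() -> pd.DataFrame:
    """Two bins on the reference hemibranch with hand-checkable numbers."""
    return pd.DataFrame(
        {
            "hemibranch_id": [4, 4],
            "bin_id": [1, 2],
            "filament_count": [12, 10],
            "median_filament_length_mm": [5.0, 8.0],
            "lamellar_freq_base_per_mm": [25.0, 20.0],
            "lamellar_freq_tip_per_mm": [35.0, 20.0],
            "lamellar_area_tip_mm2": [0.10, 0.20],
            "lamellar_area_mid_mm2": [0.10, 0.20],
            "lamellar_area_base_mm2": [0.10, 0.20],
        }
    )


def make_linear_trace(
    slope: float,
    n: int = 300,
    o2_start: float = 100.0,
    mass_g: float = 2.62,
    volume_l: float = 0.657,
    temperature_c: float = 15.0,
) -> g.OxygenTrace:
    t = np.arange(n, dtype=float)
    return g.OxygenTrace(
        fish_id="test",
        temperature_c=temperature_c,
        time_s=t,
        o2_percent_sat=o2_start + slope * t,
        system_volume_l=volume_l,
        fish_mass_g=mass_g,
    )
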