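import numpy as np
import pandas as pd
import pytest

import tempmort as tm


@pytest.fixture(scope="session")
def small_series():
    """One synthetic year, null truth, fixed seed."""
    cfg = tm.SyntheticConfig(n_years=1)
    series, _ = tm.generate_dataset(cfg, seed=11)
    return series


@pytest.fixture(scope="session")
def sthr_series():
    """Five synthetic years with a hockey-stick truth (h=30, RR 1.10/°C)."""
    cfg = tm.SyntheticConfig(
        surface=tm.TruthSurface(kind="sthr", threshold_high=30.0,
                                heat_slope=np.log(1.10)),
        mortality=tm.MortalityConfig(overdispersion=1.5),
    )
    series, truth = tm.generate_dataset(cfg, seed=7)
    return series, truth


@pytest.fixture
def tiny_frame():
    """Minimal well-formed 5-day CSV content as a DataFrame."""
    return pd.DataFrame({
        "date": ["2006-01-01", "2006-01-02", "2006-01-03", "2006-01-04", "2006-01-05"],
        "tmean": [27.0, 27.5, 28.0, 28.5, 29.0],
        "rh": [70.0, 71.0, 72.0, 73.0, 74.0],
        "all": [50, 52, 48, 55, 51],
    })


def write_csv(frame, path):
    frame.to_csv(path, index=False)
    return path
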