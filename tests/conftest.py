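import numpy as np
import pandas as pd
import pytest

from emadsem import GenDesign, GenParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Compact dataset for unit tests: 30 persons, 10 days."""
    design = GenDesign(n_persons=30, n_days=10, seed=7)
    return simulate_dataset(design, GenParams(), seed=7)


@pytest.fixture(scope="session")
def small_records(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size default dataset (140 persons, 21 days)."""
    return simulate_dataset(GenDesign(), GenParams(), seed=3)


def make_records(person_ids, times, observed=None, **columns) -> pd.DataFrame:
    """Hand-built record table for fixture-level tests."""
    n = len(times)
    frame = {
        "person_id": np.asarray(person_ids),
        "prompt_index": np.arange(n),
        "time_h": np.asarray(times, dtype=float),
        "day": (np.asarray(times, dtype=float) // 24).astype(int),
        "observed": np.ones(n, dtype=bool) if observed is None else np.asarray(observed),
    }
    frame.update({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    df = pd.DataFrame(frame)
    # prompt_index must restart per person for per-person bookkeeping
    df["prompt_index"] = df.groupby("person_id").cumcount()
    return df
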