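import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def testday_csv(tmp_path):
    """Small well-formed test-day table: 2 goats x 2 lactations."""
    rows = []
    for goat in ("A", "B"):
        for lact in (1, 2):
            kid = pd.Timestamp("2016-01-01") + pd.Timedelta(
                days=400 * (lact - 1))
            for dim in (20, 50, 80):
                rows.append({
                    "goat_id": goat, "lactation_no": lact,
                    "kidding_date": kid.date().isoformat(),
                    "control_date": (kid + pd.Timedelta(days=dim)
                                     ).date().isoformat(),
                    "milk_kg": 2.0, "protein_pct": 3.9, "fat_pct": 5.1,
                    "dm_pct": 14.0, "lactose_pct": 4.9, "scc": 5e5})
    path = tmp_path / "testday.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@pytest.fixture
def standard_fixture():
    """The 3-control lactation used in the hand-derived yield examples."""
    return np.array([20.0, 50.0, 80.0]), np.array([2.0, 2.4, 2.0])
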