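import numpy as np
import pandas as pd
import pytest

from paleosn import TimeBinScheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scheme4():
    """Four contiguous 10-Myr bins spanning 40-0 Ma."""
    return TimeBinScheme.uniform(40.0, 10.0)


@pytest.fixture
def occurrence_csv(tmp_path):
    """PBDB-dialect occurrence file with 3 valid rows."""
    path = tmp_path / "occ.csv"
    pd.DataFrame({
        "genus": ["Aa", "Bb", "Cc"],
        "class": ["Bivalvia", "Trilobita", "Anthozoa"],
        "collection_no": [1, 1, 2],
        "max_ma": [110.0, 105.0, 12.0],
        "min_ma": [100.0, 101.0, 10.0],
        "paleolat": [45.0, -12.0, 0.0],
    }).to_csv(path, index=False)
    return path


def tokens_from_counts(counts: dict) -> pd.DataFrame:
    """Bin-token frame with the given per-genus occurrence counts."""
    genera = [g for g, c in counts.items() for _ in range(c)]
    return pd.DataFrame({"genus": genera,
                         "collection_id": np.arange(len(genera))})
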